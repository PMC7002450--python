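# Methods

## The model

A tumor is treated as an exponentially growing population of cells,
`N(t) = e^{rt}`, with one new mutation per division (relaxations below).
Under the infinite-sites assumption a mutation born at time `t_n` is
carried by all descendants of its origin cell, so its final frequency in
a neutrally growing tumor is `f_n = e^{-r t_n}`: frequency rank encodes
occurrence order, and this is exact only for *linear* tumors, where every
parent subclone has a single child and higher frequency implies earlier
occurrence.

A driver mutation arising at time `t1` multiplies its subclone's growth
rate by a scalar `k >= 1` (`k = 1` is neutral).  At biopsy, `T = t1 + t2`,
the driver subclone holds `N_F = f_d N_tot` cells.  Passengers on the
driver's ancestral lineage — *generational hitchhikers* — are carried by
the whole subclone plus the ordinary descendants of their origin cell,
giving

    f_g(t_m) = [ e^{-r t_m} (N_tot - f_d N_tot + (f_d N_tot)^{1/k})
                 + f_d N_tot - (f_d N_tot)^{1/k} ] / N_tot ,

where the `(f_d N_tot)^{1/k}` term removes the subclone's hypothetical
neutral growth so it is not counted twice.  Two consequences drive the
whole method:

- `f_g` is an exponential decay `A e^{-r t} + B` toward a plateau
  `B = [f_d N_tot - (f_d N_tot)^{1/k}] / N_tot` just below the driver's
  own frequency; the gap `f_d - B = (f_d N_tot)^{1/k} / N_tot` encodes
  the driver effect and inverts in closed form:
  `k = ln(f_d N_tot) / ln((f_d - B) N_tot)`.
- differences of equally spaced hitchhiker frequencies cancel the
  plateau, so the growth rate has the affine-invariant estimators
  `r = ln[(f1 - f2)/(f2 - f3)]` (consecutive points) and, from three
  spread points at spacings n and 2n with `Λ = (f1-f2)/(f1-f3)`, the
  quadratic `Λ y² - y - Λ + 1 = 0` in `y = e^{-rn}`, whose roots are
  `y = 1` (the trivial zero-growth root) and `y = (1-Λ)/Λ` (the one
  used).

## The sliding scan

An ordered spectrum (frequencies sorted non-increasing, ties broken by
genomic coordinates) is scanned with trailing windows: position `i` is a
putative driver, the `m` mutations ranked above it are its presumed
hitchhikers, and the window is fitted with

    f_j ~ exp(-r (t_g + j)) (1 - alpha) + alpha

by least squares.  Two window models are provided, matching the two
regimes a spectrum presents:

- **offset mode** (deep windows): the within-window order is relative
  (1..m) and the generational-time offset `t_g` absorbs the window's
  absolute depth, so windows anywhere in the spectrum can be analyzed
  without the mutations outside them.  The default solver profiles the
  rate: at fixed `r` the amplitude and plateau are a linear
  least-squares solve, and the one-dimensional profile residual is
  minimized over a log grid plus local refinement (the residual can be
  bimodal in `r` — shallow pure exponential vs faster decay onto a
  plateau — so a pure local optimizer is not trusted).  A plain
  Levenberg–Marquardt path with the classical starts (`alpha = 0.01`,
  `t_g = 1`, tolerance 1e-4, best iterate kept on non-convergence) is
  retained as `method="lm"`.
- **simple mode** (first-driver windows): `t_g` is dropped and the time
  variable is the *absolute* ordering index, pinning the model's
  amplitude to 1 at order zero (the clonal root).  This is the right
  model when the window is anchored at the top of the spectrum, which
  is where an early, strong driver lives.

Per position the scan reports `r_{i-1}` (by default from the three-point
closed form on points at offsets (0, m/3, 2m/3) inside the trailing
window; the fitted `r` is used instead for head windows too short to
hold three spread points), the effect
`k_i = ln(f_i N_tot)/ln((f_i - alpha) N_tot)` with the observed `f_i` as
the putative driver frequency, and the effect signal
`e_i = r_{i-1} × k_i`, whose local maxima (optionally smoothed) are the
candidate drivers.

Undefined inversions are flagged as NaN, never dropped: `alpha >= f_i`
(the spectrum fell below the fitted plateau — itself a signature that a
real driver was just passed), a gap of at most one cell
(`(f_i - alpha) N_tot <= 1`: a plateau within one cell of the putative
driver is indistinguishable from the driver), and a gap below the
sample's frequency resolution (one part in the coverage, for
depth-downsampled spectra).  Without the resolution flag the argmax of
the effect signal lands on one-quantum staircase shelves deep in the
spectrum, with absurd implied effects.

## Simulators

The validation ground truth comes from a Gillespie birth–death process
started from one unmutated cell: events are chosen with probability
proportional to type prevalence, a uniform cell of that type divides or
dies, and each division hands the daughter `mu` new unique mutations
recorded as nodes of a lineage tree (carrier counts are subtree sizes,
which keeps ten-mutations-per-division runs in memory).  Defaults:
birth 1.0, death 0.1, driver = first mutation after the population
reaches 100 cells, driver multiplies its clone's birth rate by `k`, and
the run ends a geometric number of events (mean 5% of the population)
after the driver clone reaches 25% prevalence.  Whole-population
extinction, and loss of the driver clone before the stop rule fires,
void the attempt, which is resimulated with a fresh stream (letting the
trigger re-arm instead would allow the driver to re-arise in a much
larger tumor and adds a heavy tail of populations whose plateau gap is
unresolvable at 1000x).  A logistic mode raises the per-cell death rate
linearly toward the birth rate as a carrying capacity is approached, and
a lagged mode makes freshly divided cells ineligible to redivide for a
fixed time (tracked with a release heap).

The stochastic-mutation-rate variant draws Poisson(10) mutations per
division and grows to a fixed 10,000 cells with birth ln 2 and death 0 —
the canonical neutral protocol of the simulator family it emulates; a
selection coefficient `s` maps to `k = 1 + s`.

Coverage downsampling represents each mutation as carriers among 1000
binary individuals (frequency 0.475 = 475 carriers); coverage 1000 *is*
that representation (pure quantization), and lower coverages draw that
many carriers with replacement, dropping mutations drawn zero times.
This matters: at 1000× the plateau gap `(f_d N)^{1/k}/N` of a
10³–10⁴-cell tumor is above the quantization step and the driver effect
is recoverable, while binomial resampling noise at 100× buries it — which
is exactly the coverage degradation the benchmarks show.

### What the simulations do and do not emulate

The generators produce linear clonal expansions with a single injected
driver, exact frequencies (no sequencing error), and no deleterious
passengers, copy-number change, or spatial structure.  Passing benchmarks
therefore show that the estimators recover what the model defines under
idealized sampling; they do not certify performance on impure, CN-altered
or multi-branch tumors, whose corrections are assumed done upstream.

## Benchmark protocol and problem sizes

Each driver-effect cell simulates 100 tumors and the remaining cells 50
(the full study behind the reference numbers used several hundred across
its grid; the per-tumor effect estimates are wide and multimodal, and
100 replicates keep the cell medians stable to about ±0.1 while a cell
stays in the half-to-two-minute range on one core; the reproduction script doubles this again).  All birth–death
cells cap the population at 10⁴ cells, the simulation scale the
population projection is quoted at; the cap also bounds the heavy upper
tail of drift-delayed slow sweeps.  For the driver grid the spectrum is scanned in simple
mode with windows truncated at the spectrum head (size `min(150, i-1)`,
scan over the first 400 ordered mutations, the tumor's own final cell
count as `N_tot`); samples whose top lineage carries too little of the
population for the pinned-amplitude model (no defined effect anywhere)
are rescanned with the free-amplitude variant.  The best effect peak per
tumor gives the ranking distance `D` (peak rank minus true driver rank)
and the effect estimate; a random baseline draws one uniform mutation per
tumor and predicted-vs-random absolute distances are compared with a
two-tailed Welch t test.  A prediction within 16 ordered mutations is a
true positive (the reference distance-plus-2SE rule).  The nearly neutral
cell (`k = 1.1`) can never reach 25% prevalence in reasonable time, so it
is biopsied at a fixed 400 cells, comparable to the strong-effect cells'
final sizes.

The neutral window calibration runs 50 neutral stochastic-mutation-rate
tumors and reports the median per-window effect at window 150 — the
quantity that equals 1 at the calibrated window size (measured here:
0.80 at window 100, ~1.0–1.07 at 150, 1.13 at 200).  The per-tumor
*maximum* peak effect on the same spectra sits near 2.4 at every window
size — it is an extreme-value statistic and cannot be what a window size
tunes to 1, which is why the median-over-windows reading is used.

## Coalescent behavior of the growth estimator

When the scanned mutations are not generational hitchhikers the sign of
the three-point estimator is governed by whether the VAF-spectrum density
rises or falls.  Under the standard coalescent the interval with `n`
lineages lasts `T_n = 2/(n(n-1))`, carries `M_n ∝ mu·n·T_n` mutations at
expected frequency `1/n`, and the density in the window
`[1/n, 1/(n-1))` of length `L_n = 1/(n(n-1))` is `delta_n ∝ 2 mu n` —
increasing, hence a small positive estimate even at zero growth.  For a
population changing by a factor `alpha` per step (reverse time), the
lineage count is a Markov chain whose transition law is the occupancy
distribution `C(N,j)·S(i,j)·j!/N^i` (Stirling numbers of the second
kind).  The explicit matrix is computed in exact integer arithmetic
(Python bigints — the alternating Stirling sum is exact there at any
size); chain propagation instead uses a one-ball-at-a-time occupancy
recursion accumulated over the mixture in a single sweep, which is
numerically stable (no alternating cancellation) and O(lineages ×
population) per step, making the 10,240-lineage starting states of
strongly growing populations tractable.

Interval lengths come from threshold crossings of the expected lineage
count (linearly interpolated between steps); lineage counts the chain
falls through within the first step are unresolvable at the step
resolution and are excluded from the density profile.  Density trends:
"decreasing" is strict (every step down, matching the claim that only
fast enough shrinkage flips the estimator's sign, at about
`alpha > 1.4`, i.e. `r < -ln 1.4 ≈ -0.34`); "increasing" accepts a rank
correlation with `n` of at least 0.9, because growing-population
profiles rise with local wiggles.  Non-integer population sizes round
half-up.

## Enrichment statistics

A mutation category's association with positive growth compares its
count of `r_i > 0` mutations (strictly positive; ties at zero count as
non-positive) against 100 sample-matched bootstrap draws of equal size;
the z score divides by the bootstrap standard deviation (`SEM·√B`), and
PGE normalizes the excess by the category's total count.  Effect bins
are left-inclusive `[0.9, 1.1), [1.1, 1.3), …, [2.5, 2.7)`.  Growth
patterns are clustered by max-normalizing each sample's growth track,
averaging 20 equal-count bins, and running k-means (k = 3, 10 restarts,
fixed seed, samples processed in sorted order so labels do not depend on
input order); centroids are named steady / sigmoid / stagnation by
simple early-vs-late shape rules.  Peak alignment tests a candidate
set's distances to the nearest of the top five peaks against 1000
resampled-candidate replicates with a two-tailed Welch t test.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| window `m` | 150 | ordered mutations | neutral calibration: median window effect 1 on neutral spectra |
| `N_tot` | 1e6 (pipeline), simulated N (benchmarks) | cells | population the frequencies refer to; exposed as `--n-tot` |
| step | 1 | ordered mutations | per-mutation track, as the per-sample figures require |
| `r` source | closed form (deep), fitted (head) | — | three spread points need a window of at least ~9 |
| birth/death | 1.0 / 0.1 | rate per unit time | supercritical growth with modest turnover |
| trigger | 100 | cells | driver arises in an established but small tumor |
| stop prevalence | 0.25 | — | biopsy once the subclone is prominent |
| TP cutoff | 16 | ordered mutations | reference distance-plus-2SE rule |
| bootstrap B | 100 | replicates | enrichment expectation and SD |
| seed | 17 | — | every stochastic routine takes an explicit seed |

## Known limitations

- The effect estimate saturates near `ln(f_d N)/ln(q N)` where `q` is the
  frequency resolution; strong drivers in large tumors at finite coverage
  are reported at the cap (visible as compression of the k = 4 cell).
- On long spectra the profile solver finds genuine micro-plateaus of
  drift families; the per-sample maximum peak effect on neutral data is
  therefore ~2.4 rather than ~1, and cohort screening should compare
  peaks against this neutral-effect distribution rather than against 1.
  This also weakens the per-sample correlation between peak effect and
  simulated selection strength when pooled across wide selection ranges:
  strong sweeps leave the driver nearly clonal (no hitchhiker record) and
  weak ones leave it at drift frequencies, so only a middle band carries
  signal.
- Ranking distances cannot beat the reordering noise of the driver's own
  observed rank at a given coverage.
- Near-critical growth (death ≈ birth) makes every window look like a
  shallow plateau and is the regime where the method degrades fastest;
  the benchmarks deliberately use supercritical conditions where the
  first-driver model applies.
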