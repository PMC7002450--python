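# hitchdriver

Growth-pattern and driver-effect inference for single tumor samples,
from nothing but the variant-allele-frequency (VAF) spectrum.

Recurrence-based driver discovery needs large cohorts and misses
low-recurrence drivers.  In a deeply sequenced *linear* tumor (each
parent subclone has one child), the ordered VAF spectrum itself records
growth history: under the infinite-sites model a mutation born at
generation `t` has frequency `e^{-rt}`, and a subclonal driver that
multiplies its clone's growth rate by `k` bends the frequencies of the
passengers on its ancestral lineage — its *generational hitchhikers* —
onto

    f_g(t_m) = [e^{-r t_m}(N - f_d N + (f_d N)^{1/k}) + f_d N - (f_d N)^{1/k}] / N,

an exponential decay toward a plateau just below the driver's frequency
`f_d`.  Fitting sliding windows of ordered mutations with
`f ~ exp(-r(t_g + order))·(1-α) + α` yields a per-mutation growth rate
`r_i` (also available in closed form from three spread frequencies) and,
by inverting the plateau, a per-mutation driver effect
`k_i = ln(f_d N)/ln((f_d - α)N)`.  Peaks of the effect signal
`e_i = r_{i-1}·k_i` mark candidate drivers; cohort statistics (positive
growth enrichment, effect bins, growth-pattern clustering, peak
alignment) build on the per-mutation tracks.  Validation simulators
(Gillespie birth–death with an injected driver, logistic and
division-lag variants, a stochastic-mutation-rate variant, coverage
downsampling) and a coalescent analysis of the estimator's behavior on
non-hitchhiking mutations are included.

Intended users: cancer-genomics methodologists and analysts with
purity/copy-number-corrected mutation frequencies (frequency = 2×VAF)
from a single deeply sequenced sample.

## Worked example

```python
import numpy as np
import hitchdriver as hd

# simulate one tumor: birth-death growth, driver effect k=2 injected at
# 100 cells, biopsy after the subclone reaches 25% prevalence
tumor = hd.simulate_birth_death(hd.SimConfig(k=2.0), seed=7)
spectrum = hd.order_spectrum(
    tumor.spectrum(coverage=1000, rng=np.random.default_rng(7)), "demo"
)
true_rank = spectrum.rank_of(f"m{tumor.driver_id}")

track = hd.sliding_fit(
    spectrum, m=150, mode="simple", min_window=3, r_source="nls",
    n_tot=float(tumor.n_final), scan_limit=400, resolution=1e-3,
)
peak, k_hat = hd.best_peak(track)
print(f"driver at rank {true_rank}, peak at rank {peak}, k_hat = {k_hat:.2f}")
```

prints

```
driver at rank 5, peak at rank 6, k_hat = 1.90
```

the predicted effect peak sits one ordered mutation from the true
driver, and the estimated effect is near the simulated k = 2 (single
samples scatter; across 50 replicates the median is ~1.9–2.0).

The same pipeline is scriptable from the shell:

```
hitchdriver simulate --model bd --k 2 --coverage 1000 --n 5 --seed 17 --out sims/
hitchdriver fit sims/bd_rep0.tsv --window 150 --n-tot 1e6
hitchdriver peaks sims/bd_rep0.track.tsv --top 5
hitchdriver coalescent --alpha 1.5 --steps 200 --mu 0.01
```

## Layout

- `hitchdriver.growth` — closed-form frequency functions, growth
  estimators, effect inversion, population scaling
- `hitchdriver.inference` — spectrum ordering, window fits, sliding
  scan, peak detection, benchmarking
- `hitchdriver.simulate` — Gillespie tumors, lagged and stochastic-μ
  variants, coverage downsampling
- `hitchdriver.coalescent` — Kingman intervals, lineage-count chain,
  VAF-density trends
- `hitchdriver.enrichment` — PGE, effect bins, growth-pattern k-means,
  peak alignment
- `hitchdriver.io` / `hitchdriver.cli` — TSV/VCF formats, fixtures,
  benchmark orchestration, command line

`docs/methods.md` documents the model, the numerical choices and the
known limitations.
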