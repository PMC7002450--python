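"""Coalescent prediction of the growth estimator's sign on non-hitchhikers.

The three-point growth estimator assumes the mutations it sees are
generational hitchhikers.  When they are ordinary passengers, its sign is
governed by whether the mutational density of the VAF spectrum rises or
falls across frequency windows.  Under Kingman's coalescent the interval
with ``n`` lineages has expected length T_n = 2/(n(n-1)); mutations in it
number M_n ~ mu*n*T_n and land near frequency 1/n, so the density within
the window [1/n, 1/(n-1)) of length L_n = 1/(n(n-1)) is delta_n = M_n/L_n
~ 2*mu*n — increasing, hence a (small) positive estimate even at zero
growth.  For populations changing by a per-step factor alpha (indexed in
reverse time), the lineage count is propagated through an exact Markov
chain whose transition law is the classical occupancy distribution
(binomial-coefficient x Stirling-number form), and the density trend
classifies the estimator's predicted sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoalescentDensity",
    "kingman_intervals",
    "constant_density",
    "stirling2",
    "transition_matrix",
    "occupancy_step",
    "varying_density",
]


@dataclass
class CoalescentDensity:
    """Per-lineage-count interval lengths and VAF-window densities.

    n        lineage counts (ascending)
    T        interval length with n lineages (coalescent units or steps)
    M        mutations acquired in the interval (up to a mu constant)
    L        VAF-window length 1/(n(n-1))
    delta    density M/L
    trend    'increasing', 'decreasing' (strict) or 'mixed'
    """

    n: np.ndarray
    T: np.ndarray
    M: np.ndarray
    L: np.ndarray
    delta: np.ndarray
    trend: str

    @property
    def r_hat_sign(self) -> int:
        """Predicted sign of the growth estimator: +1 when density rises
        with n, -1 when it strictly falls, 0 otherwise."""
        if self.trend == "increasing":
            return 1
        if self.trend == "decreasing":
            return -1
        return 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.n, "T_n": self.T, "M_n": self.M, "L_n": self.L, "delta_n": self.delta}
        )


def _classify_trend(delta: np.ndarray) -> str:
    """'decreasing' is strict (every step down); 'increasing' is a trend
    call (all steps up, or a rank correlation with n of at least 0.9),
    since growing-population profiles rise with local wiggles."""
    d = np.diff(delta)
    if len(d) == 0:
        return "mixed"
    if np.all(d < 0):
        return "decreasing"
    if np.all(d > 0):
        return "increasing"
    n = np.arange(len(delta), dtype=float)
    rho = stats.spearmanr(n, delta).statistic
    if np.isfinite(rho) and rho >= 0.9:
        return "increasing"
    return "mixed"


def kingman_intervals(N: int) -> tuple[np.ndarray, np.ndarray]:
    """Expected interval lengths T_n = 2/(n(n-1)) for n = 2..N (coalescent
    time units, population size scaled out)."""
    if N < 2:
        raise ValueError("need a sample of at least 2")
    n = np.arange(2, N + 1)
    return n, 2.0 / (n * (n - 1.0))


def constant_density(N: int, mu: float) -> CoalescentDensity:
    """Closed-form density profile for a constant-size population:
    M_n = 2 mu/(n-1), L_n = 1/(n(n-1)), delta_n = 2 mu n (increasing)."""
    n, T = kingman_intervals(N)
    M = mu * n * T
    L = 1.0 / (n * (n - 1.0))
    delta = M / L
    return CoalescentDensity(n=n, T=T, M=M, L=L, delta=delta, trend=_classify_trend(delta))


def stirling2(i: int, j: int) -> int:
    """Stirling number of the second kind, exact integer alternating sum."""
    if j < 0 or j > i:
        return 0
    if i == 0:
        return 1 if j == 0 else 0
    total = 0
    for k in range(j + 1):
        term = math.comb(j, k) * k**i
        total += term if (j - k) % 2 == 0 else -term
    return total // math.factorial(j)


def transition_matrix(i_max: int, n_next: int) -> np.ndarray:
    """Markov transition law for the reverse-time lineage count.

    tau[i, j] (1-based lineage counts, returned as an (i_max+1)^2 array
    with row/col 0 unused beyond tau[0,0]=1) is the probability that i
    lineages have j distinct ancestors among ``n_next`` cells:
    C(n_next, j) * S(i, j) * j! / n_next**i.  Exact integer arithmetic
    throughout (Python bigints), converted to float at the end.
    """
    if i_max < 1 or n_next < 1:
        raise ValueError("need i_max >= 1 and n_next >= 1")
    tau = np.zeros((i_max + 1, i_max + 1))
    tau[0, 0] = 1.0
    for i in range(1, i_max + 1):
        denom = n_next**i
        for j in range(1, min(i, n_next, i_max) + 1):
            num = math.comb(n_next, j) * stirling2(i, j) * math.factorial(j)
            tau[i, j] = num / denom
    return tau


def occupancy_step(p: np.ndarray, n_next: int) -> np.ndarray:
    """Propagate a lineage-count distribution one step back in time.

    ``p[i]`` is the probability of i lineages (index 0 unused).  Each
    lineage picks a parent uniformly among ``n_next`` cells; the new count
    is the number of distinct picks.  Evaluated by the one-ball-at-a-time
    occupancy recursion, accumulating the mixture over i in a single
    sweep — numerically stable (all terms non-negative) and O(i_max *
    n_next), unlike the alternating Stirling sum.
    """
    i_max = len(p) - 1
    j_cap = min(i_max, n_next)
    v = np.zeros(j_cap + 1)
    v[0] = 1.0  # zero balls thrown -> zero boxes occupied
    out = np.zeros(i_max + 1)
    out[0] = p[0] if i_max >= 0 else 0.0
    jj = np.arange(j_cap + 1, dtype=float)
    for b in range(1, i_max + 1):
        nv = v * (jj / n_next)
        nv[1:] += v[:-1] * ((n_next - jj[1:] + 1.0) / n_next)
        v = nv
        if p[b] != 0.0:
            out[: j_cap + 1] += p[b] * v
    return out


def varying_density(
    alpha: float,
    steps: int = 200,
    mu: float = 0.01,
    n_base: int = 10,
    interpolate: bool = True,
) -> CoalescentDensity:
    """Density profile for an exponentially changing population.

    Reverse-time population model N_{t+1} = alpha * N_t.  ``alpha > 1``
    means the population grows backward in time, i.e. shrinks forward
    (negative growth, r = -ln(alpha)); ``alpha < 1`` is a forward-growing
    population.  Decreasing populations start at N_0 = ``n_base`` and cap
    at n_base * alpha**10; increasing ones are capped below at ``n_base``
    and start at n_base * alpha**-10.  After the cap is reached the size
    is held constant.  The full population is sampled, the lineage-count
    chain is propagated ``steps`` times, interval lengths come from the
    expected-lineage curve's threshold crossings (linearly interpolated
    between steps by default), and densities follow the constant-size
    construction.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if alpha >= 1.0:
        n0 = n_base
        n_cap = max(1, round(n_base * alpha**10))
        sizes = [min(n_cap, max(1, round(n0 * alpha**t))) for t in range(1, steps + 1)]
    else:
        n0 = max(1, round(n_base * alpha**-10))
        sizes = [max(n_base, max(1, round(n0 * alpha**t))) for t in range(1, steps + 1)]

    p = np.zeros(n0 + 1)
    p[n0] = 1.0
    counts = np.arange(n0 + 1, dtype=float)
    g = np.empty(steps + 1)
    g[0] = float(n0)
    support = n0
    for t, n_next in enumerate(sizes, start=1):
        p = occupancy_step(p[: support + 1], n_next)
        support = len(p) - 1
        g[t] = float(np.dot(np.arange(support + 1, dtype=float), p))

    def crossing(level: float) -> float:
        idx = np.nonzero(g <= level)[0]
        if len(idx) == 0:
            return math.nan
        t = int(idx[0])
        if t == 0 or not interpolate:
            return float(t)
        return (t - 1) + (g[t - 1] - level) / (g[t - 1] - g[t])

    ns, Ts = [], []
    for n in range(2, n0 + 1):
        hi = crossing(float(n))
        lo = crossing(float(n - 1))
        if math.isnan(hi) or math.isnan(lo):
            continue
        if lo < 1.0:
            # the chain falls below this lineage count within the first
            # discrete step; the interval length cannot be resolved
            continue
        ns.append(n)
        Ts.append(lo - hi)
    n_arr = np.asarray(ns, dtype=float)
    T_arr = np.asarray(Ts, dtype=float)
    M = mu * n_arr * T_arr
    L = 1.0 / (n_arr * (n_arr - 1.0))
    delta = M / L
    return CoalescentDensity(
        n=n_arr.astype(int), T=T_arr, M=M, L=L, delta=delta, trend=_classify_trend(delta)
    )
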