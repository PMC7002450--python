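"""Closed-form equations of the generational-hitchhiker growth framework.

A tumor is modeled as an exponentially growing cell population (rate ``r``
per generation, one new mutation per division by default).  A driver
mutation arising at time ``t1`` multiplies its subclone's growth rate by a
scalar ``k``; passengers that arose on the driver's ancestral lineage
("generational hitchhikers") end up with frequencies that decay
exponentially toward a plateau set by the driver's final frequency ``f_d``.
This module collects the pure closed-form pieces: the hitchhiker frequency
function, two growth-rate estimators built on frequency differences, the
inversion of the fitted plateau into the driver effect ``k``, and the
population-size scaling that projects simulated effects onto realistically
sized tumors.

All functions are scalar/array polymorphic and side-effect free; the
inference and simulation modules build on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthParams",
    "TripletFrequencies",
    "neutral_frequency",
    "hitchhiker_frequency",
    "growth_from_triplet",
    "growth_closed_form",
    "effect_from_asymptote",
    "asymptote_from_effect",
    "scale_effect",
    "generation_interval",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of a single-driver exponential growth episode.

    r      base growth rate per generation
    k      driver scalar multiplier (k = 1 is neutral)
    t1     driver occurrence time (generations from tumor initiation)
    t2     driver expansion time (generations from driver to biopsy)
    n_tot  total cell count at biopsy
    f_d    driver frequency at biopsy, in [0, 1]
    t_g    generational-time offset used when a window is analyzed with
           relative rather than absolute mutation order
    """

    r: float
    k: float
    t1: float
    t2: float
    n_tot: float
    f_d: float
    t_g: float = 0.0

    def __post_init__(self) -> None:
        if self.n_tot <= 0:
            raise ValueError("n_tot must be positive")
        if not (0.0 <= self.f_d <= 1.0):
            raise ValueError("f_d must lie in [0, 1]")
        if self.k < 0:
            raise ValueError("k must be non-negative")

    @property
    def T(self) -> float:
        """Biopsy time t1 + t2."""
        return self.t1 + self.t2


@dataclass(frozen=True)
class TripletFrequencies:
    """Frequencies of three hitchhikers at times t, t+n, t+m (m = 2n)."""

    f1: float
    f2: float
    f3: float
    n: float = 1.0

    def spacing_valid(self) -> bool:
        return self.n > 0


def neutral_frequency(t_n, r):
    """Frequency at biopsy of a mutation born at time ``t_n`` under neutral
    exponential growth: f = exp(-r * t_n)."""
    return np.exp(-np.asarray(r, dtype=float) * np.asarray(t_n, dtype=float))


def hitchhiker_frequency(t_m, params: GrowthParams):
    """Frequency at biopsy of a generational hitchhiker born at ``t_m``.

    The population at biopsy splits into the driver subclone (``f_d * n_tot``
    cells, grown at rate ``k * r`` since ``t1``) and the regular remainder.
    A hitchhiker born at ``t_m <= t1`` sits on the driver's ancestral
    lineage, so it is carried by the whole subclone plus the regular
    descendants of its origin cell; the subclone's hypothetical neutral
    growth ``(f_d n_tot)^(1/k)`` is subtracted once so those cells are not
    double counted:

        f_g(t_m) = [ e^{-r (t_g + t_m)} (N - fdN + fdN^(1/k)) + fdN - fdN^(1/k) ] / N

    with ``fdN = f_d * n_tot``.  For ``k = 1`` this collapses to the neutral
    exponential, and as ``t_m -> t1`` (with ``t1`` counted in effective
    generations, i.e. ``e^{-r t1} n_tot-side bookkeeping``) the frequency
    approaches ``f_d`` from above.
    """
    t_m = np.asarray(t_m, dtype=float)
    fdn = params.f_d * params.n_tot
    if fdn <= 0:
        raise ValueError("f_d * n_tot must be positive (subclone root undefined)")
    sub_root = fdn ** (1.0 / params.k)
    decay = np.exp(-params.r * (params.t_g + t_m))
    value = (decay * (params.n_tot - fdn + sub_root) + fdn - sub_root) / params.n_tot
    return value


def growth_from_triplet(f1, f2, f3) -> float:
    """Growth rate from three consecutive, equally spaced hitchhikers.

    r = ln((f1 - f2) / (f2 - f3)).  Exact on any noiseless series
    A * exp(-r t) + B (affine invariant).  A non-monotone triplet makes the
    log argument non-positive; the point is flagged as undefined growth by
    returning NaN rather than raising, so a sliding scan can continue.
    """
    d1 = f1 - f2
    d2 = f2 - f3
    if d1 == 0 or d2 == 0:
        return math.nan
    ratio = d1 / d2
    if ratio <= 0:
        return math.nan
    return math.log(ratio)


def growth_closed_form(f_t, f_tn, f_t2n, n: float = 1.0) -> float:
    """Growth rate from three hitchhikers spaced n and 2n apart.

    With lambda = (f(t) - f(t+n)) / (f(t) - f(t+2n)) the substitution
    y = e^{-r n} turns the frequency relation into the quadratic
    lambda*y^2 - y - lambda + 1 = 0 whose roots are y = 1 (the trivial
    zero-growth root) and y = (1 - lambda)/lambda.  The non-trivial branch
    is taken; r = -ln(y)/n.  Negative r (growing frequency series) is
    returned by the same formula; degenerate lambdas give NaN.
    """
    if n <= 0:
        raise ValueError("spacing n must be positive")
    denom = f_t - f_t2n
    if denom == 0:
        return math.nan
    lam = (f_t - f_tn) / denom
    if lam == 0 or lam == 1:
        return math.nan
    y = (1.0 - lam) / lam
    if y <= 0:
        return math.nan
    return -math.log(y) / n


def effect_from_asymptote(alpha: float, f_d: float, n_tot: float) -> float:
    """Invert the fitted plateau into the driver effect k.

    The hitchhiker curve's intercept is
    B = (f_d n_tot - (f_d n_tot)^(1/k)) / n_tot; identifying the fitted
    plateau ``alpha`` with B gives

        k = ln(f_d * n_tot) / ln((f_d - alpha) * n_tot).

    A negative fitted plateau maps to k < 1 by the same formula (the
    continuation used when binning effects below neutral).  Undefined (NaN)
    when alpha >= f_d or (f_d - alpha) * n_tot <= 1, where the log ratio
    leaves its meaningful branch.
    """
    if n_tot <= 0 or f_d <= 0:
        return math.nan
    fdn = f_d * n_tot
    if fdn <= 1:
        return math.nan
    if alpha >= f_d:
        return math.nan
    rem = (f_d - alpha) * n_tot
    if rem <= 1:
        return math.nan
    return math.log(fdn) / math.log(rem)


def asymptote_from_effect(k: float, f_d: float, n_tot: float) -> float:
    """Forward map: plateau alpha implied by driver effect k (inverse of
    :func:`effect_from_asymptote`)."""
    fdn = f_d * n_tot
    if fdn <= 0 or k <= 0:
        raise ValueError("need f_d * n_tot > 0 and k > 0")
    return (fdn - fdn ** (1.0 / k)) / n_tot


def scale_effect(k, n_sim, n_real):
    """Project a simulated effect onto a larger population.

    Conserves N*(k-1) (equivalently the classical 4Ns): the effect a driver
    of strength ``k`` in an ``n_sim``-cell simulation corresponds to in an
    ``n_real``-cell tumor is k* = 1 + n_sim * (k - 1) / n_real; the
    projected selection coefficient is s* = k* - 1.
    """
    if np.any(np.asarray(n_sim) <= 0) or np.any(np.asarray(n_real) <= 0):
        raise ValueError("population sizes must be positive")
    return 1.0 + np.asarray(n_sim, dtype=float) * (np.asarray(k, dtype=float) - 1.0) / np.asarray(
        n_real, dtype=float
    )


def generation_interval(mu_total: float) -> float:
    """Expected number of generations between consecutive mutations.

    Time units in the estimators are inter-mutation intervals.  With a total
    per-division mutation rate mu_total the expected interval is
    2 / mu_total generations (one new mutation per division corresponds to
    mu_total = 2), so per-interval growth rates divide by this factor to
    convert to per-generation units.
    """
    if mu_total <= 0:
        raise ValueError("mutation rate must be positive")
    return 2.0 / mu_total
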