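"""Sliding-window growth and driver-effect inference from a VAF spectrum.

The observable is an ordered mutation list: corrected mutational
frequencies (2x VAF, purity and copy-number adjusted upstream) sorted from
highest to lowest, so that in a linear tumor rank approximates occurrence
order.  A window of ``m`` consecutive ordered mutations ending just above
position ``i`` is treated as the generational hitchhikers of a putative
driver at ``i`` and fitted with the exponential-plus-plateau model

    f_j ~ exp(-r (t_g + j)) * (1 - alpha) + alpha,    j = 1..m,

by nonlinear least squares (starts alpha = 0.01, t_g = 1; the simple mode
drops t_g when the window's own amplitude is known to be ~1).  The fitted
plateau inverts to a driver effect k_i via the closed-form intercept, the
growth rate r_{i-1} comes by default from the three-point closed-form
estimator on spread points inside the window, and the per-mutation effect
signal e_i = r_{i-1} * k_i peaks at putative drivers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .growth import effect_from_asymptote, growth_closed_form

__all__ = [
    "VafSpectrum",
    "WindowFit",
    "GrowthTrack",
    "order_spectrum",
    "fit_window",
    "sliding_fit",
    "detect_peaks",
    "best_peak",
    "benchmark_distances",
    "classify_predictions",
    "tune_window",
]

_REQUIRED = ("id", "freq")
_TIE_COLS = ("chrom", "pos", "ref", "alt")


@dataclass
class VafSpectrum:
    """Ordered mutation list with corrected frequencies.

    ``table`` is sorted by non-increasing frequency, ties broken by
    (chrom, pos, ref, alt); the 1-based ordering index is in column ``i``.
    """

    table: pd.DataFrame
    sample_id: str = "sample"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def freq(self) -> np.ndarray:
        return self.table["freq"].to_numpy()

    def rank_of(self, mutation_id: str) -> int:
        """1-based ordered index of a mutation id."""
        hits = self.table.index[self.table["id"] == mutation_id]
        if len(hits) == 0:
            raise KeyError(mutation_id)
        return int(self.table.loc[hits[0], "i"])


def order_spectrum(raw: pd.DataFrame, sample_id: str = "sample") -> VafSpectrum:
    """Sort a mutation table by descending frequency and assign ranks.

    Frequencies must lie in (0, 1]; ties order deterministically by
    (chrom, pos, ref, alt) so reruns are stable.
    """
    if len(raw) == 0:
        raise ValueError("empty mutation table")
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    freq = raw["freq"].to_numpy(dtype=float)
    if np.any(~np.isfinite(freq)) or np.any(freq <= 0) or np.any(freq > 1):
        bad = np.sum(~((freq > 0) & (freq <= 1)))
        raise ValueError(f"{bad} frequencies outside (0, 1]")
    if raw["id"].duplicated().any():
        raise ValueError("duplicate mutation ids")
    df = raw.copy()
    tie_cols = [c for c in _TIE_COLS if c in df.columns]
    df["_negf"] = -df["freq"]
    df = df.sort_values(["_negf", *tie_cols], kind="mergesort").drop(columns="_negf")
    df = df.reset_index(drop=True)
    df["i"] = np.arange(1, len(df) + 1)
    return VafSpectrum(table=df, sample_id=sample_id)


@dataclass(frozen=True)
class WindowFit:
    """One sliding-window least-squares result (indices are 1-based ranks)."""

    start: int
    end: int
    r: float
    alpha: float
    t_g: float
    rss: float
    converged: bool


def _model_offset(j: np.ndarray, r: float, t_g: float, alpha: float) -> np.ndarray:
    expo = np.clip(-r * (t_g + j), -700.0, 700.0)
    return np.exp(expo) * (1.0 - alpha) + alpha


def _model_simple(j: np.ndarray, r: float, alpha: float) -> np.ndarray:
    expo = np.clip(-r * j, -700.0, 700.0)
    return np.exp(expo) * (1.0 - alpha) + alpha


def _closed_form_r(window: np.ndarray, spacing: int | None = None) -> float:
    """Three-point closed-form growth estimate inside one window."""
    m = len(window)
    n = spacing if spacing is not None else m // 3
    if n < 1 or 2 * n >= m:
        return math.nan
    return growth_closed_form(window[0], window[n], window[2 * n], n)


def _profile_rss(window: np.ndarray, j: np.ndarray, r: float, mode: str):
    """Best (amplitude, plateau) at fixed r by linear least squares.

    In offset mode the model A e^{-r j} + alpha (A = e^{-r t_g}(1-alpha))
    is linear in (A, alpha); in simple mode the amplitude is pinned so
    that e^{-r j}(1-alpha) + alpha leaves only alpha linear.  The plateau
    is deliberately left unconstrained — windows without real plateau
    curvature then land at alpha <= 0 (a sub-neutral effect) instead of
    piling up just below the window minimum; only the amplitude is kept
    non-negative.
    """
    e = np.exp(np.clip(-r * j, -700.0, 0.0))
    if mode == "simple":
        g = 1.0 - e
        gg = float(g @ g)
        alpha = float(g @ (window - e)) / gg if gg > 0 else 0.0
        resid = e * (1.0 - alpha) + alpha - window
        return float(resid @ resid), 1.0 - alpha, alpha
    # offset mode: solve the 2x2 normal equations for (A, alpha)
    see = float(e @ e)
    se = float(e.sum())
    sf = float(window.sum())
    sef = float(e @ window)
    n = float(len(j))
    det = see * n - se * se
    if det <= 0:
        return float(np.sum((e - window) ** 2)), 1.0, 0.0
    A = (sef * n - se * sf) / det
    alpha = (see * sf - se * sef) / det
    if A < 0.0:
        A = 0.0
        alpha = sf / n
    resid = A * e + alpha - window
    return float(resid @ resid), A, alpha


def fit_window(
    spectrum: VafSpectrum | np.ndarray,
    start: int,
    m: int,
    mode: str = "offset",
    tol: float = 1e-4,
    method: str = "profile",
    absolute_order: bool | None = None,
) -> WindowFit:
    """Fit the exponential-plateau model to ``m`` ordered mutations
    beginning at 1-based rank ``start``.

    The default solver profiles the rate: for each candidate r the
    amplitude and plateau are linear least-squares solutions, and the
    one-dimensional profile residual is minimized over r.
    ``method='lm'`` runs the plain unbounded Levenberg-Marquardt recipe
    instead (starts alpha = 0.01, t_g = 1).  Non-convergence keeps the
    best iterate and sets ``converged=False`` rather than raising, so a
    scan over a whole sample never aborts.

    In simple mode the time variable is the absolute ordering index (the
    model's amplitude is pinned to 1 at order zero, i.e. the clonal
    root), so the mode is meaningful for windows anchored at, or close
    to, the top of the spectrum; offset mode uses the relative order
    1..m and lets t_g absorb the window's depth.  ``absolute_order``
    overrides that default.
    """
    freqs = spectrum.freq if isinstance(spectrum, VafSpectrum) else np.asarray(spectrum, float)
    if start < 1 or start + m - 1 > len(freqs):
        raise ValueError("window out of range")
    if mode not in ("offset", "simple"):
        raise ValueError(f"unknown mode {mode!r}")
    window = freqs[start - 1 : start - 1 + m]
    if absolute_order is None:
        absolute_order = mode == "simple"
    if absolute_order:
        j = np.arange(start, start + m, dtype=float)
    else:
        j = np.arange(1, m + 1, dtype=float)

    if method == "profile":
        # the profile RSS can be bimodal in r (shallow pure exponential vs
        # faster decay onto a plateau), so scan a log grid before refining
        grid = np.exp(np.linspace(math.log(1e-4), math.log(5.0), 40))
        rss_grid = [_profile_rss(window, j, rv, mode)[0] for rv in grid]
        best = int(np.argmin(rss_grid))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda lr: _profile_rss(window, j, math.exp(lr), mode)[0],
            bounds=(math.log(lo), math.log(hi)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        r = float(math.exp(res.x))
        rss, A, alpha = _profile_rss(window, j, r, mode)
        if mode == "simple":
            t_g = 0.0
        else:
            amp = A / (1.0 - alpha) if alpha < 1.0 else A
            t_g = -math.log(amp) / r if amp > 0 else math.nan
        return WindowFit(
            start=start, end=start + m - 1, r=r, alpha=float(alpha), t_g=t_g,
            rss=rss, converged=bool(res.success),
        )

    if method != "lm":
        raise ValueError(f"unknown method {method!r}")
    r0 = _closed_form_r(window)
    if not np.isfinite(r0) or r0 == 0.0:
        r0 = 0.01
    if mode == "offset":
        x0 = np.array([r0, 1.0, 0.01])

        def resid(p):
            return _model_offset(j, *p) - window

    else:
        x0 = np.array([r0, 0.01])

        def resid(p):
            return _model_simple(j, *p) - window

    try:
        res = optimize.least_squares(resid, x0, method="lm", xtol=tol, ftol=tol, max_nfev=10_000)
        x, converged = res.x, bool(res.status > 0)
        rss = float(2.0 * res.cost)
    except Exception:  # keep the start values as a flagged non-fit
        x, converged, rss = x0, False, float(np.sum(resid(x0) ** 2))
    if mode == "offset":
        r, t_g, alpha = (float(v) for v in x)
    else:
        r, alpha = (float(v) for v in x)
        t_g = 0.0
    return WindowFit(
        start=start, end=start + m - 1, r=r, alpha=alpha, t_g=t_g, rss=rss, converged=converged
    )


@dataclass
class GrowthTrack:
    """Per-mutation growth, effect and effect-signal along a spectrum.

    ``table`` has one row per scanned rank ``i`` (the putative driver
    position): the trailing-window growth ``r`` (assigned from the window
    ending at i-1), the effect ``k``, the signal ``effect = r * k``, the
    window plateau ``alpha`` and convergence flag.
    """

    table: pd.DataFrame
    sample_id: str
    m: int
    n_tot: float
    peaks: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def effect_signal(self) -> np.ndarray:
        return self.table["effect"].to_numpy()

    @property
    def ranks(self) -> np.ndarray:
        return self.table["i"].to_numpy()


def sliding_fit(
    spectrum: VafSpectrum,
    m: int = 150,
    step: int = 1,
    n_tot: float = 1e6,
    mode: str = "offset",
    r_source: str = "closed_form",
    scan_limit: int | None = None,
    triplet_spacing: int | None = None,
    resolution: float = 0.0,
    min_window: int | None = None,
    min_gap_cells: float = 1.0,
    method: str = "profile",
) -> GrowthTrack:
    """Scan a spectrum with trailing windows and build the growth track.

    For each rank ``i`` from m+1 onward (up to ``scan_limit`` if given),
    the window covering ranks i-m..i-1 yields r_{i-1} (from the
    closed-form three-point estimator by default, or the NLS fit when
    ``r_source='nls'``) and the plateau alpha; the effect at ``i`` uses
    the observed frequency at ``i`` as the putative driver frequency:
    k_i = ln(f_i N) / ln((f_i - alpha) N).  Windows whose inversion is
    undefined carry NaN k (flagged, never dropped silently).

    ``min_window`` lets the scan start before a full window is
    available: positions with at least that many ordered mutations above
    them are fitted with the window truncated at the spectrum head (the
    first-driver regime, where the simple mode applies); by default the
    scan starts only at i = m + 1.

    Undefined-effect flags beyond the root-undefined rule:
    ``resolution`` marks gaps f_i - alpha below the smallest frequency
    step the sample can represent (1/coverage for a depth-downsampled
    spectrum), and ``min_gap_cells`` requires the implied regular
    remainder (f_i - alpha) * n_tot to exceed that many cells (the
    default restates the root-undefined rule: a plateau within one cell
    of the putative driver frequency is indistinguishable from the
    driver itself).
    """
    freqs = spectrum.freq
    L = len(freqs)
    lo = min_window if min_window is not None else m
    if L < lo + 1:
        raise ValueError(f"spectrum length {L} < minimum window + 1 = {lo + 1}")
    stop = min(L, scan_limit) if scan_limit else L
    rows = []
    for i in range(lo + 1, stop + 1, step):
        mm = min(m, i - 1)
        fit = fit_window(freqs, i - mm, mm, mode=mode, method=method)
        if r_source == "closed_form":
            r = _closed_form_r(freqs[i - mm - 1 : i - 1], spacing=triplet_spacing)
        elif r_source == "nls":
            r = fit.r
        else:
            raise ValueError(f"unknown r_source {r_source!r}")
        f_i = freqs[i - 1]
        gap = f_i - fit.alpha
        if gap < resolution or gap * n_tot <= min_gap_cells:
            k = math.nan
        else:
            k = effect_from_asymptote(fit.alpha, f_i, n_tot)
        e = r * k if (np.isfinite(r) and np.isfinite(k)) else math.nan
        rows.append(
            {
                "i": i,
                "id": spectrum.table.loc[i - 1, "id"],
                "freq": f_i,
                "r": r,
                "alpha": fit.alpha,
                "t_g": fit.t_g,
                "k": k,
                "effect": e,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    return GrowthTrack(table=table, sample_id=spectrum.sample_id, m=m, n_tot=n_tot)


def _local_maxima(signal: np.ndarray) -> np.ndarray:
    """Indices of strict-left / non-strict-right local maxima, boundaries
    included (a monotone decreasing signal peaks at its first point)."""
    x = np.where(np.isfinite(signal), signal, -np.inf)
    n = len(x)
    if n == 0:
        return np.empty(0, dtype=int)
    left = np.empty(n)
    right = np.empty(n)
    left[0] = -np.inf
    left[1:] = x[:-1]
    right[-1] = -np.inf
    right[:-1] = x[1:]
    idx = np.nonzero((x > left) & (x >= right) & np.isfinite(signal))[0]
    return idx


def detect_peaks(
    track: GrowthTrack, top_n: int = 5, smooth: int | None = None
) -> list[int]:
    """Top effect peaks of a growth track, as ordered-mutation ranks.

    ``smooth`` applies a centered moving average of that width before the
    local-maximum scan (window shorter than the smoother falls back to the
    raw signal).  Peaks are ranked by height; the track's ``peaks`` field
    is updated in place and the list returned.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    sig = track.effect_signal.astype(float)
    if smooth and smooth > 1:
        if len(sig) < smooth:
            import warnings

            warnings.warn("track shorter than smoothing bin; using raw signal")
        else:
            s = pd.Series(sig)
            sig = s.rolling(smooth, center=True, min_periods=1).mean().to_numpy()
    idx = _local_maxima(sig)
    if len(idx) == 0:
        track.peaks = []
        return []
    order = idx[np.argsort(sig[idx])[::-1]]
    ranks = track.ranks
    peaks = [int(ranks[i]) for i in order[:top_n]]
    track.peaks = peaks
    return peaks


def best_peak(track: GrowthTrack, smooth: int | None = None) -> tuple[int, float]:
    """Rank and effect estimate k of the highest effect peak."""
    peaks = detect_peaks(track, top_n=1, smooth=smooth)
    if not peaks:
        raise ValueError("no defined effect signal in track")
    i = peaks[0]
    row = track.table.loc[track.table["i"] == i].iloc[0]
    return i, float(row["k"])


def benchmark_distances(
    predicted: list[int],
    truths: list[int],
    spectrum_lengths: list[int],
    seed: int = 17,
) -> dict:
    """Ranking-distance summary over a batch of simulated tumors.

    D = predicted - true in ordered-mutation units.  The random baseline
    draws one uniform mutation per simulation; significance of the
    separation between predicted and random absolute distances is a
    two-tailed Welch t test.
    """
    if not (len(predicted) == len(truths) == len(spectrum_lengths)):
        raise ValueError("length mismatch")
    rng = np.random.default_rng(seed)
    d = np.asarray(predicted, dtype=float) - np.asarray(truths, dtype=float)
    rand_pred = rng.integers(1, np.asarray(spectrum_lengths) + 1)
    d_rand = rand_pred - np.asarray(truths, dtype=float)
    n = len(d)

    def med_se(x):
        if len(x) < 2:
            return math.nan
        return 1.2533 * float(np.std(x, ddof=1)) / math.sqrt(len(x))

    out = {
        "n": n,
        "D": d.tolist(),
        "D_random": d_rand.tolist(),
        "median_D": float(np.median(d)),
        "median_abs_D": float(np.median(np.abs(d))),
        "se_median_abs_D": med_se(np.abs(d)),
        "median_D_random": float(np.median(d_rand)),
        "median_abs_D_random": float(np.median(np.abs(d_rand))),
        "p_value": None,
    }
    if n >= 2:
        t = stats.ttest_ind(np.abs(d), np.abs(d_rand), equal_var=False)
        out["p_value"] = float(t.pvalue)
    return out


def classify_predictions(abs_distances: list[float], cutoff: float = 16.0) -> dict:
    """TP/FP/TN/FN bookkeeping under the fixed-distance rule.

    A prediction within ``cutoff`` ordered mutations of the truth is a TP
    (and the simulation, having no FP, contributes a TN); otherwise it is
    an FP (and the missing TP contributes an FN).
    """
    tp = fp = tn = fn = 0
    for ad in abs_distances:
        if ad <= cutoff:
            tp += 1
            tn += 1
        else:
            fp += 1
            fn += 1
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    ppv = tp / (tp + fp) if (tp + fp) else math.nan
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn, "sensitivity": sens, "PPV": ppv}


def tune_window(
    nonneutral: list[tuple[VafSpectrum, int]],
    neutral: list[VafSpectrum],
    candidates: list[int],
    n_tot: float = 1e6,
    scan_limit: int | None = None,
    seed: int = 17,
) -> pd.DataFrame:
    """Window-size selection report.

    For every candidate window the absolute median ranking distance on the
    driver batch and the median peak effect on the neutral batch are
    computed; the returned frame is sorted so the best window (smallest
    absolute median distance, ties broken by neutral median effect closest
    to 1) comes first.
    """
    if not candidates:
        raise ValueError("no candidate window sizes")
    records = []
    for m in candidates:
        preds, truths, lengths = [], [], []
        for spec, true_idx in nonneutral:
            track = sliding_fit(spec, m=m, n_tot=n_tot, scan_limit=scan_limit)
            i, _ = best_peak(track)
            preds.append(i)
            truths.append(true_idx)
            lengths.append(len(spec))
        summary = benchmark_distances(preds, truths, lengths, seed=seed) if preds else None
        neutral_ks = []
        for spec in neutral:
            track = sliding_fit(spec, m=m, n_tot=n_tot, scan_limit=scan_limit)
            _, k = best_peak(track)
            neutral_ks.append(k)
        records.append(
            {
                "m": m,
                "median_abs_D": summary["median_abs_D"] if summary else math.nan,
                "median_neutral_k": float(np.nanmedian(neutral_ks)) if neutral_ks else math.nan,
            }
        )
    df = pd.DataFrame(records)
    df["_neu"] = (df["median_neutral_k"] - 1.0).abs()
    df = df.sort_values(["median_abs_D", "_neu"], na_position="last").drop(columns="_neu")
    return df.reset_index(drop=True)
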