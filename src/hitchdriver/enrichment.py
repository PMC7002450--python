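"""Cohort statistics on growth tracks.

Once every mutation in a cohort carries a growth value r_i and an effect
k_i, mutation categories (a gene, a consequence class, a gene-list) can be
scored for association with periods of positive tumor growth.  The null is
always sample-matched: for each tested mutation an equal number of random
mutations is drawn from the same sample, and the draw is bootstrapped.
Also here: k-means clustering of per-sample growth profiles into the three
canonical patterns (steady, sigmoid, stagnation) and the peak-alignment
test used for candidate drivers in a deeply sequenced sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "EnrichmentResult",
    "GrowthPatternProfile",
    "positive_growth_enrichment",
    "effect_bin_enrichment",
    "cluster_growth_patterns",
    "peak_alignment_significance",
    "DEFAULT_EFFECT_BINS",
]

DEFAULT_EFFECT_BINS = np.arange(0.9, 2.701, 0.2)  # 0.9-1.1, 1.1-1.3, ... 2.5-2.7


@dataclass(frozen=True)
class EnrichmentResult:
    """Positive-growth enrichment of one mutation category.

    x_p        observed category mutations with r > 0
    x_pr_mean  mean matched-random count over B bootstrap replicates
    sem        standard error of the replicate mean
    z          (x_p - x_pr_mean) / bootstrap SD, with SD = sem * sqrt(B)
    pge        (x_p - x_pr_mean) / total category count
    total      category size
    """

    label: str
    x_p: int
    x_pr_mean: float
    sem: float
    z: float
    pge: float
    total: int
    replicates: int


def _sample_matched_draw(
    pool_by_sample: dict[str, np.ndarray],
    counts_by_sample: dict[str, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw, per sample, as many random values as the category has there
    (with replacement), and concatenate."""
    parts = []
    for sample, cnt in counts_by_sample.items():
        pool = pool_by_sample[sample]
        if len(pool) == 0:
            continue
        parts.append(rng.choice(pool, size=cnt, replace=True))
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def positive_growth_enrichment(
    target: pd.DataFrame,
    pools: pd.DataFrame,
    label: str = "target",
    B: int = 100,
    seed: int = 17,
) -> EnrichmentResult:
    """Is a mutation category enriched during periods of positive growth?

    ``target`` and ``pools`` need columns ``sample`` and ``r``; ``pools``
    holds every scored mutation of each sample.  Positive growth means
    r > 0 strictly.  The expectation is built from ``B`` sample-matched
    bootstrap draws of equal size.
    """
    if len(target) == 0:
        raise ValueError("empty target set")
    rng = np.random.default_rng(seed)
    x_p = int((target["r"].to_numpy() > 0).sum())
    total = len(target)
    counts = target.groupby("sample").size().to_dict()
    pool_by_sample = {s: grp["r"].to_numpy() for s, grp in pools.groupby("sample")}
    missing = [s for s in counts if s not in pool_by_sample]
    if missing:
        raise ValueError(f"samples absent from pools: {missing}")
    reps = np.empty(B)
    for b in range(B):
        draw = _sample_matched_draw(pool_by_sample, counts, rng)
        reps[b] = (draw > 0).sum()
    mean = float(reps.mean())
    sd = float(reps.std(ddof=1)) if B > 1 else math.nan
    sem = sd / math.sqrt(B) if B > 1 else math.nan
    z = (x_p - mean) / sd if sd and sd > 0 else math.nan
    pge = (x_p - mean) / total
    return EnrichmentResult(
        label=label, x_p=x_p, x_pr_mean=mean, sem=sem, z=z, pge=pge, total=total, replicates=B
    )


def effect_bin_enrichment(
    target: pd.DataFrame,
    pools: pd.DataFrame,
    bins: np.ndarray | None = None,
    label: str = "target",
    B: int = 100,
    seed: int = 17,
) -> pd.DataFrame:
    """Per-effect-bin enrichment of a category against matched randoms.

    Bins are left-inclusive, right-exclusive on the per-mutation effect
    ``k`` (defaults 0.9-1.1 ... 2.5-2.7).  Empty observed bins report NaN
    z.  Columns: bin_left, bin_right, x, x_rand_mean, sem, z.
    """
    if bins is None:
        bins = DEFAULT_EFFECT_BINS
    bins = np.asarray(bins, dtype=float)
    rng = np.random.default_rng(seed)
    counts = target.groupby("sample").size().to_dict()
    pool_by_sample = {s: grp["k"].to_numpy() for s, grp in pools.groupby("sample")}

    def bin_counts(values: np.ndarray) -> np.ndarray:
        values = values[np.isfinite(values)]
        out, _ = np.histogram(values, bins=bins)
        return out

    obs = bin_counts(target["k"].to_numpy())
    reps = np.empty((B, len(bins) - 1))
    for b in range(B):
        draw = _sample_matched_draw(pool_by_sample, counts, rng)
        reps[b] = bin_counts(draw)
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1)
    sem = sd / math.sqrt(B)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    return pd.DataFrame(
        {
            "label": label,
            "bin_left": bins[:-1],
            "bin_right": bins[1:],
            "x": obs,
            "x_rand_mean": mean,
            "sem": sem,
            "z": z,
        }
    )


@dataclass(frozen=True)
class GrowthPatternProfile:
    """Max-normalized, 20-bin growth profile of one sample with its
    k-means cluster and shape label."""

    sample_id: str
    profile: np.ndarray
    cluster: int
    label: str


def _bin_means(values: np.ndarray, bins: int) -> np.ndarray:
    """Means over ``bins`` equal-count bins of an ordered vector."""
    edges = np.linspace(0, len(values), bins + 1).astype(int)
    return np.array([values[a:b].mean() if b > a else np.nan for a, b in zip(edges, edges[1:])])


def _shape_label(centroid: np.ndarray) -> str:
    """Heuristic naming of a cluster centroid: late collapse toward or
    below zero = stagnation, early rise then late plateau = sigmoid,
    otherwise steady growth."""
    third = max(1, len(centroid) // 3)
    early = float(np.mean(centroid[:third]))
    late = float(np.mean(centroid[-third:]))
    if late < 0.25 * early or late < 0.05:
        return "stagnation"
    if late > 0.6 and (late - early) > 0.15:
        return "sigmoid"
    return "steady"


def cluster_growth_patterns(
    tracks: dict[str, np.ndarray],
    bins: int = 20,
    clusters: int = 3,
    seed: int = 17,
) -> list[GrowthPatternProfile]:
    """Cluster per-sample growth trajectories into growth patterns.

    ``tracks`` maps sample id to its ordered per-mutation growth vector
    r_i.  Each is normalized by the sample's maximum growth, averaged in
    ``bins`` equal-count bins, and the bin profiles are k-means clustered
    (fixed seed, 10 restarts).  Samples are processed in sorted order so
    labels do not depend on dict ordering.
    """
    ids = sorted(tracks)
    profiles = []
    for sid in ids:
        r = np.asarray(tracks[sid], dtype=float)
        r = r[np.isfinite(r)]
        if len(r) < bins:
            raise ValueError(f"track {sid!r} shorter than {bins} mutations")
        mx = np.max(r)
        norm = r / mx if mx > 0 else r
        profiles.append(_bin_means(norm, bins))
    X = np.vstack(profiles)
    if np.allclose(X, X[0]):
        warnings.warn("all profiles identical; clustering is degenerate")
    km = KMeans(n_clusters=clusters, n_init=10, random_state=seed)
    assign = km.fit_predict(X)
    names = [_shape_label(c) for c in km.cluster_centers_]
    return [
        GrowthPatternProfile(sample_id=sid, profile=prof, cluster=int(a), label=names[int(a)])
        for sid, prof, a in zip(ids, profiles, assign)
    ]


def peak_alignment_significance(
    peaks: list[int],
    candidates: list[int],
    mutation_ranks: np.ndarray,
    replicates: int = 1000,
    top_n: int = 5,
    seed: int = 17,
) -> dict:
    """Do candidate mutations align with the sample's top growth peaks?

    The observed statistic is each candidate's distance (in ordered
    mutations) to the nearest of the ``top_n`` highest peaks; the null
    resamples random mutations (with replacement, from
    ``mutation_ranks``) and recomputes the same distances.  A two-tailed
    Welch t test compares observed against the pooled null distances.
    """
    if not peaks:
        raise ValueError("no peaks supplied")
    if not candidates:
        raise ValueError("no candidate mutations supplied")
    use = np.asarray(peaks[:top_n], dtype=float)
    if len(peaks) < top_n:
        warnings.warn(f"only {len(peaks)} peaks available; using all")
    rng = np.random.default_rng(seed)
    cand = np.asarray(candidates, dtype=float)
    obs = np.min(np.abs(cand[:, None] - use[None, :]), axis=1)
    ranks = np.asarray(mutation_ranks, dtype=float)
    null = np.empty((replicates, len(cand)))
    for b in range(replicates):
        draw = rng.choice(ranks, size=len(cand), replace=True)
        null[b] = np.min(np.abs(draw[:, None] - use[None, :]), axis=1)
    t = stats.ttest_ind(obs, null.ravel(), equal_var=False)
    return {
        "observed_distances": obs.tolist(),
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "p_value": float(t.pvalue),
        "n_peaks_used": int(len(use)),
    }
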