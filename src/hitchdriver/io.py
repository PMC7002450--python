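"""Formats, fixtures and end-to-end benchmark orchestration.

The canonical interchange format is a VAF TSV with columns
``id chrom pos ref alt freq`` (optional ``gene`` and ``class``), holding
corrected mutational frequencies (2x VAF, purity/copy-number adjusted
upstream).  VCF 4.x is supported read-only, mapping an INFO allele-
frequency field to frequency with the 2x convention unless the file is
declared precorrected.  Also here: deterministic toy-spectrum builders
used by the tests and docs, and the simulate -> downsample -> fit ->
peak -> score pipeline run over (k x coverage) grids.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import growth, inference, simulate

__all__ = [
    "RunConfig",
    "read_spectrum",
    "write_spectrum",
    "forward_model_spectrum",
    "neutral_spectrum",
    "make_fixtures",
    "benchmark_cell",
    "run_benchmark",
]

SPECTRUM_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "freq"]


@dataclass
class RunConfig:
    """Validated run configuration, echoed into every output artifact."""

    window: int = 150
    mode: str = "offset"
    n_tot: float = 1e6
    r_source: str = "closed_form"
    coverage: list[int] = field(default_factory=lambda: [1000])
    models: list[str] = field(default_factory=lambda: ["bd"])
    k_values: list[float] = field(default_factory=lambda: [2.0])
    replicates: int = 50
    scan_limit: int = 1000
    seed: int = 17
    out_dir: str = "results"

    def validate(self) -> "RunConfig":
        if self.window < 10:
            raise ValueError("window must be >= 10")
        if self.mode not in ("offset", "simple"):
            raise ValueError("mode must be 'offset' or 'simple'")
        if self.r_source not in ("closed_form", "nls"):
            raise ValueError("r_source must be 'closed_form' or 'nls'")
        if any(c <= 0 for c in self.coverage):
            raise ValueError("coverages must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        version = data.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema version {version}")
        return cls(**data).validate()

    def to_yaml(self, path: str | Path) -> None:
        data = {"schema_version": 1, **asdict(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def read_spectrum(
    path: str | Path,
    fmt: str | None = None,
    precorrected: bool = True,
    af_field: str = "AF",
    sample_id: str | None = None,
) -> tuple[inference.VafSpectrum, dict]:
    """Read a mutation table from TSV or VCF and order it.

    Returns the ordered spectrum and a report dict counting rows skipped
    for malformed or out-of-range frequencies.  TSV frequencies are taken
    as already corrected unless ``precorrected=False`` (then doubled);
    VCF allele frequencies are doubled unless ``precorrected=True`` is
    explicitly kept... i.e. the 2x rule applies whenever the input is a
    raw allele fraction.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in "".join(path.suffixes).lower() else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    elif fmt == "vcf":
        df = _read_vcf(path, af_field)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not precorrected:
        df["freq"] = 2.0 * df["freq"]
    n_raw = len(df)
    freq = pd.to_numeric(df["freq"], errors="coerce")
    good = freq.notna() & (freq > 0) & (freq <= 1)
    skipped = int((~good).sum())
    df = df.loc[good].copy()
    df["freq"] = freq[good]
    if len(df) == 0:
        raise ValueError(f"no valid rows in {path} ({skipped} skipped)")
    spectrum = inference.order_spectrum(df, sample_id=sample_id or path.stem)
    return spectrum, {"rows": n_raw, "skipped": skipped}


def _read_vcf(path: Path, af_field: str) -> pd.DataFrame:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("VCF support needs the cyvcf2 extra") from exc
    rows = []
    for var in VCF(str(path)):
        af = var.INFO.get(af_field)
        if af is None:
            continue
        if isinstance(af, (tuple, list)):
            af = af[0]
        alt = var.ALT[0] if var.ALT else "."
        rows.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{alt}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": alt,
                "freq": float(af),
            }
        )
    return pd.DataFrame(rows)


def write_spectrum(spectrum: inference.VafSpectrum, path: str | Path) -> None:
    cols = [c for c in [*SPECTRUM_COLUMNS, "gene", "class", "i"] if c in spectrum.table.columns]
    spectrum.table[cols].to_csv(path, sep="\t", index=False)


def write_track(track: inference.GrowthTrack, path: str | Path) -> None:
    df = track.table.copy()
    df["is_peak"] = df["i"].isin(track.peaks)
    df.to_csv(path, sep="\t", index=False)


def _as_table(freqs: np.ndarray, prefix: str) -> pd.DataFrame:
    n = len(freqs)
    return pd.DataFrame(
        {
            "id": [f"{prefix}{i}" for i in range(n)],
            "chrom": "toy",
            "pos": np.arange(n),
            "ref": "A",
            "alt": "T",
            "freq": freqs,
        }
    )


def neutral_spectrum(
    length: int = 300, r: float = 0.02, noise_sd: float = 0.0, seed: int = 17
) -> pd.DataFrame:
    """Pure neutral exponential spectrum f_i = exp(-r i), optional
    multiplicative log-normal noise."""
    i = np.arange(1, length + 1, dtype=float)
    f = np.exp(-r * i)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f * np.exp(rng.normal(0.0, noise_sd, size=length)), 1e-9, 1.0)
    return _as_table(f, "n")


def forward_model_spectrum(
    drivers: list[tuple[float, float]],
    r: float = 0.02,
    n_tot: float = 1e6,
    tail: int = 150,
    tail_floor_ratio: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 17,
) -> tuple[pd.DataFrame, list[int]]:
    """Noise-free (optionally jittered) spectrum of a multi-driver tumor.

    ``drivers`` is a list of (f_d, k) with decreasing f_d.  Each segment
    decays exponentially from the previous driver's frequency toward the
    plateau implied by (f_d, k); the segment ends where it reaches f_d,
    which is where that driver sits.  After the last driver a plain
    exponential tail of ``tail`` mutations is appended.  Returns the
    mutation table and the 1-based ranks of the drivers.
    """
    freqs: list[float] = []
    driver_ranks: list[int] = []
    f_start = 1.0
    for f_d, k in drivers:
        if not (0 < f_d < f_start):
            raise ValueError("driver frequencies must decrease and stay in (0,1)")
        alpha = growth.asymptote_from_effect(k, f_d, n_tot)
        if alpha >= f_d:
            raise ValueError("degenerate plateau; increase n_tot or lower k")
        length = int(math.ceil(math.log((f_start - alpha) / (f_d - alpha)) / r))
        j = np.arange(1, length + 1, dtype=float)
        seg = (f_start - alpha) * np.exp(-r * j) + alpha
        seg = np.maximum(seg, f_d)
        freqs.extend(seg.tolist())
        driver_ranks.append(len(freqs))
        f_start = f_d
    floor = f_start * tail_floor_ratio
    decay = math.log(f_start / floor) / max(tail, 1)
    j = np.arange(1, tail + 1, dtype=float)
    freqs.extend((f_start * np.exp(-decay * j)).tolist())
    f = np.asarray(freqs)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f * np.exp(rng.normal(0.0, noise_sd, size=len(f))), 1e-9, 1.0)
    # enforce the descending order the builder already implies up to noise
    order = np.argsort(-f, kind="mergesort")
    f = f[order]
    ranks = [int(np.nonzero(order == dr - 1)[0][0]) + 1 for dr in driver_ranks]
    return _as_table(f, "f"), ranks


def make_fixtures(out_dir: str | Path, seed: int = 17) -> dict[str, Path]:
    """Write the deterministic toy datasets used by tests and docs.

    (a) a pure neutral spectrum, (b) a single-driver forward-model
    spectrum, (c) a three-driver forward-model spectrum, (d) a small
    birth-death simulation with its truth JSON.  Same seed, same bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    neutral = neutral_spectrum(length=400, r=0.015, seed=seed)
    paths["neutral"] = out / "neutral.tsv"
    neutral.to_csv(paths["neutral"], sep="\t", index=False)

    single, ranks1 = forward_model_spectrum([(0.3, 2.0)], r=0.02, tail=200, seed=seed)
    paths["single_driver"] = out / "single_driver.tsv"
    single.to_csv(paths["single_driver"], sep="\t", index=False)
    (out / "single_driver.truth.json").write_text(
        json.dumps({"driver_ranks": ranks1, "k": [2.0], "f_d": [0.3], "seed": seed})
    )

    multi, ranks3 = forward_model_spectrum(
        [(0.55, 1.8), (0.3, 2.5), (0.12, 2.0)], r=0.02, tail=200, seed=seed
    )
    paths["three_driver"] = out / "three_driver.tsv"
    multi.to_csv(paths["three_driver"], sep="\t", index=False)
    (out / "three_driver.truth.json").write_text(
        json.dumps({"driver_ranks": ranks3, "k": [1.8, 2.5, 2.0], "seed": seed})
    )

    cfg = simulate.SimConfig(trigger_population=50, stop_prevalence=0.3, death=0.5)
    tumor = simulate.simulate_birth_death(cfg, seed=seed)
    spec_df = tumor.spectrum()
    paths["bd_sample"] = out / "bd_sample.tsv"
    spec_df.head(200).to_csv(paths["bd_sample"], sep="\t", index=False)
    (out / "bd_sample.truth.json").write_text(
        json.dumps(
            {
                "driver_id": f"m{tumor.driver_id}",
                "true_k": tumor.true_k,
                "n_final": tumor.n_final,
                "seed": seed,
                "attempts": tumor.attempts,
            }
        )
    )
    return paths


def benchmark_cell(
    k: float,
    coverage: int,
    n_rep: int,
    seed: int,
    window: int = 150,
    scan_limit: int = 400,
    config: simulate.SimConfig | None = None,
    tumors: list[simulate.SimulatedTumor] | None = None,
    smooth: int | None = None,
    min_window: int = 3,
) -> dict:
    """Simulate (or reuse) a batch of driver tumors and score the pipeline.

    Per replicate: grow a birth-death tumor with driver effect ``k``,
    downsample its spectrum to ``coverage``, scan it with first-driver
    windows (simple mode, truncated at the spectrum head, the tumor's own
    final cell count as N_tot) and record the best effect peak.  Samples
    whose spectrum the pinned-amplitude model cannot represent (no
    defined effect anywhere) are rescanned with the free-amplitude
    offset model.  Returns per-replicate arrays plus the
    ranking-distance summary.
    """
    cfg = config or simulate.SimConfig(k=k)
    if tumors is None:
        tumors = [simulate.simulate_birth_death(cfg, seed=seed + 1000 * rep) for rep in range(n_rep)]
    k_hats, preds, truths, lengths = [], [], [], []
    for rep, tumor in enumerate(tumors):
        rng = np.random.default_rng(seed + 7919 * rep + coverage)
        df = tumor.spectrum(coverage=coverage, rng=rng)
        spec = inference.order_spectrum(df, sample_id=f"sim{rep}")
        if len(spec) < min_window + 2:
            continue
        try:
            true_rank = spec.rank_of(f"m{tumor.driver_id}")
        except KeyError:
            continue  # driver lost in downsampling
        fit_kw = dict(
            m=window,
            n_tot=float(tumor.n_final),
            scan_limit=scan_limit,
            min_window=min_window,
            r_source="nls",
            resolution=1.0 / coverage,
        )
        track = inference.sliding_fit(spec, mode="simple", **fit_kw)
        if not np.isfinite(track.effect_signal).any():
            track = inference.sliding_fit(spec, mode="offset", **fit_kw)
        try:
            pred, k_hat = inference.best_peak(track, smooth=smooth)
        except ValueError:
            continue
        k_hats.append(k_hat)
        preds.append(pred)
        truths.append(true_rank)
        lengths.append(len(spec))
    summary = inference.benchmark_distances(preds, truths, lengths, seed=seed)
    finite_k = [v for v in k_hats if np.isfinite(v)]
    summary.update(
        {
            "k_true": k,
            "coverage": coverage,
            "median_k_hat": float(np.median(finite_k)) if finite_k else math.nan,
            "k_hats": k_hats,
            "predicted": preds,
            "truths": truths,
            "classification": inference.classify_predictions(
                np.abs(np.asarray(preds) - np.asarray(truths)).tolist()
            ),
            "tumors": tumors,
        }
    )
    return summary


def neutral_window_calibration(
    n_sims: int = 50,
    window: int = 150,
    seed: int = 17,
    scan_limit: int = 1000,
) -> dict:
    """Median window effect on neutral stochastic-mutation-rate tumors.

    Generates ``n_sims`` neutral (s = 0) simulations with Poisson(10)
    mutations per division grown to 10,000 cells, runs the deep sliding
    scan at the given window, and reports the median per-window effect of
    each simulation plus the batch median — the quantity the window size
    is calibrated against (1 at the calibrated window).
    """
    per_sim = []
    for rep in range(n_sims):
        tumor = simulate.simulate_stochastic_mu(s=0.0, seed=seed + 101 * rep)
        rng = np.random.default_rng(seed + 577 * rep)
        spec = inference.order_spectrum(
            tumor.spectrum(coverage=1000, rng=rng), sample_id=f"neutral{rep}"
        )
        track = inference.sliding_fit(
            spec, m=window, n_tot=float(tumor.n_final),
            scan_limit=scan_limit, resolution=1e-3,
        )
        per_sim.append(float(np.nanmedian(track.table["k"].to_numpy())))
    return {
        "window": window,
        "n": len(per_sim),
        "per_sim_median_k": per_sim,
        "median_k": float(np.nanmedian(per_sim)),
    }


def effect_selection_correlation(
    n_neutral: int = 40,
    n_nonneutral: int = 60,
    seed: int = 17,
    n_sim_cells: int = 10_000,
    n_projected: float = 1e6,
    window: int = 150,
    scan_limit: int = 1000,
) -> dict:
    """Correlation between simulated selection and predicted effect.

    Stochastic-mutation-rate tumors with selection coefficients s drawn
    log-uniformly over [0.5, 32] (driver introduction size drawn
    log-uniformly over [30, 3000] so final driver VAFs spread across the
    spectrum) are pooled with neutral tumors; each simulation contributes
    its highest-peak effect estimate.  Both the simulated coefficient
    (1 + s) and the prediction are projected onto ``n_projected`` cells
    by conserving N(k-1), and the Pearson correlation is reported.
    """
    rng0 = np.random.default_rng(seed)
    xs, ys, cats = [], [], []

    def run_one(s: float, trig: int | None, tag: str, rep: int):
        tumor = simulate.simulate_stochastic_mu(
            s=s, seed=seed + 211 * rep + (0 if s == 0 else 7), n_cells=n_sim_cells,
            trigger_population=trig,
        )
        rng = np.random.default_rng(seed + 613 * rep + int(s * 100))
        spec = inference.order_spectrum(
            tumor.spectrum(coverage=1000, rng=rng), sample_id=f"{tag}{rep}"
        )
        track = inference.sliding_fit(
            spec, m=window, n_tot=float(tumor.n_final),
            scan_limit=scan_limit, resolution=1e-3,
        )
        try:
            _, k_hat = inference.best_peak(track)
        except ValueError:
            return
        if not np.isfinite(k_hat):
            return
        xs.append(float(growth.scale_effect(1.0 + s, n_sim_cells, n_projected)))
        ys.append(float(growth.scale_effect(k_hat, n_sim_cells, n_projected)))
        f_d = tumor.driver_frequency or 0.0
        vaf = f_d / 2.0
        cats.append(
            "neutral" if s == 0 else
            "small" if 0.1 <= vaf < 0.2 else
            "medium" if 0.2 <= vaf < 0.3 else
            "large" if 0.3 <= vaf < 0.4 else "other"
        )

    for rep in range(n_nonneutral):
        s = float(np.exp(rng0.uniform(np.log(0.5), np.log(32.0))))
        trig = int(np.exp(rng0.uniform(np.log(30.0), np.log(3000.0))))
        run_one(s, trig, "sel", rep)
    for rep in range(n_neutral):
        run_one(0.0, None, "neu", 10_000 + rep)

    from scipy import stats as _st

    r = float(_st.pearsonr(xs, ys).statistic) if len(xs) > 2 else math.nan
    return {"n": len(xs), "pearson_r": r, "s_star": xs, "k_star": ys, "vaf_category": cats}


def run_benchmark(config: RunConfig) -> pd.DataFrame:
    """Grid benchmark over (model is birth-death) x k x coverage.

    Emits one row per cell with the Fig-style statistics: median absolute
    ranking distance, its SE, the random baseline, the two-tailed t-test
    p-value and the median predicted effect.
    """
    config.validate()
    rows = []
    for k in config.k_values:
        tumors = None
        for cov in config.coverage:
            cell = benchmark_cell(
                k=k,
                coverage=cov,
                n_rep=config.replicates,
                seed=config.seed,
                window=config.window,
                scan_limit=config.scan_limit,
                tumors=tumors,
            )
            tumors = cell["tumors"]  # reuse the same tumors across coverages
            rows.append(
                {
                    "k_true": k,
                    "coverage": cov,
                    "n": cell["n"],
                    "median_abs_D": cell["median_abs_D"],
                    "se_median_abs_D": cell["se_median_abs_D"],
                    "median_abs_D_random": cell["median_abs_D_random"],
                    "p_value": cell["p_value"],
                    "median_k_hat": cell["median_k_hat"],
                    "sensitivity": cell["classification"]["sensitivity"],
                    "PPV": cell["classification"]["PPV"],
                    "config_digest": config.digest(),
                }
            )
    return pd.DataFrame(rows)
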