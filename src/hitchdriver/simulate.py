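"""Ground-truth tumor simulators.

Stochastic birth-death (optionally logistic) Gillespie growth of a single
transformed cell, with an injected driver mutation that multiplies its
subclone's birth rate by a scalar ``k``; an exponential variant with a
division lag; a stochastic-mutation-rate variant (Poisson-distributed
mutation counts per division, mean 10, grown to a fixed population); and
binomial coverage downsampling of the resulting frequency spectra.

Every division hands the daughter cell ``mu`` brand-new mutations under the
infinite-sites model, recorded as nodes of a lineage tree (each node's
parent is the mother's most recent mutation), so final carrier counts are
subtree sizes and memory stays linear in the number of mutations even at
ten mutations per division.

Default rates are supercritical (birth 1.0, death 0.1) with the driver
triggered once the population reaches 100 cells: the driver then sits
within the first ~dozen ordered mutations, its ancestral hitchhikers form
the head of the frequency spectrum, and the first-driver (head-anchored)
window scan of the inference module applies.
"""

from __future__ import annotations

import heapq
import math
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimulatedTumor",
    "simulate_birth_death",
    "simulate_lagged_exponential",
    "simulate_stochastic_mu",
    "downsample_coverage",
]

_TRAJ_STRIDE = 256  # record population trajectory every this many events


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated tumor.

    The run starts from one unmutated cell.  The first new mutation after
    the population reaches ``trigger_population`` (or, if ``trigger_time``
    is set, after that simulation time) becomes the driver and multiplies
    its carriers' birth rate by ``k``.  The simulation ends randomly once
    the driver subclone reaches ``stop_prevalence``: a geometric number of
    further events with mean ``overshoot_fraction * N`` is drawn and then
    the run stops.  ``stop_population`` instead stops the run at a fixed
    cell count (used by the stochastic-mutation-rate protocol, where no
    prevalence rule applies).
    """

    birth: float = 1.0
    death: float = 0.1
    carrying_capacity: float | None = None
    k: float = 2.0
    trigger_population: int | None = 100
    trigger_time: float | None = None
    stop_prevalence: float = 0.25
    overshoot_fraction: float = 0.05
    mu: float = 1.0
    stochastic_mu: bool = False
    stop_population: int | None = None
    max_population: int = 5_000_000
    max_events: int = 200_000_000
    division_lag: float = 0.0
    max_attempts: int = 5000

    def __post_init__(self) -> None:
        if self.birth <= 0 or self.death < 0:
            raise ValueError("need birth > 0 and death >= 0")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if not (0.0 < self.stop_prevalence < 1.0):
            raise ValueError("stop_prevalence must lie in (0, 1)")
        if self.mu <= 0:
            raise ValueError("mu must be positive")


@dataclass
class SimulatedTumor:
    """Ground truth for one simulated tumor.

    ``carriers[i]`` is the final number of cells carrying mutation ``i``;
    mutation ids are assigned in occurrence order.  ``parents[i]`` is the
    id of the mutation the mother cell most recently acquired (-1 at the
    root), so carrier sets are nested along lineages.
    """

    carriers: np.ndarray
    parents: np.ndarray
    n_final: int
    driver_id: int | None
    true_k: float
    config: SimConfig
    seed: int
    attempts: int
    trajectory_t: np.ndarray
    trajectory_n: np.ndarray
    trajectory_driver: np.ndarray
    final_genotypes: np.ndarray | None = None  # most recent mutation per final cell

    @property
    def frequencies(self) -> np.ndarray:
        """Final frequency (carrier fraction) of every mutation ever born."""
        return self.carriers / float(self.n_final)

    @property
    def driver_frequency(self) -> float | None:
        if self.driver_id is None:
            return None
        return float(self.carriers[self.driver_id]) / self.n_final

    def hitchhiker_ids(self) -> np.ndarray:
        """Ids of the driver's ancestral mutations (its g-hitchhikers)."""
        if self.driver_id is None:
            return np.empty(0, dtype=np.int64)
        out = []
        node = int(self.parents[self.driver_id])
        while node >= 0:
            out.append(node)
            node = int(self.parents[node])
        return np.asarray(out[::-1], dtype=np.int64)

    def spectrum(self, coverage: int | None = None, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """Mutation table (id, chrom, pos, ref, alt, freq) of surviving
        mutations, optionally downsampled to a simulated coverage depth.

        ``pos`` is the mutation id, so frequency ties order by occurrence.
        """
        freq = self.frequencies
        ids = np.nonzero(self.carriers)[0]
        freq = freq[ids]
        if coverage is not None:
            if rng is None:
                raise ValueError("coverage downsampling needs an rng")
            freq = downsample_coverage(freq, coverage, rng, drop_zero=False)
            keep = freq > 0
            ids, freq = ids[keep], freq[keep]
        return pd.DataFrame(
            {
                "id": [f"m{i}" for i in ids],
                "chrom": "sim",
                "pos": ids,
                "ref": "A",
                "alt": "T",
                "freq": freq,
            }
        )


def _poisson(rng: random.Random, mean: float) -> int:
    """Knuth Poisson draw (fine for the small means used here)."""
    limit = math.exp(-mean)
    prod = rng.random()
    n = 0
    while prod > limit:
        prod *= rng.random()
        n += 1
    return n


def _run_gillespie(cfg: SimConfig, rng: random.Random):
    """One attempt; returns None on extinction before completion."""
    b, d, kk = cfg.birth, cfg.death, cfg.k
    cap = cfg.carrying_capacity
    parents: list[int] = []
    wild: list[int] = [-1]  # founder carries no mutations
    drv: list[int] = []
    driver_id: int | None = None
    want_driver = cfg.trigger_population is not None or cfg.trigger_time is not None
    countdown = -1  # events remaining after the stop rule fires; -1 = not armed
    t = 0.0
    traj_t, traj_n, traj_d = [0.0], [1], [0]
    events = 0

    while events < cfg.max_events:
        nw, nd = len(wild), len(drv)
        n = nw + nd
        if n == 0:
            return None
        death = d if cap is None else d + (b - d) * n / cap
        bw = b * nw
        bf = kk * b * nd
        dw = death * nw
        df = death * nd
        tot = bw + bf + dw + df
        t += rng.expovariate(tot)
        u = rng.random() * tot
        events += 1
        if u < bw + bf:
            # division; daughter inherits the mother's genotype plus mu new mutations
            if u < bw:
                mother = wild[int(rng.random() * nw)]
            else:
                mother = drv[int(rng.random() * nd)]
            nmut = _poisson(rng, cfg.mu) if cfg.stochastic_mu else int(cfg.mu)
            g = mother
            first_new = -1
            for _ in range(nmut):
                parents.append(g)
                g = len(parents) - 1
                if first_new < 0:
                    first_new = g
            triggered = (
                want_driver
                and driver_id is None
                and first_new >= 0
                and (
                    (cfg.trigger_time is not None and t >= cfg.trigger_time)
                    or (cfg.trigger_population is not None and n + 1 >= cfg.trigger_population)
                )
            )
            if triggered:
                driver_id = first_new
                drv.append(g)
            elif u >= bw:
                drv.append(g)
            else:
                wild.append(g)
        else:
            if u < bw + bf + dw:
                idx = int(rng.random() * nw)
                wild[idx] = wild[-1]
                wild.pop()
            else:
                idx = int(rng.random() * nd)
                drv[idx] = drv[-1]
                drv.pop()
                if not drv and countdown < 0:
                    # driver clone lost before the stop rule fired: the
                    # attempt is void and is resimulated afresh
                    return None
        if events % _TRAJ_STRIDE == 0:
            traj_t.append(t)
            traj_n.append(len(wild) + len(drv))
            traj_d.append(len(drv))
        n = len(wild) + len(drv)
        if cfg.stop_population is not None:
            if n >= cfg.stop_population:
                break
        elif want_driver:
            if countdown < 0 and drv and len(drv) >= cfg.stop_prevalence * n:
                mean_extra = cfg.overshoot_fraction * n
                p = 1.0 / (1.0 + mean_extra)
                countdown = int(math.log(1.0 - rng.random()) / math.log(1.0 - p)) if p < 1.0 else 0
            elif countdown > 0:
                countdown -= 1
            if countdown == 0:
                break
        if n >= cfg.max_population:
            break

    if want_driver and driver_id is None:
        return None
    n_final = len(wild) + len(drv)
    if n_final == 0:
        return None
    n_mut = len(parents)
    counts = np.zeros(n_mut, dtype=np.int64)
    for g in wild:
        if g >= 0:
            counts[g] += 1
    for g in drv:
        if g >= 0:
            counts[g] += 1
    par = np.asarray(parents, dtype=np.int64)
    for i in range(n_mut - 1, -1, -1):
        p = par[i]
        if p >= 0:
            counts[p] += counts[i]
    traj_t.append(t)
    traj_n.append(n_final)
    traj_d.append(len(drv))
    genotypes = np.asarray(wild + drv, dtype=np.int64)
    return counts, par, n_final, driver_id, traj_t, traj_n, traj_d, genotypes


def simulate_birth_death(config: SimConfig, seed: int) -> SimulatedTumor:
    """Grow one tumor under the (exponential or logistic) birth-death model.

    Attempts ending in extinction of the whole population, or finishing
    without a driver where one was requested, are retried with a fresh
    random stream; the attempt count is reported on the result.
    """
    for attempt in range(1, config.max_attempts + 1):
        rng = random.Random(f"{seed}:{attempt}")
        out = _run_gillespie(config, rng)
        if out is not None:
            counts, par, n_final, driver_id, tt, tn, td, genotypes = out
            return SimulatedTumor(
                carriers=counts,
                parents=par,
                n_final=n_final,
                driver_id=driver_id,
                true_k=config.k if driver_id is not None else 1.0,
                config=config,
                seed=seed,
                attempts=attempt,
                trajectory_t=np.asarray(tt),
                trajectory_n=np.asarray(tn, dtype=np.int64),
                trajectory_driver=np.asarray(td, dtype=np.int64),
                final_genotypes=genotypes,
            )
    raise RuntimeError(f"no surviving tumor in {config.max_attempts} attempts (seed {seed})")


def simulate_stochastic_mu(
    s: float,
    seed: int,
    mu_mean: float = 10.0,
    n_cells: int = 10_000,
    birth: float = math.log(2),
    death: float = 0.0,
    trigger_population: int | None = 300,
) -> SimulatedTumor:
    """Stochastic-mutation-rate protocol: Poisson(``mu_mean``) mutations per
    division, growth to a fixed population of ``n_cells``.

    ``s`` is the driver's selection coefficient in the source model's
    convention, i.e. the driver multiplies the birth rate by k = 1 + s;
    ``s = 0`` yields a neutral tumor (no driver is injected at all so the
    spectrum is exactly neutral).
    """
    cfg = SimConfig(
        birth=birth,
        death=death,
        k=1.0 + s,
        trigger_population=trigger_population if s > 0 else None,
        stop_population=n_cells,
        mu=mu_mean,
        stochastic_mu=True,
    )
    tumor = simulate_birth_death(cfg, seed)
    return tumor


def simulate_lagged_exponential(config: SimConfig, seed: int) -> SimulatedTumor:
    """Exponential growth in which a freshly divided cell cannot redivide
    for ``config.division_lag`` time units.

    With lag 0 this reduces to the exponential Gillespie model (up to the
    event-scheduling implementation).  Cells are tracked individually with
    a release heap, so this engine is slower than the flat birth-death one
    and is intended for moderate population sizes.
    """
    lag = config.division_lag
    for attempt in range(1, config.max_attempts + 1):
        rng = random.Random(f"{seed}:lag:{attempt}")
        out = _run_lagged(config, rng, lag)
        if out is not None:
            counts, par, n_final, driver_id, tt, tn, td = out
            return SimulatedTumor(
                carriers=counts,
                parents=par,
                n_final=n_final,
                driver_id=driver_id,
                true_k=config.k if driver_id is not None else 1.0,
                config=config,
                seed=seed,
                attempts=attempt,
                trajectory_t=np.asarray(tt),
                trajectory_n=np.asarray(tn, dtype=np.int64),
                trajectory_driver=np.asarray(td, dtype=np.int64),
            )
    raise RuntimeError(f"no surviving tumor in {config.max_attempts} attempts (seed {seed})")


def _run_lagged(cfg: SimConfig, rng: random.Random, lag: float):
    b, d, kk = cfg.birth, cfg.death, cfg.k
    parents: list[int] = []
    # eligible / refractory pools per type; cells are genotype ids
    pools = {("w", True): [-1], ("w", False): [], ("d", True): [], ("d", False): []}
    releases: list[tuple[float, str, int]] = []  # (time, type, genotype)
    driver_id: int | None = None
    want_driver = cfg.trigger_population is not None or cfg.trigger_time is not None
    countdown = -1
    t = 0.0
    traj_t, traj_n, traj_d = [0.0], [1], [0]
    events = 0
    while events < cfg.max_events:
        while releases and releases[0][0] <= t:
            _, typ, g = heapq.heappop(releases)
            pool = pools[(typ, False)]
            pool.remove(g)
            pools[(typ, True)].append(g)
        nw = len(pools[("w", True)]) + len(pools[("w", False)])
        nd = len(pools[("d", True)]) + len(pools[("d", False)])
        n = nw + nd
        if n == 0:
            return None
        bw = b * len(pools[("w", True)])
        bf = kk * b * len(pools[("d", True)])
        dw = d * nw
        df = d * nd
        tot = bw + bf + dw + df
        if tot == 0.0:
            t = releases[0][0]
            continue
        dt = rng.expovariate(tot)
        if releases and t + dt > releases[0][0]:
            t = releases[0][0]
            continue
        t += dt
        events += 1
        u = rng.random() * tot
        if u < bw + bf:
            typ = "w" if u < bw else "d"
            pool = pools[(typ, True)]
            idx = int(rng.random() * len(pool))
            mother = pool.pop(idx)
            nmut = _poisson(rng, cfg.mu) if cfg.stochastic_mu else int(cfg.mu)
            g = mother
            first_new = -1
            for _ in range(nmut):
                parents.append(g)
                g = len(parents) - 1
                if first_new < 0:
                    first_new = g
            triggered = (
                want_driver
                and driver_id is None
                and first_new >= 0
                and (
                    (cfg.trigger_time is not None and t >= cfg.trigger_time)
                    or (cfg.trigger_population is not None and n + 1 >= cfg.trigger_population)
                )
            )
            dtyp = "d" if (triggered or typ == "d") else "w"
            if triggered:
                driver_id = first_new
            if lag > 0:
                pools[(typ, False)].append(mother)
                heapq.heappush(releases, (t + lag, typ, mother))
                pools[(dtyp, False)].append(g)
                heapq.heappush(releases, (t + lag, dtyp, g))
            else:
                pools[(typ, True)].append(mother)
                pools[(dtyp, True)].append(g)
        else:
            typ = "w" if u < bw + bf + dw else "d"
            n_elig = len(pools[(typ, True)])
            n_typ = n_elig + len(pools[(typ, False)])
            idx = int(rng.random() * n_typ)
            if idx < n_elig:
                pool = pools[(typ, True)]
                pool[idx] = pool[-1]
                pool.pop()
            else:
                pool = pools[(typ, False)]
                g = pool[idx - n_elig]
                pool.remove(g)
                for j, (rt, rtyp, rg) in enumerate(releases):
                    if rtyp == typ and rg == g:
                        releases[j] = releases[-1]
                        releases.pop()
                        heapq.heapify(releases)
                        break
            if (
                typ == "d"
                and driver_id is not None
                and not (pools[("d", True)] or pools[("d", False)])
                and countdown < 0
            ):
                return None  # driver clone lost: resimulate the attempt
        if events % _TRAJ_STRIDE == 0:
            traj_t.append(t)
            traj_n.append(
                sum(len(pools[key]) for key in pools)
            )
            traj_d.append(len(pools[("d", True)]) + len(pools[("d", False)]))
        nw = len(pools[("w", True)]) + len(pools[("w", False)])
        nd = len(pools[("d", True)]) + len(pools[("d", False)])
        n = nw + nd
        if cfg.stop_population is not None:
            if n >= cfg.stop_population:
                break
        elif want_driver:
            if countdown < 0 and nd and nd >= cfg.stop_prevalence * n:
                mean_extra = cfg.overshoot_fraction * n
                p = 1.0 / (1.0 + mean_extra)
                countdown = int(math.log(1.0 - rng.random()) / math.log(1.0 - p)) if p < 1.0 else 0
            elif countdown > 0:
                countdown -= 1
            if countdown == 0:
                break
        if n >= cfg.max_population:
            break
    if want_driver and driver_id is None:
        return None
    cells = [g for key in pools for g in pools[key]]
    n_final = len(cells)
    if n_final == 0:
        return None
    n_mut = len(parents)
    counts = np.zeros(n_mut, dtype=np.int64)
    for g in cells:
        if g >= 0:
            counts[g] += 1
    par = np.asarray(parents, dtype=np.int64)
    for i in range(n_mut - 1, -1, -1):
        p = par[i]
        if p >= 0:
            counts[p] += counts[i]
    traj_t.append(t)
    traj_n.append(n_final)
    traj_d.append(len(pools[("d", True)]) + len(pools[("d", False)]))
    return counts, par, n_final, driver_id, traj_t, traj_n, traj_d


def downsample_coverage(
    frequencies: np.ndarray,
    coverage: int,
    rng: np.random.Generator,
    drop_zero: bool = True,
) -> np.ndarray:
    """Resample a frequency spectrum at a simulated sequencing depth.

    Each mutation's frequency is first quantized to a 1000-cell binary
    carrier representation (a frequency of 0.475 means 475 carriers out
    of 1000).  Coverage 1000 is that base representation itself; lower
    coverages draw ``coverage`` carriers from it with replacement, and
    the downsampled frequency is the carrier fraction of the draw.
    Mutations with zero carriers are dropped (or kept at frequency 0 when
    ``drop_zero=False`` so the caller can align with other arrays).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    freq = np.asarray(frequencies, dtype=float)
    base = np.clip(np.round(freq * 1000.0) / 1000.0, 0.0, 1.0)
    if coverage >= 1000:
        drawn = base
    else:
        drawn = rng.binomial(coverage, base) / float(coverage)
    if drop_zero:
        return drawn[drawn > 0]
    return drawn
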