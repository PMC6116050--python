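"""Replication-fork scheduling on a circular chromosome.

For one *cell class* (a set of origins firing synchronously at t=0, with
the fork trap on or off) every chromosomal bin receives the arrival time of
the first replication fork to reach it.  Two independent implementations
are provided: an analytic piecewise-linear schedule (`replication_schedule`)
and a time-stepped discrete-event simulator (`simulate_schedule_events`)
used as its oracle.  Schedules convert to population marker-frequency
profiles via exponential-age weighting, and class profiles combine linearly
into population mixtures.

Conventions: forks launch from the centre of the bin containing their
origin; a fork reaching a ter site whose polarity matches its travel
direction halts there (hard stop) and waits; the bins beyond the block are
replicated by the converging fork.  Ties in arrival time go to the
clockwise fork.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_model import (
    ChromosomeMap,
    bin_index,
    bin_mids,
    bin_widths,
    n_bins,
)

__all__ = [
    "CellClass",
    "SimulationParams",
    "ReplicationSchedule",
    "MarkerFrequencyProfile",
    "replication_schedule",
    "simulate_schedule_events",
    "sample_leaked_ters",
    "marker_frequency",
    "class_profile",
    "mixture_profile",
]


@dataclass(frozen=True)
class CellClass:
    """A subpopulation: which origins fire, and whether Tus trapping acts."""

    active_origins: frozenset[str]
    tus_active: bool = True
    label: str = ""

    def __init__(self, active_origins, tus_active: bool = True, label: str = ""):
        origins = frozenset(active_origins)
        if not origins:
            raise ValueError("a cell class needs at least one active origin")
        object.__setattr__(self, "active_origins", origins)
        object.__setattr__(self, "tus_active", bool(tus_active))
        object.__setattr__(
            self,
            "label",
            label or "+".join(sorted(origins)) + ("" if tus_active else " dtus"),
        )


@dataclass(frozen=True)
class SimulationParams:
    """Fork kinetics.

    fork_speed          nt/s, constant once a fork is established
    tau_min             minutes; inter-initiation period of the population
    headon_speed_factor multiplier on fork speed inside a highly
                        transcribed feature traversed against its
                        transcription direction
    ter_leakage         probability that a blocking ter site is passed
                        (sampled per site via `sample_leaked_ters`)
    """

    fork_speed: float = 1000.0
    tau_min: float = 25.0
    headon_speed_factor: float = 1.0
    ter_leakage: float = 0.0

    def __post_init__(self) -> None:
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be positive")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive")
        if not 0 < self.headon_speed_factor <= 1:
            raise ValueError("headon_speed_factor must be in (0, 1]")
        if not 0 <= self.ter_leakage < 1:
            raise ValueError("ter_leakage must be in [0, 1)")

    @property
    def tau_s(self) -> float:
        return self.tau_min * 60.0


@dataclass
class BlockEvent:
    ter_name: str
    fork: str
    time_s: float


@dataclass
class FusionEvent:
    position_bp: float
    time_s: float


@dataclass
class ReplicationSchedule:
    """Per-bin first-arrival times for one cell class."""

    length_bp: int
    bin_size: int
    t: np.ndarray                 # seconds, shape (n_bins,)
    fork_id: np.ndarray           # int index into fork_labels
    fork_labels: list[str]
    block_events: list[BlockEvent] = field(default_factory=list)
    fusion_events: list[FusionEvent] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.t.shape[0]

    def fork_name(self, i: int) -> str:
        return self.fork_labels[self.fork_id[i]]


@dataclass
class MarkerFrequencyProfile:
    """Per-bin relative copy number, model- or data-derived.

    ``values`` holds NaN at masked (invalid) bins; ``mask`` is True where a
    bin carries a usable value.
    """

    length_bp: int
    bin_size: int
    values: np.ndarray
    mask: np.ndarray | None = None
    source: str = "model"
    normalisation: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            mask = np.isfinite(self.values)
        else:
            mask = np.asarray(self.mask, dtype=bool)
        self.mask = mask
        expected = n_bins(self.length_bp, self.bin_size)
        if self.values.shape != (expected,) or self.mask.shape != (expected,):
            raise ValueError(
                f"profile needs {expected} bins, got {self.values.shape[0]}"
            )
        if np.any(self.values[self.mask] <= 0):
            raise ValueError("profile values must be strictly positive")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_mids(self) -> np.ndarray:
        return bin_mids(self.length_bp, self.bin_size)

    def same_binning(self, other: "MarkerFrequencyProfile") -> bool:
        return self.length_bp == other.length_bp and self.bin_size == other.bin_size


# ---------------------------------------------------------------------------
# shared geometry


def _speed_factors(
    cmap: ChromosomeMap, bin_size: int, params: SimulationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin speed multipliers for cw- and ccw-travelling forks."""
    n = n_bins(cmap.length_bp, bin_size)
    f_cw = np.ones(n)
    f_ccw = np.ones(n)
    if params.headon_speed_factor == 1.0:
        return f_cw, f_ccw
    for feat in cmap.transcribed_features:
        if not feat.highly_transcribed:
            continue
        lo = feat.start_bp // bin_size
        hi = min((feat.end_bp - 1) // bin_size, n - 1)
        sl = slice(lo, hi + 1)
        if feat.direction == "ccw":   # head-on for cw forks
            f_cw[sl] = params.headon_speed_factor
        else:                         # head-on for ccw forks
            f_ccw[sl] = params.headon_speed_factor
    return f_cw, f_ccw


def _resolve_forks(
    cmap: ChromosomeMap, cell_class: CellClass
) -> list[tuple[str, int, int]]:
    """(label, origin position, direction sign); cw forks listed first so
    first-wins tie-breaking prefers them."""
    known = {o.name for o in cmap.origins}
    missing = cell_class.active_origins - known
    if missing:
        raise KeyError(f"cell class references unknown origins: {sorted(missing)}")
    names = sorted(cell_class.active_origins)
    forks = [(f"{nm}:cw", cmap.origin(nm).position_bp, +1) for nm in names]
    forks += [(f"{nm}:ccw", cmap.origin(nm).position_bp, -1) for nm in names]
    return forks


def _blocking_ters(
    cmap: ChromosomeMap,
    cell_class: CellClass,
    direction: int,
    leaked: frozenset[str],
) -> list:
    if not cell_class.tus_active:
        return []
    want = "cw" if direction > 0 else "ccw"
    return [t for t in cmap.ter_sites if t.blocks == want and t.name not in leaked]


def sample_leaked_ters(
    cmap: ChromosomeMap, params: SimulationParams, rng: np.random.Generator
) -> frozenset[str]:
    """Draw the set of ter sites passed despite their blocking polarity."""
    if params.ter_leakage == 0.0:
        return frozenset()
    return frozenset(
        t.name for t in cmap.ter_sites if rng.random() < params.ter_leakage
    )


class _ForkPath:
    """Geometry of one fork's path.

    The fork starts at the centre of its origin bin; its speed is the bin's
    local speed and switches at bin edges.  ``dist_c[k]``/``arrive[k]`` are
    the path distance/time to the k-th visited bin centre, ``edge[k]``/
    ``t_edge[k]`` to the far edge of the k-th visited bin.  ``reach`` is
    the number of centres replicated before the first blocking ter site.
    """

    def __init__(
        self,
        cmap: ChromosomeMap,
        label: str,
        origin_pos: int,
        sign: int,
        bin_size: int,
        speed: float,
        factors: np.ndarray,
        blockers: list,
    ) -> None:
        L = cmap.length_bp
        n = n_bins(L, bin_size)
        widths = bin_widths(L, bin_size)
        mids = bin_mids(L, bin_size)
        self.label = label
        self.sign = sign
        b0 = bin_index(origin_pos, L, bin_size)
        self.order = (b0 + sign * np.arange(n)) % n
        w_path = widths[self.order]
        self.speed_path = speed * factors[self.order]

        self.edge = np.cumsum(w_path) - w_path[0] / 2.0
        seg_t = w_path / self.speed_path
        self.t_edge = np.cumsum(seg_t) - seg_t[0] / 2.0
        self.dist_c = np.empty(n)
        self.dist_c[0] = 0.0
        self.dist_c[1:] = self.edge[:-1] + w_path[1:] / 2.0
        self.arrive = np.empty(n)
        self.arrive[0] = 0.0
        self.arrive[1:] = self.t_edge[:-1] + 0.5 * seg_t[1:]

        # blocking: smallest path distance to a matching-polarity ter
        self.block_dist = np.inf
        self.block_ter: str | None = None
        for ter in blockers:
            d = (sign * (ter.position_bp - mids[b0])) % L
            if d < self.block_dist:
                self.block_dist = d
                self.block_ter = ter.name
        if np.isfinite(self.block_dist):
            self.reach = int(np.searchsorted(self.dist_c, self.block_dist, "right"))
        else:
            self.reach = n

    def time_at(self, path_dist: float) -> float:
        """Travel time to a given path distance."""
        k = int(np.searchsorted(self.edge, path_dist, "right"))
        if k == 0:
            return path_dist / self.speed_path[0]
        k = min(k, len(self.edge) - 1)
        return self.t_edge[k - 1] + (path_dist - self.edge[k - 1]) / self.speed_path[k]


def _build_paths(
    cmap: ChromosomeMap,
    cell_class: CellClass,
    params: SimulationParams,
    bin_size: int,
    leaked_ters: frozenset[str],
) -> list[_ForkPath]:
    f_cw, f_ccw = _speed_factors(cmap, bin_size, params)
    paths = []
    for label, opos, sign in _resolve_forks(cmap, cell_class):
        paths.append(
            _ForkPath(
                cmap,
                label,
                opos,
                sign,
                bin_size,
                params.fork_speed,
                f_cw if sign > 0 else f_ccw,
                _blocking_ters(cmap, cell_class, sign, leaked_ters),
            )
        )
    return paths


def _fusion_events(
    t: np.ndarray, fork_id: np.ndarray, signs: np.ndarray, bin_size: int, L: int
) -> list[FusionEvent]:
    out = []
    n = len(t)
    for i in range(n):
        j = (i + 1) % n
        if fork_id[i] == fork_id[j]:
            continue
        if signs[fork_id[i]] == +1 and signs[fork_id[j]] == -1:
            out.append(FusionEvent(float((j * bin_size) % L), float(max(t[i], t[j]))))
    return sorted(out, key=lambda e: e.position_bp)


def _block_events(
    paths: list[_ForkPath], fork_id: np.ndarray, times: list[float | None]
) -> list[BlockEvent]:
    """Keep a block only if the blocked fork actually owned the territory
    next to its stop position (otherwise it fused with a converging fork
    before ever reaching the ter site)."""
    n = len(fork_id)
    out = []
    for fi, p in enumerate(paths):
        if p.block_ter is None or p.reach >= n:
            continue
        last = p.order[p.reach - 1]
        if fork_id[last] == fi:
            tb = times[fi]
            if tb is None:  # fork halted before the sim stepped it to the ter
                tb = p.time_at(p.block_dist)
            out.append(BlockEvent(p.block_ter, p.label, float(tb)))
    return out


# ---------------------------------------------------------------------------
# analytic schedule


def replication_schedule(
    cmap: ChromosomeMap,
    cell_class: CellClass,
    params: SimulationParams,
    bin_size: int = 1000,
    leaked_ters: frozenset[str] = frozenset(),
) -> ReplicationSchedule:
    """Analytic piecewise-linear first-arrival schedule.

    Each fork's arrival time along its path is the cumulative
    centre-to-centre crossing time (distance / local speed); a fork's path
    ends at the first blocking ter site it meets.  A bin belongs to
    whichever fork arrives first.
    """
    L, n = cmap.length_bp, n_bins(cmap.length_bp, bin_size)
    paths = _build_paths(cmap, cell_class, params, bin_size, leaked_ters)

    t_all = np.full((len(paths), n), np.inf)
    for fi, p in enumerate(paths):
        t_all[fi, p.order[: p.reach]] = p.arrive[: p.reach]

    t = t_all.min(axis=0)
    fork_id = t_all.argmin(axis=0).astype(np.int64)
    if not np.all(np.isfinite(t)):
        raise AssertionError(
            "unreplicable bins despite >=1 active origin -- inconsistent trap"
        )

    block_times = [
        p.time_at(p.block_dist) if np.isfinite(p.block_dist) else None for p in paths
    ]
    signs = np.array([p.sign for p in paths])
    return ReplicationSchedule(
        length_bp=L,
        bin_size=bin_size,
        t=t,
        fork_id=fork_id,
        fork_labels=[p.label for p in paths],
        block_events=_block_events(paths, fork_id, block_times),
        fusion_events=_fusion_events(t, fork_id, signs, bin_size, L),
    )


# ---------------------------------------------------------------------------
# discrete-event oracle


def simulate_schedule_events(
    cmap: ChromosomeMap,
    cell_class: CellClass,
    params: SimulationParams,
    bin_size: int = 1000,
    dt: float = 1.0,
    leaked_ters: frozenset[str] = frozenset(),
    max_steps: int | None = None,
) -> ReplicationSchedule:
    """Time-stepped fork simulation; brute-force oracle for
    `replication_schedule`.

    Each live fork advances for ``dt`` of wall time per step through the
    per-bin speed field, halting at its first blocking ter site.  A bin's
    arrival time is the step time at which the first fork passes its
    centre, so recorded times overshoot truth by at most ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    L, n = cmap.length_bp, n_bins(cmap.length_bp, bin_size)
    paths = _build_paths(cmap, cell_class, params, bin_size, leaked_ters)

    t = np.full(n, np.inf)
    fork_id = np.full(n, -1, dtype=np.int64)

    # per-fork state: path distance travelled, next-centre pointer
    s = np.zeros(len(paths))
    nxt = np.zeros(len(paths), dtype=int)
    blocked = np.zeros(len(paths), dtype=bool)
    block_time: list[float | None] = [None] * len(paths)

    def record(fi: int, now: float) -> int:
        """Claim all centres the fork has passed; return bins newly claimed."""
        p = paths[fi]
        claimed = 0
        while nxt[fi] < p.reach and p.dist_c[nxt[fi]] <= s[fi] + 1e-9:
            b = p.order[nxt[fi]]
            if fork_id[b] == -1:
                fork_id[b] = fi
                t[b] = now
                claimed += 1
            nxt[fi] += 1
        return claimed

    remaining = n
    for fi in range(len(paths)):
        remaining -= record(fi, 0.0)

    slow = params.headon_speed_factor
    if max_steps is None:
        max_steps = int(np.ceil(L / (params.fork_speed * slow * dt))) * 2 + 10

    step = 0
    while remaining > 0:
        step += 1
        if step > max_steps:
            raise RuntimeError("event simulation exceeded its step budget")
        now = step * dt
        for fi, p in enumerate(paths):
            if blocked[fi] or nxt[fi] >= p.reach:
                continue
            budget = dt
            while budget > 1e-12:
                # speed switches at bin edges
                k = int(np.searchsorted(p.edge, s[fi], "right"))
                if k >= n:
                    break  # full circle travelled
                speed = p.speed_path[k]
                stop = min(p.edge[k], p.block_dist)
                move = min(budget * speed, stop - s[fi])
                s[fi] += max(move, 0.0)
                budget -= move / speed if move > 0 else budget
                if s[fi] >= p.block_dist - 1e-9:
                    blocked[fi] = True
                    block_time[fi] = now - max(budget, 0.0)
                    break
            remaining -= record(fi, now)

    signs = np.array([p.sign for p in paths])
    return ReplicationSchedule(
        length_bp=L,
        bin_size=bin_size,
        t=t,
        fork_id=fork_id,
        fork_labels=[p.label for p in paths],
        block_events=_block_events(paths, fork_id, block_time),
        fusion_events=_fusion_events(t, fork_id, signs, bin_size, L),
    )


# ---------------------------------------------------------------------------
# profiles


def marker_frequency(
    schedule: ReplicationSchedule, tau_min: float
) -> MarkerFrequencyProfile:
    """Population marker frequency from a schedule.

    With origins firing every ``tau`` minutes in a steady-state
    exponential population, the relative copy number of a locus replicated
    t seconds after initiation is ``2**(-t / tau)``; the profile is 1 at
    active origins by construction.
    """
    if tau_min <= 0:
        raise ValueError("tau must be positive")
    values = np.exp2(-schedule.t / (tau_min * 60.0))
    return MarkerFrequencyProfile(
        length_bp=schedule.length_bp,
        bin_size=schedule.bin_size,
        values=values,
        source="model",
        normalisation="origin=1",
    )


def class_profile(
    cmap: ChromosomeMap,
    cell_class: CellClass,
    params: SimulationParams,
    bin_size: int = 1000,
) -> MarkerFrequencyProfile:
    """Convenience: analytic schedule + marker frequency for one class."""
    sched = replication_schedule(cmap, cell_class, params, bin_size)
    return marker_frequency(sched, params.tau_min)


def mixture_profile(
    profiles: Sequence[MarkerFrequencyProfile],
    weights: Sequence[float],
) -> MarkerFrequencyProfile:
    """Weighted superposition of class profiles (weights sum to 1)."""
    if len(profiles) != len(weights) or not profiles:
        raise ValueError("need equal, non-zero numbers of profiles and weights")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    first = profiles[0]
    for p in profiles[1:]:
        if not first.same_binning(p):
            raise ValueError("profiles have mismatched binning")
    values = np.zeros(first.n_bins)
    mask = np.ones(first.n_bins, dtype=bool)
    for wi, p in zip(w, profiles):
        values += wi * np.where(p.mask, p.values, 0.0)
        mask &= p.mask
    values[~mask] = np.nan
    return MarkerFrequencyProfile(
        length_bp=first.length_bp,
        bin_size=first.bin_size,
        values=values,
        mask=mask,
        source="model",
        normalisation="mixture",
    )
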