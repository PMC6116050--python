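"""Marker-frequency profile processing.

Binned read counts from an exponential-phase sample are normalised against
a stationary-phase control, smoothed with a circular (periodic) tricube
degree-2 LOESS at a 10% span, and profile features are called: the global
low point, origin peaks, polar-trap steps and free discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .genome_model import ChromosomeMap, n_bins
from .replication_engine import MarkerFrequencyProfile

__all__ = [
    "BinnedCounts",
    "LoessConfig",
    "ProfileFeatures",
    "normalize_counts",
    "circular_loess",
    "find_extrema",
    "detect_steps",
    "origin_activity",
]


@dataclass
class BinnedCounts:
    """Per-bin read counts over a circular chromosome."""

    length_bp: int
    bin_size: int
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        expected = n_bins(self.length_bp, self.bin_size)
        if self.counts.shape != (expected,):
            raise ValueError(
                f"expected {expected} bins, got {self.counts.shape[0]}"
            )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def same_binning(self, other: "BinnedCounts") -> bool:
        return self.length_bp == other.length_bp and self.bin_size == other.bin_size


@dataclass
class LoessConfig:
    """Circular LOESS settings: degree-2 local fits, tricube weights in
    circular bin distance, neighbourhood = nearest ``span_fraction`` of
    bins.  At a 0.10 span on 1 kb bins of the full chromosome the window is
    ~460 kb wide."""

    span_fraction: float = 0.10
    degree: int = 2
    weight_kernel: str = "tricube"
    periodic: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.span_fraction <= 1:
            raise ValueError("span_fraction must be in (0, 1]")
        if self.degree != 2:
            raise ValueError("only degree-2 local fits are supported")
        if self.weight_kernel != "tricube":
            raise ValueError("only the tricube kernel is supported")
        if not self.periodic:
            raise ValueError("only periodic (circular) smoothing is supported")


@dataclass
class ProfileFeatures:
    low_point_bp: float | None = None
    peaks: list[tuple[float, float]] = field(default_factory=list)
    steps: list[tuple[str, float, float]] = field(default_factory=list)
    discontinuities: list[tuple[float, float]] = field(default_factory=list)
    flat: bool = False

    def to_dict(self) -> dict:
        return {
            "low_point_bp": self.low_point_bp,
            "peaks": [
                {"position_bp": p, "height": h} for p, h in self.peaks
            ],
            "steps": [
                {"ter": t, "position_bp": p, "magnitude": m}
                for t, p, m in self.steps
            ],
            "discontinuities": [
                {"position_bp": p, "jump": j} for p, j in self.discontinuities
            ],
            "flat": self.flat,
        }


# ---------------------------------------------------------------------------
# normalisation


def normalize_counts(
    sample: BinnedCounts,
    control: BinnedCounts,
    control_floor: int = 10,
) -> MarkerFrequencyProfile:
    """Ratio of within-library frequencies, sample over stationary control.

    Bins whose control count falls below ``control_floor`` are masked (their
    ratio variance is unbounded); the output is rescaled so the mean over
    unmasked bins is 1.
    """
    if not sample.same_binning(control):
        raise ValueError("sample and control have mismatched binning")
    mask = control.counts >= control_floor
    mask &= sample.counts > 0
    if not mask.any():
        raise ValueError("all bins masked during normalisation")
    ratio = np.full(sample.n_bins, np.nan)
    ratio[mask] = (sample.counts[mask] / sample.total) / (
        control.counts[mask] / control.total
    )
    ratio[mask] /= ratio[mask].mean()
    return MarkerFrequencyProfile(
        length_bp=sample.length_bp,
        bin_size=sample.bin_size,
        values=ratio,
        mask=mask,
        source="data",
        normalisation=f"control:{control.label or 'stationary'};floor={control_floor}",
    )


def mask_artifact_loci(
    profile: MarkerFrequencyProfile,
    cmap: ChromosomeMap,
    ter_pad_bp: int = 2000,
) -> MarkerFrequencyProfile:
    """Mask bins prone to the column-purification depletion artifact.

    Tightly or frequently protein-bound loci (highly transcribed features,
    ter/Tus sites +/- a pad) lose DNA fragments during purification and
    show depressed read counts in every library; flagging them out keeps
    the depression from biasing smoothing and mixture fits.
    """
    mask = profile.mask.copy()
    values = profile.values.copy()
    bs = profile.bin_size
    n = profile.n_bins
    spans = [(f.start_bp, f.end_bp) for f in cmap.transcribed_features
             if f.highly_transcribed]
    spans += [
        (max(t.position_bp - ter_pad_bp, 0), t.position_bp + ter_pad_bp)
        for t in cmap.ter_sites
    ]
    for start, end in spans:
        lo = start // bs
        hi = min((end - 1) // bs, n - 1)
        mask[lo: hi + 1] = False
    values[~mask] = np.nan
    return MarkerFrequencyProfile(
        length_bp=profile.length_bp,
        bin_size=profile.bin_size,
        values=values,
        mask=mask,
        source=profile.source,
        normalisation=profile.normalisation + ";artifact_masked",
    )


# ---------------------------------------------------------------------------
# circular LOESS


def _circular_offsets(n: int) -> np.ndarray:
    """Signed circular index offsets j - i for j in 0..n-1, i=0."""
    off = np.arange(n, dtype=float)
    off[off > n / 2] -= n
    return off


def circular_loess(
    profile: MarkerFrequencyProfile,
    config: LoessConfig | None = None,
) -> MarkerFrequencyProfile:
    """Locally weighted quadratic smoothing with periodic boundaries.

    For every bin (masked or not) the nearest ``span_fraction * n_bins``
    unmasked bins by circular distance form the neighbourhood; tricube
    weights are taken in circular distance scaled to the window's maximum
    distance, and a weighted degree-2 polynomial evaluated at the target
    bin gives the smoothed value.
    """
    config = config or LoessConfig()
    n = profile.n_bins
    valid = np.flatnonzero(profile.mask)
    k = int(np.ceil(config.span_fraction * n))
    if len(valid) < max(k, 4):
        raise ValueError(
            f"need at least {max(k, 4)} unmasked bins, have {len(valid)}"
        )
    y = profile.values
    # batched weighted quadratic fits via normal equations
    A = np.empty((n, 3, 3))
    b = np.empty((n, 3))
    for i in range(n):
        d_signed = valid.astype(float) - i
        d_signed[d_signed > n / 2] -= n
        d_signed[d_signed < -n / 2] += n
        d_abs = np.abs(d_signed)
        sel = np.argpartition(d_abs, k - 1)[:k]
        u = d_signed[sel]
        dmax = np.abs(u).max()
        w = (1.0 - (np.abs(u) / dmax) ** 3) ** 3
        x = u / dmax  # scaled for conditioning; prediction at x=0
        yy = y[valid[sel]]
        x2 = x * x
        A[i, 0, 0] = w.sum()
        A[i, 0, 1] = A[i, 1, 0] = (w * x).sum()
        A[i, 0, 2] = A[i, 2, 0] = A[i, 1, 1] = (w * x2).sum()
        A[i, 1, 2] = A[i, 2, 1] = (w * x2 * x).sum()
        A[i, 2, 2] = (w * x2 * x2).sum()
        b[i, 0] = (w * yy).sum()
        b[i, 1] = (w * x * yy).sum()
        b[i, 2] = (w * x2 * yy).sum()
    beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    smoothed = beta[:, 0]
    if np.any(smoothed <= 0):
        # LOESS can undershoot near sharp dips; clip to a tiny positive
        # floor so downstream ratio arithmetic stays defined
        floor = np.nanmin(y[profile.mask]) * 1e-6
        smoothed = np.maximum(smoothed, floor)
    return MarkerFrequencyProfile(
        length_bp=profile.length_bp,
        bin_size=profile.bin_size,
        values=smoothed,
        mask=np.ones(n, dtype=bool),
        source=profile.source,
        normalisation=profile.normalisation
        + f";loess(span={config.span_fraction},deg=2,tricube,periodic)",
    )


# ---------------------------------------------------------------------------
# feature calling


def find_extrema(
    profile: MarkerFrequencyProfile,
    min_prominence: float | None = None,
    flat_tol: float = 1e-12,
) -> ProfileFeatures:
    """Global low point and circular local maxima of a smoothed profile.

    ``min_prominence`` defaults to 1% of the profile's value range.  A flat
    profile is reported as such (no extrema).
    """
    vals = np.where(profile.mask, profile.values, np.nan)
    mids = profile.bin_mids()
    vrange = np.nanmax(vals) - np.nanmin(vals)
    if not np.isfinite(vrange) or vrange < flat_tol:
        return ProfileFeatures(flat=True)
    if min_prominence is None:
        min_prominence = 0.01 * vrange
    low_i = int(np.nanargmin(vals))
    n = profile.n_bins
    # circular peak finding on a padded copy
    pad = n // 2
    ext = np.concatenate([vals[-pad:], vals, vals[:pad]])
    idx, props = find_peaks(ext, prominence=min_prominence)
    peaks: dict[int, float] = {}
    for j, prom in zip(idx, props["prominences"]):
        i = (j - pad) % n
        peaks[i] = max(peaks.get(i, -np.inf), float(vals[i]))
    return ProfileFeatures(
        low_point_bp=float(mids[low_i]),
        peaks=sorted((float(mids[i]), h) for i, h in peaks.items()),
    )


def _flank_jump(
    vals: np.ndarray, mask: np.ndarray, boundary: int, k: int
) -> tuple[float, float, float]:
    """Robust, trend-corrected step estimate at a bin boundary.

    Each flank is split into an inner and an outer half; the four
    half-flank medians define one line per flank, and the jump is the gap
    between the two lines extrapolated to the boundary:

        jump = 1.5*(R_in - L_in) - 0.5*(R_out - L_out)

    which cancels any shared linear trend exactly.  Returns
    (jump, noise_var_of_jump, local_level); the variance comes from a
    robust per-bin sigma so callers can express jumps in noise units.
    Medians keep locus-specific depletion artifacts (rrn operons, ter/Tus
    sites) from masquerading as steps.
    """
    n = len(vals)
    h = k // 2
    idx = [
        (np.arange(boundary - k, boundary - h)) % n,   # left outer
        (np.arange(boundary - h, boundary)) % n,       # left inner
        (np.arange(boundary, boundary + h)) % n,       # right inner
        (np.arange(boundary + h, boundary + k)) % n,   # right outer
    ]
    windows = [vals[i][mask[i]] for i in idx]
    if any(len(w) < 3 for w in windows):
        return np.nan, np.nan, np.nan
    l_out, l_in, r_in, r_out = (float(np.median(w)) for w in windows)
    jump = 1.5 * (r_in - l_in) - 0.5 * (r_out - l_out)
    # per-bin sigma from within-window first differences
    diffs = np.concatenate([np.diff(w) for w in windows])
    sigma_d = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs))))
    sigma_bin2 = sigma_d**2 / 2.0
    m = np.mean([len(w) for w in windows])
    var_median = (np.pi / 2.0) * sigma_bin2 / m
    var_jump = (2 * 1.5**2 + 2 * 0.5**2) * var_median
    level = float(np.median(np.concatenate(windows)))
    return float(jump), float(var_jump), level


def detect_steps(
    profile: MarkerFrequencyProfile,
    cmap: ChromosomeMap,
    threshold: float | None = None,
    flank_bp: int = 50_000,
    match_bins: int = 1,
    sigma_gate: float = 5.0,
) -> ProfileFeatures:
    """Call step-like transitions and label those at annotated ter sites.

    A candidate step is a bin boundary where the trend-corrected difference
    of flanking-window medians exceeds both ``threshold`` (default: 10% of
    the profile's interquartile range) and ``sigma_gate`` noise standard
    deviations.  Candidates within ``match_bins`` bins of an annotated ter
    site carry its name; the rest are reported as free discontinuities
    (rearrangement candidates).
    """
    vals = profile.values
    mask = profile.mask
    n = profile.n_bins
    bs = profile.bin_size
    k = max(int(round(flank_bp / bs)), 5)
    if threshold is None:
        q1, q3 = np.nanpercentile(vals[mask], [25, 75])
        threshold = 0.1 * (q3 - q1)
    jumps = np.full(n, np.nan)
    sig = np.full(n, np.inf)
    for b in range(n):
        jumps[b], var_b, _ = _flank_jump(vals, mask, b, k)
        sig[b] = sigma_gate * np.sqrt(var_b)  # gate against count noise
    with np.errstate(invalid="ignore"):
        hits = (np.abs(jumps) > threshold) & (np.abs(jumps) > sig)
    # group contiguous candidate boundaries (circularly) and keep the
    # strongest boundary of each run
    feats = ProfileFeatures()
    if not hits.any():
        return feats
    hit_idx = np.flatnonzero(hits)
    # one physical step spreads candidate boundaries (and sign-flipped
    # echoes) over up to +/- flank bins: merge runs closer than the flank
    runs: list[list[int]] = [[hit_idx[0]]]
    for b in hit_idx[1:]:
        if b - runs[-1][-1] <= k:
            runs[-1].append(b)
        else:
            runs.append([b])
    if len(runs) > 1 and (runs[0][0] + n) - runs[-1][-1] <= k:
        # wrapped run: express the tail as negative indices so the run is
        # contiguous; modular arithmetic below restores real positions
        runs[0] = [b - n for b in runs.pop()] + runs[0]

    def local_jump(b: int) -> float:
        """Tight mean difference: peaks exactly at the step boundary
        (medians would plateau over half a window)."""
        w = 8
        li = np.arange(b - w, b) % n
        ri = np.arange(b, b + w) % n
        lv, rv = vals[li][mask[li]], vals[ri][mask[ri]]
        if len(lv) < 3 or len(rv) < 3:
            return 0.0
        return float(np.mean(rv) - np.mean(lv))

    ter_pos = {t.name: t.position_bp for t in cmap.ter_sites}
    for run in runs:
        cand = range(min(run), max(run) + 1)
        best = max(cand, key=lambda b: abs(local_jump(b)))
        pos = (best * bs) % profile.length_bp
        mag = float(jumps[max(run, key=lambda b: abs(jumps[b]))])
        label = None
        best_d = match_bins * bs + bs  # ter may sit anywhere inside a bin
        for name, tp in ter_pos.items():
            d = min(
                abs(tp - pos), profile.length_bp - abs(tp - pos)
            )
            if d <= best_d:
                best_d = d
                label = name
        if label is not None:
            feats.steps.append((label, float(pos), mag))
        else:
            feats.discontinuities.append((float(pos), mag))
    return feats


def origin_activity(
    profile: MarkerFrequencyProfile, cmap: ChromosomeMap
) -> dict[str, float]:
    """Relative origin usage read off the profile.

    Returns the profile value at each active origin's bin, rescaled so the
    strongest origin is 1.
    """
    active = cmap.active_origins
    if not active:
        raise ValueError("map has no active origins")
    heights = {}
    for o in active:
        b = min(o.position_bp // profile.bin_size, profile.n_bins - 1)
        if not profile.mask[b]:
            # fall back to the nearest valid bin
            valid = np.flatnonzero(profile.mask)
            n = profile.n_bins
            d = np.abs(valid - b)
            d = np.minimum(d, n - d)
            b = int(valid[np.argmin(d)])
        heights[o.name] = float(profile.values[b])
    top = max(heights.values())
    return {name: h / top for name, h in heights.items()}
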