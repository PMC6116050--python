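"""Inversions and tandem duplications of chromosome maps and profiles.

An inversion reflects the contained features about the segment and flips
ter-site polarities and transcription directions; a tandem duplication
repeats the segment.  Profiles measured on a rearranged chromosome can be
projected onto reference coordinates (modelling reads from the rearranged
genome mapped to the reference assembly), and a candidate rearrangement is
scored by how much re-projecting the observed profile restores its
continuity at the candidate breakpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .genome_model import ChromosomeMap, ISElement, Origin, TerSite, TranscribedFeature
from .mfa_pipeline import _flank_jump
from .replication_engine import MarkerFrequencyProfile

__all__ = [
    "Rearrangement",
    "apply_rearrangement",
    "project_profile",
    "continuity_score",
    "evaluate_candidate",
    "is_pair_candidates",
]


@dataclass(frozen=True)
class Rearrangement:
    """An inversion or tandem duplication in reference coordinates.

    ``start_bp``/``end_bp`` are half-open and must satisfy start < end (the
    segment may not wrap the origin of coordinates).  ``copies`` applies to
    duplications only: total copy count of the segment.
    """

    kind: str
    start_bp: int
    end_bp: int
    copies: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "duplication"):
            raise ValueError(f"kind must be inversion|duplication, not {self.kind!r}")
        if self.start_bp >= self.end_bp:
            raise ValueError("require start_bp < end_bp (non-wrapping segment)")
        if self.kind == "duplication" and self.copies < 2:
            raise ValueError("a duplication needs copies >= 2")

    @property
    def segment_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def breakpoints(self) -> tuple[int, int]:
        return (self.start_bp, self.end_bp)

    @classmethod
    def parse(cls, text: str) -> "Rearrangement":
        """Parse 'kind:start-end[:copies]', e.g. 'inversion:575000-1394000'."""
        parts = text.split(":")
        if len(parts) not in (2, 3):
            raise ValueError(f"cannot parse rearrangement spec {text!r}")
        kind = parts[0]
        span = parts[1].split("-")
        if len(span) != 2:
            raise ValueError(f"cannot parse span in {text!r}")
        copies = int(parts[2]) if len(parts) == 3 else 2
        return cls(kind, int(span[0]), int(span[1]), copies)


def _contained(pos: int, r: Rearrangement) -> bool:
    return r.start_bp <= pos < r.end_bp


def _invert_point(pos: int, r: Rearrangement) -> int:
    return r.start_bp + r.end_bp - 1 - pos


def _check_straddle(start: int, end: int, r: Rearrangement, name: str) -> None:
    inside = (_contained(start, r), _contained(end - 1, r))
    if inside[0] != inside[1]:
        raise ValueError(
            f"feature {name} straddles a breakpoint of {r.kind} "
            f"{r.start_bp}-{r.end_bp}"
        )


def apply_rearrangement(cmap: ChromosomeMap, r: Rearrangement) -> ChromosomeMap:
    """Return the rearranged chromosome map.

    Inversion: coordinates inside the segment are reflected; contained ter
    sites flip their blocking polarity and contained transcribed features
    flip direction.  Duplication: the segment is repeated in tandem;
    features inside it appear once per copy (suffixed ``_copy2`` ...) and
    everything downstream shifts by (copies-1) segment lengths.  A
    duplication containing an origin duplicates that origin (allowed, but
    flagged with a warning).
    """
    if not 0 <= r.start_bp < cmap.length_bp or not 0 < r.end_bp <= cmap.length_bp:
        raise ValueError("rearrangement breakpoints outside the chromosome")
    flip = {"cw": "ccw", "ccw": "cw"}
    if r.kind == "inversion":
        origins = [
            replace(o, position_bp=_invert_point(o.position_bp, r))
            if _contained(o.position_bp, r)
            else replace(o)
            for o in cmap.origins
        ]
        ters = [
            TerSite(t.name, _invert_point(t.position_bp, r), flip[t.blocks])
            if _contained(t.position_bp, r)
            else replace(t)
            for t in cmap.ter_sites
        ]
        feats = []
        for f in cmap.transcribed_features:
            _check_straddle(f.start_bp, f.end_bp, r, f.name)
            if _contained(f.start_bp, r):
                feats.append(
                    TranscribedFeature(
                        f.name,
                        r.start_bp + r.end_bp - f.end_bp,
                        r.start_bp + r.end_bp - f.start_bp,
                        flip[f.direction],
                        f.highly_transcribed,
                    )
                )
            else:
                feats.append(replace(f))
        iss = []
        for e in cmap.is_elements:
            _check_straddle(e.position_bp, e.position_bp + e.length_bp, r, e.name)
            if _contained(e.position_bp, r):
                iss.append(
                    ISElement(
                        e.name,
                        r.start_bp + r.end_bp - (e.position_bp + e.length_bp),
                        e.length_bp,
                    )
                )
            else:
                iss.append(replace(e))
        return ChromosomeMap(
            name=cmap.name,
            length_bp=cmap.length_bp,
            origins=origins,
            ter_sites=ters,
            transcribed_features=feats,
            is_elements=iss,
        )

    # duplication
    seg = r.segment_bp
    shift = (r.copies - 1) * seg

    def new_positions(pos: int) -> list[int]:
        if pos >= r.end_bp:
            return [pos + shift]
        if _contained(pos, r):
            return [pos + j * seg for j in range(r.copies)]
        return [pos]

    def suffixed(name: str, j: int) -> str:
        return name if j == 0 else f"{name}_copy{j + 1}"

    origins, ters, feats, iss = [], [], [], []
    for o in cmap.origins:
        pp = new_positions(o.position_bp)
        if len(pp) > 1:
            warnings.warn(
                f"duplication copies origin {o.name}; the rearranged map "
                f"carries {len(pp)} copies",
                stacklevel=2,
            )
        origins += [
            replace(o, name=suffixed(o.name, j), position_bp=p)
            for j, p in enumerate(pp)
        ]
    for t in cmap.ter_sites:
        ters += [
            TerSite(suffixed(t.name, j), p, t.blocks)
            for j, p in enumerate(new_positions(t.position_bp))
        ]
    for f in cmap.transcribed_features:
        _check_straddle(f.start_bp, f.end_bp, r, f.name)
        for j, p in enumerate(new_positions(f.start_bp)):
            feats.append(
                TranscribedFeature(
                    suffixed(f.name, j),
                    p,
                    p + (f.end_bp - f.start_bp),
                    f.direction,
                    f.highly_transcribed,
                )
            )
    for e in cmap.is_elements:
        _check_straddle(e.position_bp, e.position_bp + e.length_bp, r, e.name)
        iss += [
            ISElement(suffixed(e.name, j), p, e.length_bp)
            for j, p in enumerate(new_positions(e.position_bp))
        ]
    return ChromosomeMap(
        name=cmap.name,
        length_bp=cmap.length_bp + shift,
        origins=origins,
        ter_sites=ters,
        transcribed_features=feats,
        is_elements=iss,
    )


# ---------------------------------------------------------------------------
# profile projection


def _aligned_bins(r: Rearrangement, bin_size: int) -> tuple[int, int]:
    if r.start_bp % bin_size or r.end_bp % bin_size:
        raise ValueError(
            f"breakpoints {r.start_bp}-{r.end_bp} must align to the "
            f"{bin_size} bp binning for profile projection"
        )
    return r.start_bp // bin_size, r.end_bp // bin_size


def project_profile(
    profile: MarkerFrequencyProfile,
    r: Rearrangement,
    inverse: bool = False,
) -> MarkerFrequencyProfile:
    """Project a profile between rearranged and reference coordinates.

    Forward (default): the profile lives on the rearranged chromosome and
    is mapped onto reference coordinates, as read mapping does --
    inversions reverse the segment's bins in place; duplicated copies pile
    up (sum) onto the single reference segment.  ``inverse=True`` maps a
    reference profile onto the rearranged chromosome (duplicated copies
    each receive an equal share).
    """
    sb, eb = _aligned_bins(r, profile.bin_size)
    if r.kind == "inversion":
        values = profile.values.copy()
        mask = profile.mask.copy()
        values[sb:eb] = values[sb:eb][::-1]
        mask[sb:eb] = mask[sb:eb][::-1]
        return replace(profile, values=values, mask=mask)

    seg_bins = eb - sb
    extra = (r.copies - 1) * seg_bins
    if inverse:  # reference -> rearranged
        n_out = profile.n_bins + extra
        values = np.full(n_out, np.nan)
        mask = np.zeros(n_out, dtype=bool)
        values[:sb] = profile.values[:sb]
        mask[:sb] = profile.mask[:sb]
        for j in range(r.copies):
            sl = slice(sb + j * seg_bins, eb + j * seg_bins)
            values[sl] = profile.values[sb:eb] / r.copies
            mask[sl] = profile.mask[sb:eb]
        values[eb + extra:] = profile.values[eb:]
        mask[eb + extra:] = profile.mask[eb:]
        return MarkerFrequencyProfile(
            length_bp=profile.length_bp + extra * profile.bin_size,
            bin_size=profile.bin_size,
            values=values,
            mask=mask,
            source=profile.source,
            normalisation=profile.normalisation + ";proj_inverse",
        )
    # rearranged -> reference
    n_out = profile.n_bins - extra
    values = np.full(n_out, np.nan)
    mask = np.zeros(n_out, dtype=bool)
    values[:sb] = profile.values[:sb]
    mask[:sb] = profile.mask[:sb]
    acc = np.zeros(seg_bins)
    ok = np.ones(seg_bins, dtype=bool)
    for j in range(r.copies):
        sl = slice(sb + j * seg_bins, eb + j * seg_bins)
        acc += np.where(profile.mask[sl], profile.values[sl], 0.0)
        ok &= profile.mask[sl]
    values[sb:eb] = np.where(ok, acc, np.nan)
    mask[sb:eb] = ok
    values[eb:] = profile.values[eb + extra:]
    mask[eb:] = profile.mask[eb + extra:]
    return MarkerFrequencyProfile(
        length_bp=profile.length_bp - extra * profile.bin_size,
        bin_size=profile.bin_size,
        values=values,
        mask=mask,
        source=profile.source,
        normalisation=profile.normalisation + ";proj_reference",
    )


# ---------------------------------------------------------------------------
# continuity scoring


def continuity_score(
    profile: MarkerFrequencyProfile,
    breakpoints: list[int],
    flank_bp: int = 50_000,
    level_floor_frac: float = 0.01,
) -> float:
    """Squared, noise-scaled step size summed over breakpoints.

    At each breakpoint the trend-corrected difference of flanking-window
    medians is squared and divided by its estimated sampling variance plus
    a small level-proportional floor; a continuous profile scores near 0,
    a genuine discontinuity scores far above it.
    """
    if flank_bp < profile.bin_size:
        raise ValueError("flank must be at least one bin")
    k = max(int(round(flank_bp / profile.bin_size)), 5)
    total = 0.0
    for p in breakpoints:
        b = int(round(p / profile.bin_size)) % profile.n_bins
        jump, var_jump, level = _flank_jump(profile.values, profile.mask, b, k)
        if not np.isfinite(jump):
            continue
        scale = var_jump + (level_floor_frac * level) ** 2
        total += jump**2 / scale
    return float(total)


def evaluate_candidate(
    observed: MarkerFrequencyProfile,
    candidate: Rearrangement,
    flank_bp: int = 50_000,
) -> tuple[float, float]:
    """Continuity score at the candidate's breakpoints before and after
    undoing its projection.

    ``observed`` is a reference-coordinate profile.  If the candidate is
    the true rearrangement, re-projecting the profile restores continuity
    and the after-score collapses to the noise floor.
    """
    bps = list(candidate.breakpoints)
    before = continuity_score(observed, bps, flank_bp)
    corrected = project_profile(observed, candidate, inverse=True)
    if candidate.kind == "duplication":
        bps = [
            candidate.start_bp,
            candidate.end_bp + (candidate.copies - 1) * candidate.segment_bp,
        ]
    after = continuity_score(corrected, bps, flank_bp)
    return before, after


def is_pair_candidates(
    cmap: ChromosomeMap, kind: str = "inversion"
) -> list[Rearrangement]:
    """Enumerate candidate rearrangements with breakpoints at annotated IS
    elements (the biologically favoured recombination substrates)."""
    out = []
    for a, b in combinations(sorted(cmap.is_elements, key=lambda e: e.position_bp), 2):
        out.append(Rearrangement(kind, a.position_bp, b.position_bp))
    return out
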