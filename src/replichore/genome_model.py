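"""Circular chromosome coordinates and annotation model.

All coordinates are 0-based base pairs on a circular chromosome of
``length_bp`` bases; intervals are half-open.  "Clockwise" (``cw``) means
travelling in the direction of increasing coordinate, "counter-clockwise"
(``ccw``) the direction of decreasing coordinate.  Every arc operation is
invariant under rotating all coordinates by a constant (mod length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

Direction = Literal["cw", "ccw"]

_DIRECTIONS = ("cw", "ccw")


@dataclass
class Origin:
    """A replication origin (native or ectopic) modelled as a point locus."""

    name: str
    position_bp: int
    active: bool = True


@dataclass
class TerSite:
    """A polar fork trap site.

    ``blocks`` is the travel direction a replication fork must have in
    order to be arrested here; forks travelling the other way pass freely.
    Polarity belongs to the site, not to the fork.
    """

    name: str
    position_bp: int
    blocks: Direction

    def __post_init__(self) -> None:
        if self.blocks not in _DIRECTIONS:
            raise ValueError(f"ter site {self.name}: blocks must be 'cw' or 'ccw'")


@dataclass
class TranscribedFeature:
    """A transcribed interval; highly transcribed ones slow head-on forks."""

    name: str
    start_bp: int
    end_bp: int
    direction: Direction
    highly_transcribed: bool = True

    def __post_init__(self) -> None:
        if self.start_bp == self.end_bp:
            raise ValueError(f"transcribed feature {self.name}: empty interval")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"transcribed feature {self.name}: bad direction")


@dataclass
class ISElement:
    name: str
    position_bp: int
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"IS element {self.name}: length must be positive")


@dataclass
class ChromosomeMap:
    """A circular chromosome with annotated origins, ter sites, transcribed
    features and IS elements."""

    name: str
    length_bp: int
    origins: list[Origin] = field(default_factory=list)
    ter_sites: list[TerSite] = field(default_factory=list)
    transcribed_features: list[TranscribedFeature] = field(default_factory=list)
    is_elements: list[ISElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        L = self.length_bp
        if L <= 0:
            raise ValueError("length_bp must be positive")
        for o in self.origins:
            self._check_pos(o.position_bp, f"origin {o.name}")
        for t in self.ter_sites:
            self._check_pos(t.position_bp, f"ter site {t.name}")
        for f in self.transcribed_features:
            self._check_pos(f.start_bp, f"feature {f.name} start")
            if not 0 < f.end_bp <= L:
                raise ValueError(f"feature {f.name} end out of range")
        for e in self.is_elements:
            self._check_pos(e.position_bp, f"IS element {e.name}")
        for label, names in (
            ("origin", [o.name for o in self.origins]),
            ("ter site", [t.name for t in self.ter_sites]),
        ):
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate {label} names: {sorted(names)}")

    def _check_pos(self, pos: int, what: str) -> None:
        if not 0 <= pos < self.length_bp:
            raise ValueError(f"{what}: position {pos} outside [0, {self.length_bp})")

    # -- lookups -------------------------------------------------------
    def origin(self, name: str) -> Origin:
        for o in self.origins:
            if o.name == name:
                return o
        raise KeyError(f"no origin named {name!r}")

    def ter(self, name: str) -> TerSite:
        for t in self.ter_sites:
            if t.name == name:
                return t
        raise KeyError(f"no ter site named {name!r}")

    @property
    def active_origins(self) -> list[Origin]:
        return [o for o in self.origins if o.active]

    def with_active_origins(self, names: Iterable[str]) -> "ChromosomeMap":
        """Copy of this map with exactly the named origins flagged active."""
        wanted = set(names)
        known = {o.name for o in self.origins}
        missing = wanted - known
        if missing:
            raise KeyError(f"unknown origins: {sorted(missing)}")
        return replace(
            self,
            origins=[replace(o, active=o.name in wanted) for o in self.origins],
            ter_sites=[replace(t) for t in self.ter_sites],
            transcribed_features=[replace(f) for f in self.transcribed_features],
            is_elements=[replace(e) for e in self.is_elements],
        )


# ---------------------------------------------------------------------------
# coordinate arithmetic


def minutes_to_bp(cmap: ChromosomeMap, minutes: float) -> int:
    """Convert a genetic-map position (0-100 min) to bp, linearly."""
    if not 0 <= minutes < 100:
        raise ValueError(f"minutes must be in [0, 100), got {minutes}")
    return int(round(minutes / 100.0 * cmap.length_bp)) % cmap.length_bp


def arc_distance(cmap: ChromosomeMap, a: int, b: int, direction: Direction) -> int:
    """Distance from ``a`` to ``b`` travelling only in ``direction``."""
    L = cmap.length_bp
    if not (0 <= a < L and 0 <= b < L):
        raise ValueError("coordinates outside chromosome")
    if direction == "cw":
        return (b - a) % L
    if direction == "ccw":
        return (a - b) % L
    raise ValueError(f"direction must be 'cw' or 'ccw', got {direction!r}")


def arc_midpoint(cmap: ChromosomeMap, a: int, b: int, through: int) -> int:
    """Coordinate equidistant from ``a`` and ``b`` along the arc that
    contains ``through``.

    For ``a == b`` the two arcs degenerate into the full circle and the
    midpoint is the antipode of ``a``.  ``through`` must not coincide with
    either endpoint.
    """
    L = cmap.length_bp
    for x, what in ((a, "a"), (b, "b"), (through, "through")):
        if not 0 <= x < L:
            raise ValueError(f"{what}={x} outside chromosome")
    if through == a or through == b:
        raise ValueError("'through' coincides with an arc endpoint")
    if a == b:
        mid = (a + L / 2.0) % L
        return int(math.floor(mid + 0.5)) % L
    d_cw = (b - a) % L
    if (through - a) % L < d_cw:  # through lies on the cw arc a -> b
        mid = (a + d_cw / 2.0) % L
    else:  # through lies on the cw arc b -> a
        mid = (b + ((a - b) % L) / 2.0) % L
    return int(math.floor(mid + 0.5)) % L


# ---------------------------------------------------------------------------
# binning helpers shared by the profile modules


def n_bins(length_bp: int, bin_size: int) -> int:
    return -(-length_bp // bin_size)


def bin_widths(length_bp: int, bin_size: int) -> np.ndarray:
    """Per-bin widths; the final bin may be short on a non-multiple length."""
    n = n_bins(length_bp, bin_size)
    w = np.full(n, bin_size, dtype=float)
    w[-1] = length_bp - (n - 1) * bin_size
    return w


def bin_starts(length_bp: int, bin_size: int) -> np.ndarray:
    return np.arange(n_bins(length_bp, bin_size), dtype=float) * bin_size


def bin_mids(length_bp: int, bin_size: int) -> np.ndarray:
    return bin_starts(length_bp, bin_size) + bin_widths(length_bp, bin_size) / 2.0


def bin_index(pos: int, length_bp: int, bin_size: int) -> int:
    if not 0 <= pos < length_bp:
        raise ValueError(f"position {pos} outside [0, {length_bp})")
    return min(pos // bin_size, n_bins(length_bp, bin_size) - 1)


# ---------------------------------------------------------------------------
# BED-like annotation I/O

_TYPE_COL = {"origin", "ter", "transcribed", "is_element"}


def _infer_type(name: str) -> str:
    if name.startswith("ori"):
        return "origin"
    if name.startswith("ter"):
        return "ter"
    if name.startswith("IS"):
        return "is_element"
    return "transcribed"


def read_map_bed(path: str | Path, name: str | None = None) -> ChromosomeMap:
    """Read a chromosome map from BED6(+type) text.

    A ``# length=<bp>`` header line is required (circular length is not
    expressible in BED records).  See the bundled MG1655 fixture for the
    column conventions.
    """
    length: int | None = None
    origins: list[Origin] = []
    ters: list[TerSite] = []
    feats: list[TranscribedFeature] = []
    iss: list[ISElement] = []
    chrom = name
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "length=" in line:
                length = int(line.split("length=")[1].split()[0])
            continue
        cols = line.split("\t")
        if len(cols) < 6:
            raise ValueError(f"expected >=6 BED columns, got: {line!r}")
        chrom = chrom or cols[0]
        start, end = int(cols[1]), int(cols[2])
        fname, score, strand = cols[3], cols[4], cols[5]
        ftype = cols[6] if len(cols) > 6 else _infer_type(fname)
        if ftype not in _TYPE_COL:
            raise ValueError(f"unknown feature type {ftype!r} for {fname}")
        if ftype == "origin":
            origins.append(Origin(fname, start, active=score not in ("0", ".")))
        elif ftype == "ter":
            ters.append(TerSite(fname, start, "cw" if strand == "+" else "ccw"))
        elif ftype == "transcribed":
            feats.append(
                TranscribedFeature(
                    fname, start, end,
                    "cw" if strand == "+" else "ccw",
                    highly_transcribed=score not in ("0", "."),
                )
            )
        else:
            iss.append(ISElement(fname, start, end - start))
    if length is None:
        raise ValueError(f"{path}: missing '# length=<bp>' header")
    return ChromosomeMap(
        name=chrom or "chromosome",
        length_bp=length,
        origins=origins,
        ter_sites=ters,
        transcribed_features=feats,
        is_elements=iss,
    )


def write_map_bed(cmap: ChromosomeMap, path: str | Path) -> None:
    lines = [f"# chromosome map: {cmap.name}", f"# length={cmap.length_bp}"]
    for o in cmap.origins:
        lines.append(
            f"{cmap.name}\t{o.position_bp}\t{o.position_bp + 1}\t{o.name}\t"
            f"{1 if o.active else 0}\t.\torigin"
        )
    for t in cmap.ter_sites:
        strand = "+" if t.blocks == "cw" else "-"
        lines.append(
            f"{cmap.name}\t{t.position_bp}\t{t.position_bp + 1}\t{t.name}\t0\t"
            f"{strand}\tter"
        )
    for f in cmap.transcribed_features:
        strand = "+" if f.direction == "cw" else "-"
        lines.append(
            f"{cmap.name}\t{f.start_bp}\t{f.end_bp}\t{f.name}\t"
            f"{1 if f.highly_transcribed else 0}\t{strand}\ttranscribed"
        )
    for e in cmap.is_elements:
        lines.append(
            f"{cmap.name}\t{e.position_bp}\t{e.position_bp + e.length_bp}\t"
            f"{e.name}\t0\t.\tis_element"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def map_to_config(cmap: ChromosomeMap) -> dict:
    """Serialise a map to a plain dict (YAML/JSON-safe)."""
    return {
        "name": cmap.name,
        "length_bp": cmap.length_bp,
        "origins": [
            {"name": o.name, "position_bp": o.position_bp, "active": o.active}
            for o in cmap.origins
        ],
        "ter_sites": [
            {"name": t.name, "position_bp": t.position_bp, "blocks": t.blocks}
            for t in cmap.ter_sites
        ],
        "transcribed_features": [
            {
                "name": f.name,
                "start_bp": f.start_bp,
                "end_bp": f.end_bp,
                "direction": f.direction,
                "highly_transcribed": f.highly_transcribed,
            }
            for f in cmap.transcribed_features
        ],
        "is_elements": [
            {"name": e.name, "position_bp": e.position_bp, "length_bp": e.length_bp}
            for e in cmap.is_elements
        ],
    }


def map_from_config(cfg: dict) -> ChromosomeMap:
    return ChromosomeMap(
        name=cfg["name"],
        length_bp=cfg["length_bp"],
        origins=[Origin(**o) for o in cfg.get("origins", [])],
        ter_sites=[TerSite(**t) for t in cfg.get("ter_sites", [])],
        transcribed_features=[
            TranscribedFeature(**f) for f in cfg.get("transcribed_features", [])
        ],
        is_elements=[ISElement(**e) for e in cfg.get("is_elements", [])],
    )


def build_default_map() -> ChromosomeMap:
    """The bundled MG1655 fixture: 4,641,652 bp, oriC plus the three
    ectopic origins (inactive by default), ter sites A-J with wild-type
    polarities, the seven rrn operons, the ribosomal-protein gene cluster
    and the three IS5 elements used as rearrangement breakpoints."""
    ref = resources.files("replichore.data") / "mg1655_features.bed"
    with resources.as_file(ref) as path:
        cmap = read_map_bed(path, name="MG1655")
    return cmap
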