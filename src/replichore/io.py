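"""Plain-text readers/writers for binned counts, profiles and reports.

Counts and profiles travel as TSV (``start  end  value``) or bedGraph
(``chrom  start  end  value``); ``#``-prefixed header lines carry the
circular length, bin size and provenance and are required on read (the
circular length is not recoverable from the records alone).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mfa_pipeline import BinnedCounts
from .replication_engine import MarkerFrequencyProfile


def _header_lines(length_bp: int, bin_size: int, extra: dict | None) -> list[str]:
    lines = [f"# length={length_bp}", f"# bin_size={bin_size}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}={v}")
    return lines


def _parse_headers(path: Path) -> tuple[dict, list[str]]:
    meta: dict[str, str] = {}
    rows = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        rows.append(line)
    return meta, rows


def write_counts(
    counts: BinnedCounts,
    path: str | Path,
    bedgraph: bool = False,
    chrom: str = "chr",
    extra_header: dict | None = None,
) -> None:
    lines = _header_lines(counts.length_bp, counts.bin_size, extra_header)
    if counts.label:
        lines.append(f"# label={counts.label}")
    n = counts.n_bins
    for i in range(n):
        start = i * counts.bin_size
        end = min(start + counts.bin_size, counts.length_bp)
        prefix = f"{chrom}\t" if bedgraph else ""
        lines.append(f"{prefix}{start}\t{end}\t{int(counts.counts[i])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts(path: str | Path) -> BinnedCounts:
    path = Path(path)
    meta, rows = _parse_headers(path)
    if "length" not in meta or "bin_size" not in meta:
        raise ValueError(f"{path}: missing '# length=' / '# bin_size=' headers")
    values = []
    for row in rows:
        cols = row.split("\t")
        if len(cols) == 4:   # bedGraph
            cols = cols[1:]
        if len(cols) != 3:
            raise ValueError(f"{path}: expected 3 or 4 columns, got {row!r}")
        values.append(int(float(cols[2])))
    return BinnedCounts(
        length_bp=int(meta["length"]),
        bin_size=int(meta["bin_size"]),
        counts=np.array(values, dtype=np.int64),
        label=meta.get("label", path.stem),
    )


def write_profile(
    profile: MarkerFrequencyProfile,
    path: str | Path,
    bedgraph: bool = False,
    chrom: str = "chr",
    extra_header: dict | None = None,
) -> None:
    extra = {"source": profile.source, "normalisation": profile.normalisation}
    extra.update(extra_header or {})
    lines = _header_lines(profile.length_bp, profile.bin_size, extra)
    for i in range(profile.n_bins):
        start = i * profile.bin_size
        end = min(start + profile.bin_size, profile.length_bp)
        val = profile.values[i] if profile.mask[i] else np.nan
        prefix = f"{chrom}\t" if bedgraph else ""
        lines.append(f"{prefix}{start}\t{end}\t{val:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> MarkerFrequencyProfile:
    path = Path(path)
    meta, rows = _parse_headers(path)
    if "length" not in meta or "bin_size" not in meta:
        raise ValueError(f"{path}: missing '# length=' / '# bin_size=' headers")
    values = []
    for row in rows:
        cols = row.split("\t")
        if len(cols) == 4:
            cols = cols[1:]
        values.append(float(cols[2]))
    arr = np.array(values)
    return MarkerFrequencyProfile(
        length_bp=int(meta["length"]),
        bin_size=int(meta["bin_size"]),
        values=arr,
        mask=np.isfinite(arr),
        source=meta.get("source", "data"),
        normalisation=meta.get("normalisation", ""),
    )


def write_schedule_tsv(schedule, path: str | Path) -> None:
    lines = [
        f"# length={schedule.length_bp}",
        f"# bin_size={schedule.bin_size}",
        "# columns: start\tend\tt_seconds\tfork",
    ]
    for i in range(schedule.n_bins):
        start = i * schedule.bin_size
        end = min(start + schedule.bin_size, schedule.length_bp)
        lines.append(
            f"{start}\t{end}\t{schedule.t[i]:.6f}\t{schedule.fork_name(i)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
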