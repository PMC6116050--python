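"""Synthetic sequencing datasets with the statistical structure the
pipeline assumes.

Binned read counts are drawn from a model marker-frequency profile with
Poisson or negative-binomial noise, optionally depleted at loci where
tightly bound protein-DNA complexes cause fragment loss during library
preparation (rrn operons, ter/Tus sites).  Named scenarios bundle a sample,
a flat stationary-phase control and a machine-readable truth record, so the
whole pipeline is testable without any sequencing download.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as _io
from .genome_model import ChromosomeMap, build_default_map, n_bins, write_map_bed
from .mfa_pipeline import BinnedCounts
from .rearrangements import Rearrangement, apply_rearrangement, project_profile
from .replication_engine import (
    CellClass,
    MarkerFrequencyProfile,
    SimulationParams,
    marker_frequency,
    mixture_profile,
    replication_schedule,
)

__all__ = [
    "NoiseSpec",
    "ArtifactSpec",
    "ScenarioBundle",
    "SCENARIOS",
    "simulate_counts",
    "simulate_control",
    "generate_scenario",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Count noise family and depth (mean reads per bin at copy number 1)."""

    family: str = "poisson"
    depth: float = 100.0
    dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.family == "negative_binomial" and (
            self.dispersion is None or self.dispersion <= 0
        ):
            raise ValueError("negative binomial noise needs dispersion > 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """Locus-specific read depletion near tight protein-DNA complexes.

    ``loci`` is a list of (start_bp, end_bp) intervals; when None it
    defaults to the map's highly transcribed features plus +/-2 kb around
    every ter site.  The depletion magnitude is not derivable from first
    principles; the 0.5 default is a placeholder of the right order.
    """

    loci: tuple[tuple[int, int], ...] | None = None
    depletion_factor: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.depletion_factor <= 1:
            raise ValueError("depletion_factor must be in (0, 1]")

    def resolved_loci(self, cmap: ChromosomeMap) -> list[tuple[int, int]]:
        if self.loci is not None:
            return list(self.loci)
        out = [(f.start_bp, f.end_bp) for f in cmap.transcribed_features]
        for t in cmap.ter_sites:
            out.append((max(t.position_bp - 2000, 0), t.position_bp + 2000))
        return out


def _depletion_multiplier(
    cmap: ChromosomeMap, artifact: ArtifactSpec | None, bin_size: int
) -> np.ndarray:
    n = n_bins(cmap.length_bp, bin_size)
    mult = np.ones(n)
    if artifact is None:
        return mult
    for start, end in artifact.resolved_loci(cmap):
        lo = start // bin_size
        hi = min((end - 1) // bin_size, n - 1)
        mult[lo: hi + 1] = artifact.depletion_factor
    return mult


def _draw(mean: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    if noise.family == "poisson":
        return rng.poisson(mean)
    # gamma-poisson: var = m + m^2 / dispersion
    shape = noise.dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_counts(
    profile: MarkerFrequencyProfile,
    noise: NoiseSpec,
    artifact: ArtifactSpec | None = None,
    cmap: ChromosomeMap | None = None,
    rng: np.random.Generator | None = None,
    label: str = "sample",
) -> BinnedCounts:
    """Draw per-bin read counts with mean depth x copy number x depletion."""
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    mult = np.ones(profile.n_bins)
    if artifact is not None:
        if cmap is None:
            raise ValueError("an ArtifactSpec needs the chromosome map")
        mult = _depletion_multiplier(cmap, artifact, profile.bin_size)
    mean = noise.depth * np.where(profile.mask, profile.values, 0.0) * mult
    return BinnedCounts(
        length_bp=profile.length_bp,
        bin_size=profile.bin_size,
        counts=_draw(mean, noise, rng),
        label=label,
    )


def simulate_control(
    cmap: ChromosomeMap,
    noise: NoiseSpec,
    bin_size: int = 1000,
    rng: np.random.Generator | None = None,
) -> BinnedCounts:
    """Stationary-phase control: a non-replicating population has uniform
    copy number, so counts are flat-mean draws."""
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    n = n_bins(cmap.length_bp, bin_size)
    mean = np.full(n, noise.depth)
    return BinnedCounts(
        length_bp=cmap.length_bp,
        bin_size=bin_size,
        counts=_draw(mean, noise, rng),
        label="stationary_control",
    )


# ---------------------------------------------------------------------------
# named scenarios


@dataclass
class ScenarioBundle:
    name: str
    sample: BinnedCounts
    control: BinnedCounts
    truth: dict
    reference_map: ChromosomeMap
    sample_map: ChromosomeMap
    model_profile: MarkerFrequencyProfile | None = None  # reference coords

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_counts(self.sample, outdir / "sample.tsv")
        _io.write_counts(self.control, outdir / "control.tsv")
        _io.write_json(self.truth, outdir / "truth.json")
        write_map_bed(self.sample_map, outdir / "map.bed")


_INV820 = Rearrangement("inversion", 575_000, 1_394_000)
_INV895 = Rearrangement("inversion", 1_394_000, 2_288_000)
_DUP175 = Rearrangement("duplication", 4_020_000, 4_195_000, copies=2)

SCENARIOS = (
    "wild_type",
    "oriC_oriX",
    "oriC_oriX_dtus",
    "doriC_oriX_inv820",
    "doriC_oriX_rpo_inv895",
    "triple_origin_mix",
    "dup175",
)


def _scenario_spec(name: str) -> dict:
    """Scenario recipe: origin set(s), tus status, rearrangement."""
    if name == "wild_type":
        return {"classes": [({"oriC"}, True)], "weights": [1.0]}
    if name == "oriC_oriX":
        return {"classes": [({"oriC", "oriX"}, True)], "weights": [1.0]}
    if name == "oriC_oriX_dtus":
        return {"classes": [({"oriC", "oriX"}, False)], "weights": [1.0]}
    if name == "doriC_oriX_inv820":
        return {
            "classes": [({"oriX"}, True)],
            "weights": [1.0],
            "rearrangement": _INV820,
        }
    if name == "doriC_oriX_rpo_inv895":
        return {
            "classes": [({"oriX"}, True)],
            "weights": [1.0],
            "rearrangement": _INV895,
        }
    if name == "triple_origin_mix":
        # double-origin fractions as observed for the triple-origin strain;
        # the 10% remainder goes to the all-three-origins class
        return {
            "classes": [
                ({"oriC", "oriX"}, True),
                ({"oriC", "oriZ"}, True),
                ({"oriC", "oriX", "oriZ"}, True),
            ],
            "weights": [0.5, 0.4, 0.1],
        }
    if name == "dup175":
        return {
            "classes": [({"oriX"}, False)],
            "weights": [1.0],
            "rearrangement": _DUP175,
        }
    raise ValueError(f"unknown scenario {name!r}; known: {', '.join(SCENARIOS)}")


def generate_scenario(
    name: str,
    seed: int,
    outdir: str | Path | None = None,
    bin_size: int = 1000,
    depth: float = 100.0,
    params: SimulationParams | None = None,
    artifact: ArtifactSpec | None = None,
    with_artifact: bool = True,
) -> ScenarioBundle:
    """Build a named dataset bundle: sample counts, stationary control and
    a truth record for downstream recovery tests.

    The model profile is computed on the scenario's (possibly rearranged)
    chromosome, depleted at artifact loci, projected onto reference
    coordinates as read mapping would, and only then sampled with noise.
    A single seed fans out to independent substreams per stage.
    """
    spec = _scenario_spec(name)
    params = params or SimulationParams()
    if artifact is None and with_artifact:
        artifact = ArtifactSpec()

    # stable across processes (unlike hash()) so bundles are reproducible
    name_key = zlib.crc32(name.encode())
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(name_key,))
    rng_sample, rng_control = (np.random.default_rng(s) for s in ss.spawn(2))

    ref_map = build_default_map()
    all_origins = set().union(*(set(origins) for origins, _ in spec["classes"]))
    ref_map = ref_map.with_active_origins(all_origins)
    rearr: Rearrangement | None = spec.get("rearrangement")
    sample_map = apply_rearrangement(ref_map, rearr) if rearr else ref_map

    schedules = [
        replication_schedule(sample_map, CellClass(origins, tus), params, bin_size)
        for origins, tus in spec["classes"]
    ]
    profiles = [marker_frequency(s, params.tau_min) for s in schedules]
    model = (
        profiles[0]
        if len(profiles) == 1
        else mixture_profile(profiles, spec["weights"])
    )
    # per-bin expected relative depth on the physical (sample) chromosome,
    # including the purification artifact, then mapped to reference coords
    mult = _depletion_multiplier(sample_map, artifact, bin_size)
    expected = MarkerFrequencyProfile(
        length_bp=sample_map.length_bp,
        bin_size=bin_size,
        values=model.values * mult,
        mask=model.mask,
        source="model",
        normalisation="expected_depth",
    )
    expected_ref = project_profile(expected, rearr) if rearr else expected
    model_ref = project_profile(model, rearr) if rearr else model

    noise = NoiseSpec(depth=depth, seed=seed)
    sample = simulate_counts(
        expected_ref, noise, rng=rng_sample, label=f"{name}_sample"
    )
    control = simulate_control(ref_map, noise, bin_size, rng=rng_control)

    truth = {
        "scenario": name,
        "seed": seed,
        "bin_size": bin_size,
        "depth": depth,
        "classes": [
            {"origins": sorted(origins), "tus_active": tus}
            for origins, tus in spec["classes"]
        ],
        "weights": spec["weights"],
        "params": {
            "fork_speed": params.fork_speed,
            "tau_min": params.tau_min,
            "headon_speed_factor": params.headon_speed_factor,
        },
        "breakpoints": list(rearr.breakpoints) if rearr else [],
        "rearrangement": (
            f"{rearr.kind}:{rearr.start_bp}-{rearr.end_bp}" if rearr else None
        ),
        "expected_ter_steps": sorted(
            {e.ter_name for s in schedules for e in s.block_events}
        ),
        "low_point_bp": float(
            model_ref.bin_mids()[np.nanargmin(
                np.where(model_ref.mask, model_ref.values, np.nan)
            )]
        ),
        "artifact_depletion": artifact.depletion_factor if artifact else None,
    }

    bundle = ScenarioBundle(
        name=name,
        sample=sample,
        control=control,
        truth=truth,
        reference_map=ref_map,
        sample_map=sample_map,
        model_profile=model_ref,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
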