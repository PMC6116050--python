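"""Shared fixtures.

Model profiles and the default map are deterministic, so expensive ones are
session-scoped.  Synthetic noisy datasets are generated per test from fixed
seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

import replichore as rp


@pytest.fixture(scope="session")
def default_map():
    return rp.build_default_map()


@pytest.fixture(scope="session")
def params():
    return rp.SimulationParams(fork_speed=1000.0, tau_min=25.0)


@pytest.fixture(scope="session")
def map_cx(default_map):
    return default_map.with_active_origins({"oriC", "oriX"})


@pytest.fixture(scope="session")
def map_cz(default_map):
    return default_map.with_active_origins({"oriC", "oriZ"})


@pytest.fixture(scope="session")
def profile_cx(map_cx, params):
    """oriC+oriX, trap active: the terA-step profile."""
    return rp.class_profile(map_cx, rp.CellClass({"oriC", "oriX"}), params)


@pytest.fixture(scope="session")
def profile_cx_dtus(map_cx, params):
    """oriC+oriX without Tus: symmetrical profile."""
    return rp.class_profile(
        map_cx, rp.CellClass({"oriC", "oriX"}, tus_active=False), params
    )


@pytest.fixture(scope="session")
def smoothed_cx_dtus(profile_cx_dtus):
    return rp.circular_loess(profile_cx_dtus)


@pytest.fixture(scope="session")
def triple_classes():
    return [
        rp.CellClass({"oriC", "oriX"}),
        rp.CellClass({"oriC", "oriZ"}),
        rp.CellClass({"oriC", "oriX", "oriZ"}),
    ]


def small_random_map(rng: np.random.Generator, require_trap: bool = False):
    """A valid random circular map for oracle-equivalence testing.

    Retries until the configuration leaves no unreplicable bin (random
    polar trap placements can strand chromosome segments).
    """
    for _ in range(50):
        L = int(rng.integers(50, 201)) * 1000
        n_ori = int(rng.integers(1, 4))
        ori_pos = rng.choice(L, size=n_ori, replace=False)
        origins = [
            rp.Origin(f"ori{i}", int(p), active=True)
            for i, p in enumerate(sorted(ori_pos))
        ]
        n_ter = int(rng.integers(0, 5)) if not require_trap else int(rng.integers(2, 5))
        ters = [
            rp.TerSite(
                "ABCDEFGHIJ"[i],
                int(rng.integers(0, L)),
                "cw" if rng.random() < 0.5 else "ccw",
            )
            for i in range(n_ter)
        ]
        feats = []
        for i in range(int(rng.integers(0, 3))):
            start = int(rng.integers(0, L - 6000))
            feats.append(
                rp.TranscribedFeature(
                    f"hot{i}",
                    start,
                    start + int(rng.integers(2000, 6000)),
                    "cw" if rng.random() < 0.5 else "ccw",
                )
            )
        cmap = rp.ChromosomeMap(
            name="random",
            length_bp=L,
            origins=origins,
            ter_sites=ters,
            transcribed_features=feats,
        )
        cls = rp.CellClass(
            {o.name for o in origins}, tus_active=bool(rng.random() < 0.7)
        )
        p = rp.SimulationParams(
            fork_speed=float(rng.integers(500, 1501)),
            tau_min=25.0,
            headon_speed_factor=float(rng.choice([1.0, 1.0, 0.5, 0.8])),
        )
        try:
            rp.replication_schedule(cmap, cls, p, 1000)
        except AssertionError:
            continue  # stranded segment; resample
        return cmap, cls, p
    raise RuntimeError("could not build a valid random map")
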