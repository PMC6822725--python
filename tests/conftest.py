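"""Shared fixtures: reference swimmer pipeline and a pool of random feasible swimmers."""

from __future__ import annotations

import numpy as np
import pytest

from undulate.body import build_geometry, build_motion, ShapeParams
from undulate.energetics import integral_report, longitudinal_profiles
from undulate.fixtures import generate_fixture
from undulate.hydro import solve_speed
from undulate.optimize import evaluate
from undulate.structure import bending_moment


@pytest.fixture(scope="session")
def ref_config():
    return generate_fixture(1.0)


@pytest.fixture(scope="session")
def ref_geom(ref_config):
    s = ref_config.swimmer
    return build_geometry(ShapeParams(s.DL, s.BL, s.c_d1, s.c_d2, s.c_b1), s.mass)


@pytest.fixture(scope="session")
def ref_motion(ref_config, ref_geom):
    s = ref_config.swimmer
    return build_motion(ref_geom, s.omega, (s.e0, s.e1, s.e2))


@pytest.fixture(scope="session")
def ref_hydro(ref_geom, ref_motion):
    return solve_speed(ref_geom, ref_motion)[0]


@pytest.fixture(scope="session")
def ref_structural(ref_geom, ref_motion, ref_hydro):
    return bending_moment(ref_geom, ref_motion, ref_hydro.recoil, ref_hydro.U)


@pytest.fixture(scope="session")
def ref_profiles(ref_geom, ref_motion, ref_structural):
    return longitudinal_profiles(ref_geom, ref_motion, ref_structural)


@pytest.fixture(scope="session")
def ref_report(ref_geom, ref_motion, ref_hydro, ref_structural, ref_profiles):
    return integral_report(ref_geom, ref_motion, ref_hydro, ref_structural, ref_profiles)


def _random_feasible_candidates(n, seed, masses=(0.3, 1.0, 3.0)):
    """Randomly perturbed reference swimmers, kept only if feasible."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        m = float(rng.choice(masses))
        cfg = generate_fixture(m).swimmer
        base = np.array(cfg.params)
        x = base * np.exp(rng.normal(0.0, 0.15, base.size))
        cand = evaluate(x, m)
        if cand.feasible:
            out.append(cand)
    return out


@pytest.fixture(scope="session")
def feasible_pool():
    """20 random feasible swimmers spanning a few masses (seeded)."""
    return _random_feasible_candidates(20, seed=42)
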