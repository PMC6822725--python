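"""Two-objective evolutionary optimization of swimmers at fixed body mass.

Objectives: maximize the steady sustained speed U and minimize the cost of
transport COT.  A candidate is feasible when its shape is valid, a steady
speed exists, the muscle activation envelope satisfies mu^ <= 1 everywhere
and the relative contraction rate stays below 1.  The optimal population is
the non-dominated (Pareto) set; its ends are the U-optimal and COT-optimal
swimmers.

The optimizer is an elitist (mu + lambda) evolutionary algorithm with
self-adaptive variation: parents chosen by binary tournament on
(non-domination rank, crowding distance) recombine by simulated binary
crossover (whose step scales with the population spread) followed by
polynomial mutation, and the merged population is truncated by
non-dominated rank with crowding-distance tie-breaks (infeasible candidates
rank behind every feasible one).  An external archive accumulates every
feasible non-dominated point, so the front hypervolume is non-decreasing
over generations.  Runs are fully reproducible from the seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body import InfeasibleMotionError, InvalidShapeError, ShapeParams, build_geometry, build_motion
from .config import PARAM_NAMES
from .constants import Constants, DEFAULT_CONSTANTS
from .energetics import SwimmerReport, integral_report, longitudinal_profiles
from .hydro import NoSteadySpeedError, solve_speed
from .structure import bending_moment

__all__ = [
    "BOUNDS",
    "Candidate",
    "ParetoFront",
    "evaluate",
    "dominates",
    "non_dominated_sort",
    "hypervolume_2d",
    "pareto_optimize",
    "mass_scan",
]

# Search-space bounds for the 9 parameters (5 shape + 4 motion).  The height
# profile can still turn invalid (d <= 0) for adversarial coefficient
# combinations; those candidates are simply infeasible.  Envelope bounds keep
# r(x)/L <= ~0.2 (small-amplitude hydrodynamics).
BOUNDS: dict[str, tuple[float, float]] = {
    "DL": (0.05, 0.35),
    "BL": (0.05, 0.30),
    "c_d1": (-0.04, 0.20),
    "c_d2": (-0.08, 0.08),
    "c_b1": (0.6, 3.0),
    "omega": (0.1, 200.0),
    "e0": (0.0, 0.12),
    "e1": (-0.06, 0.12),
    "e2": (-0.04, 0.08),
}
_LO = np.array([BOUNDS[k][0] for k in PARAM_NAMES])
_HI = np.array([BOUNDS[k][1] for k in PARAM_NAMES])

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Candidate:
    """One evaluated swimmer: parameters, objectives and full report."""

    params: tuple[float, ...]
    U: float
    COT: float
    feasible: bool
    report: SwimmerReport | None = field(repr=False, default=None)
    diagnostic: str = ""


@dataclass(frozen=True)
class ParetoFront:
    """Non-dominated set at one body mass, with its single-objective ends."""

    members: tuple[Candidate, ...]
    mass: float
    hypervolume_history: tuple[float, ...] = ()

    @property
    def U_opt(self) -> Candidate:
        return max(self.members, key=lambda c: c.U)

    @property
    def COT_opt(self) -> Candidate:
        return min(self.members, key=lambda c: c.COT)


def evaluate(
    params,
    mass: float,
    constants: Constants = DEFAULT_CONSTANTS,
    grid_n: int = 256,
    n_quad: int = 1024,
) -> Candidate:
    """Full model evaluation of one parameter vector at the given mass.

    Composition: geometry -> steady-speed solve (with recoil) -> bending
    moment -> longitudinal profiles -> integral report.  Any solver failure
    (invalid shape, no steady speed, closure failure) yields an infeasible
    candidate carrying a diagnostic, never an exception.  Evaluation is
    deterministic.
    """
    p = tuple(float(v) for v in params)
    DL, BL, c_d1, c_d2, c_b1, omega, e0, e1, e2 = p
    try:
        geom = build_geometry(ShapeParams(DL, BL, c_d1, c_d2, c_b1), mass, constants, grid_n)
        motion = build_motion(geom, omega, (e0, e1, e2))
        hydro = solve_speed(geom, motion)[0]
        structural = bending_moment(geom, motion, hydro.recoil, hydro.U)
        profiles = longitudinal_profiles(geom, motion, structural, n_quad)
        report = integral_report(geom, motion, hydro, structural, profiles)
    except (InvalidShapeError, InfeasibleMotionError, NoSteadySpeedError,
            ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
        return Candidate(params=p, U=np.nan, COT=np.nan, feasible=False,
                         diagnostic=f"{type(exc).__name__}: {exc}")
    return Candidate(
        params=p, U=report.U, COT=report.COT, feasible=report.feasible,
        report=report,
        diagnostic="" if report.feasible else "muscle/rate envelope exceeded",
    )


def dominates(a: Candidate, b: Candidate) -> bool:
    """True if a is at least as fast and as cheap as b, and better in one."""
    return (a.U >= b.U and a.COT <= b.COT) and (a.U > b.U or a.COT < b.COT)


def non_dominated_sort(candidates) -> ParetoFront:
    """Extract the Pareto set of the feasible candidates (ties kept)."""
    feas = [c for c in candidates if c.feasible]
    if not feas:
        raise ValueError("no feasible candidate to sort")
    front = [c for c in feas if not any(dominates(o, c) for o in feas)]
    mass = feas[0].report.m if feas[0].report is not None else float("nan")
    return ParetoFront(members=tuple(front), mass=mass)


def hypervolume_2d(points, ref: tuple[float, float]) -> float:
    """Dominated hypervolume of (U, COT) points w.r.t. a reference corner.

    ``ref = (U_ref, COT_ref)`` must be slower and costlier than the region of
    interest; points outside the reference box contribute nothing.
    """
    u0, c0 = ref
    pts = {(u, c) for u, c in points if u > u0 and c < c0}
    pareto: list[tuple[float, float]] = []
    for u, c in sorted(pts, key=lambda p: (-p[0], p[1])):  # U descending
        if not pareto or c < pareto[-1][1]:
            pareto.append((u, c))
    hv, c_prev = 0.0, c0
    for u, c in pareto:
        hv += (u - u0) * (c_prev - c)
        c_prev = c
    return hv


def _crowding(front: list[Candidate]) -> np.ndarray:
    n = len(front)
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for key in (lambda c: c.U, lambda c: c.COT):
        order = np.argsort([key(c) for c in front])
        vals = np.array([key(front[i]) for i in order])
        span = vals[-1] - vals[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (vals[2:] - vals[:-2]) / span
    return dist


def _select(candidates: list[Candidate], k: int) -> list[int]:
    """NSGA-II style truncation: non-dominated rank, then crowding distance.

    Returns indices into ``candidates``; infeasible candidates are ranked
    behind all feasible ones so they never displace a feasible swimmer.
    """
    idx_feas = [i for i, c in enumerate(candidates) if c.feasible]
    idx_inf = [i for i, c in enumerate(candidates) if not c.feasible]
    chosen: list[int] = []
    remaining = idx_feas[:]
    while remaining and len(chosen) < k:
        front = [
            i for i in remaining
            if not any(dominates(candidates[j], candidates[i]) for j in remaining)
        ]
        if len(chosen) + len(front) <= k:
            chosen.extend(front)
        else:
            cd = _crowding([candidates[i] for i in front])
            order = np.argsort(-cd, kind="stable")
            chosen.extend(front[int(o)] for o in order[: k - len(chosen)])
        remaining = [i for i in remaining if i not in set(front)]
    chosen.extend(idx_inf[: k - len(chosen)])
    return chosen


def _sample_initial(rng: np.random.Generator, mass: float, constants, grid_n, n_quad,
                    pop_size: int, max_tries: int) -> list[Candidate]:
    """Rejection-sample a feasible initial population.

    Uniform in the bounds except omega, drawn log-uniformly (the feasible
    frequency window spans decades across body masses).
    """
    pop: list[Candidate] = []
    tries = 0
    while len(pop) < pop_size:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not find {pop_size} feasible initial swimmers in {max_tries} draws"
            )
        tries += 1
        x = _LO + (_HI - _LO) * rng.random(9)
        i_om = PARAM_NAMES.index("omega")
        lo, hi = BOUNDS["omega"]
        x[i_om] = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        cand = evaluate(x, mass, constants, grid_n, n_quad)
        if cand.feasible:
            pop.append(cand)
    return pop


def _ranks_and_crowding(pop: list[Candidate]) -> tuple[np.ndarray, np.ndarray]:
    """Non-domination level and crowding distance for tournament selection."""
    n = len(pop)
    rank = np.full(n, n, dtype=float)
    crowd = np.zeros(n)
    remaining = [i for i in range(n) if pop[i].feasible]
    level = 0
    while remaining:
        front = [
            i for i in remaining
            if not any(dominates(pop[j], pop[i]) for j in remaining)
        ]
        cd = _crowding([pop[i] for i in front])
        for i, d in zip(front, cd):
            rank[i] = level
            crowd[i] = d
        remaining = [i for i in remaining if i not in set(front)]
        level += 1
    return rank, crowd


def _sbx(rng, p1: np.ndarray, p2: np.ndarray, eta: float = 10.0) -> np.ndarray:
    """Simulated binary crossover (one child); step scales with parent spread."""
    u = rng.random(p1.size)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    sign = np.where(rng.random(p1.size) < 0.5, 1.0, -1.0)
    child = 0.5 * ((p1 + p2) + sign * beta * (p1 - p2))
    mask = rng.random(p1.size) < 0.5
    return np.where(mask, child, p1)


def _poly_mutate(rng, x: np.ndarray, eta: float = 20.0, p_m: float = 1.0 / 9.0) -> np.ndarray:
    """Polynomial mutation within the box bounds."""
    u = rng.random(x.size)
    delta = np.where(u < 0.5, (2 * u) ** (1 / (eta + 1)) - 1.0,
                     1.0 - (2 * (1 - u)) ** (1 / (eta + 1)))
    mask = rng.random(x.size) < p_m
    return x + np.where(mask, delta * (_HI - _LO), 0.0)


def pareto_optimize(
    mass: float,
    pop_size: int = 40,
    generations: int = 60,
    seed: int = 0,
    constants: Constants = DEFAULT_CONSTANTS,
    grid_n: int = 256,
    n_quad: int = 1024,
    max_init_tries: int | None = None,
) -> ParetoFront:
    """Evolve a population at fixed mass and return the archived Pareto front.

    Reproducible: the same seed yields the same front.  The returned front
    carries the per-generation hypervolume of the external archive
    (non-decreasing by construction).
    """
    rng = np.random.default_rng(seed)
    if max_init_tries is None:
        max_init_tries = 250 * pop_size
    t0 = time.perf_counter()
    pop = _sample_initial(rng, mass, constants, grid_n, n_quad, pop_size, max_init_tries)
    logger.info("m=%g kg: initial feasible population of %d in %.2f s",
                mass, pop_size, time.perf_counter() - t0)

    archive: list[Candidate] = list(non_dominated_sort(pop).members)
    ref = (0.0, 2.0 * max(c.COT for c in pop))
    hv_hist = [hypervolume_2d([(c.U, c.COT) for c in archive], ref)]

    for _ in range(generations):
        rank, crowd = _ranks_and_crowding(pop)

        def tourney() -> np.ndarray:
            i, j = rng.integers(0, len(pop), 2)
            if (rank[i], -crowd[i]) <= (rank[j], -crowd[j]):
                return np.array(pop[i].params)
            return np.array(pop[j].params)

        offspring: list[Candidate] = []
        for _k in range(pop_size):
            x = _sbx(rng, tourney(), tourney())
            x = np.clip(_poly_mutate(rng, x), _LO, _HI)
            offspring.append(evaluate(x, mass, constants, grid_n, n_quad))
        merged = pop + offspring
        pop = [merged[j] for j in _select(merged, pop_size)]
        feas_children = [c for c in offspring if c.feasible]
        if feas_children:
            archive.extend(feas_children)
            archive = list(non_dominated_sort(archive).members)
        hv_hist.append(hypervolume_2d([(c.U, c.COT) for c in archive], ref))
        logger.debug("m=%g kg gen %d: archive %d, hypervolume %.4g",
                     mass, len(hv_hist) - 1, len(archive), hv_hist[-1])
    logger.info("m=%g kg: %d generations in %.2f s, front size %d",
                mass, generations, time.perf_counter() - t0, len(archive))

    return ParetoFront(members=tuple(archive), mass=mass,
                       hypervolume_history=tuple(hv_hist))


def mass_scan(
    masses,
    pop_size: int = 40,
    generations: int = 60,
    seed: int = 0,
    constants: Constants = DEFAULT_CONSTANTS,
    grid_n: int = 256,
    n_quad: int = 1024,
) -> tuple[pd.DataFrame, dict[float, ParetoFront]]:
    """Optimize every mass on the grid and tabulate the front extremes.

    Returns the summary table (one row per mass and objective end) and the
    fronts themselves.  A mass whose optimization fails is recorded with the
    failure message and the scan continues.  The ``near_transition`` flag
    marks optima holding Re within 5% below the critical Reynolds number,
    the signature of swimmers staying laminar to avoid the drag jump.
    """
    rows = []
    fronts: dict[float, ParetoFront] = {}
    for j, m in enumerate(masses):
        t0 = time.perf_counter()
        try:
            front = pareto_optimize(m, pop_size, generations, seed + j,
                                    constants, grid_n, n_quad)
        except RuntimeError as exc:
            logger.warning("m=%g kg failed after %.2f s: %s", m, time.perf_counter() - t0, exc)
            rows.append({"mass": m, "end": "failed", "error": str(exc)})
            continue
        fronts[m] = front
        for end, cand in (("U", front.U_opt), ("COT", front.COT_opt)):
            r = cand.report
            rows.append({
                "mass": m, "end": end, "U": r.U, "COT": r.COT, "Re": r.Re,
                "branch": r.branch, "eta_M": r.eta_M, "eta_H": r.eta_H,
                "eta_T": r.eta_T, "Psi": r.Psi, "Theta": r.Theta,
                "near_transition": bool(0.95 * constants.Re_cr <= r.Re < constants.Re_cr),
                "error": "",
            })
    return pd.DataFrame(rows), fronts
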