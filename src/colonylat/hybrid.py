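"""Minimal hybrid colony model: discrete bacteria coupled to a nutrient field.

One bacterium at most per lattice site.  Bacteria consume nutrient from
the shared field as point sinks with Monod kinetics, accumulate it in an
internal state ``n``, and once ``n`` exceeds the threshold ``n_g`` place a
daughter on a uniformly chosen empty neighbor site (optionally a
Moore-weighted choice on square lattices), handing it a stochastic share
``n_d ~ U[n/2 - delta, n/2 + delta)`` of the internal nutrient.  Division
events within a time step are executed in a freshly randomized order.

The nutrient field is integrated with the scheme matching the lattice:
five-point differences on square lattices, finite volumes otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rd
from .lattice import Lattice, build_square_lattice

__all__ = [
    "HybridParams",
    "ColonyState",
    "RunResult",
    "monod_uptake",
    "init_colony",
    "consume_step",
    "attempt_division",
    "step_colony",
    "run_colony",
    "run_channel_benchmark",
]


@dataclass(frozen=True)
class HybridParams:
    """Model parameters; defaults are the standard simulation-unit values.

    ``w_d`` enables Moore-mode daughter placement on square lattices: the
    four diagonal neighbors are weighted by ``w_d`` relative to the
    lateral ones.  ``None`` disables Moore mode.
    """

    n_g: float = 1.0
    v_max: float = 0.04
    K: float = 1.0
    c0: float = 1.0
    D_c: float = 0.04
    delta: float = 0.2
    w_d: float | None = None
    dt: float = 1.0
    stop_mean_c: float = 0.01
    stop_occupancy: float = 0.70
    max_steps: int = 200_000

    def __post_init__(self) -> None:
        if min(self.n_g, self.v_max, self.K, self.dt) <= 0:
            raise ValueError("n_g, v_max, K and dt must be positive")
        if self.c0 < 0 or self.D_c < 0:
            raise ValueError("c0 and D_c must be non-negative")
        if not 0 <= self.delta < self.n_g / 2:
            raise ValueError("delta must satisfy 0 <= delta < n_g/2")
        if self.w_d is not None and self.w_d <= 0:
            raise ValueError("w_d must be positive in Moore mode")


def monod_uptake(c, v_max: float, K: float):
    """Saturating uptake rate ``v_max * c / (K + c)``."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = v_max * c / (K + c)
    return float(out) if out.ndim == 0 else out


@dataclass
class ColonyState:
    """Per-site colony state plus the nutrient field.

    Sites are the unit of bookkeeping: ``occupied[i]`` marks a bacterium
    at site ``i`` with internal nutrient ``n[i]``, lineage depth
    ``depth[i]`` (divisions since its founder) and inherited ``label[i]``
    (-1 where unset).  ``active`` is a superset of the bacteria that may
    still have an empty growth-neighbor; it shrinks lazily, which is
    exact because occupied sites never free up.
    """

    lattice: Lattice
    c: np.ndarray
    occupied: np.ndarray
    n: np.ndarray
    depth: np.ndarray
    label: np.ndarray
    active: np.ndarray
    rng: np.random.Generator
    step_count: int = 0
    clamp_events: int = 0

    @property
    def population(self) -> int:
        return int(np.count_nonzero(self.occupied))

    @property
    def occupancy_fraction(self) -> float:
        return self.population / self.lattice.n_sites

    def mean_concentration(self) -> float:
        a = self.lattice.cell_area
        return float(np.dot(a, self.c) / a.sum())

    def bacteria_sites(self) -> np.ndarray:
        return np.nonzero(self.occupied)[0]

    def total_internal(self) -> float:
        return float(self.n[self.occupied].sum())


@dataclass
class RunResult:
    """Final state plus per-interval time series."""

    state: ColonyState
    steps: list = field(default_factory=list)
    population: list = field(default_factory=list)
    mean_c: list = field(default_factory=list)
    occupancy: list = field(default_factory=list)
    stop_reason: str = "max_steps"


def init_colony(
    lattice: Lattice,
    params: HybridParams,
    rng: np.random.Generator,
    founder_sites=None,
    founder_labels=None,
) -> ColonyState:
    """Uniform field at ``c0`` with founders (default: one bacterium with
    ``n = 0`` at the site nearest the domain center)."""
    N = lattice.n_sites
    if founder_sites is None:
        center = np.asarray(lattice.points.domain) / 2.0
        founder_sites = [int(np.argmin(((lattice.coords - center) ** 2).sum(axis=1)))]
    founder_sites = np.asarray(founder_sites, dtype=np.int64)
    occupied = np.zeros(N, dtype=bool)
    occupied[founder_sites] = True
    n = np.zeros(N)
    depth = np.zeros(N, dtype=np.int64)
    label = np.full(N, -1, dtype=np.int64)
    if founder_labels is not None:
        label[founder_sites] = np.asarray(founder_labels, dtype=np.int64)
    active = occupied.copy()
    c = np.full(N, float(params.c0))
    return ColonyState(lattice, c, occupied, n, depth, label, active, rng)


def consume_step(state: ColonyState, params: HybridParams) -> None:
    """One RD step with bacteria as point sinks; internal states gain what
    the field loses (both evaluated at the pre-step concentration)."""
    f = monod_uptake(state.c, params.v_max, params.K)
    sink = np.where(state.occupied, f, 0.0)
    if state.lattice.kind == "square":
        res = rd.step_square(state.lattice, state.c, params.D_c, params.dt, sink)
    else:
        res = rd.step_finite_volume(state.lattice, state.c, params.D_c, params.dt, sink)
    if rd.detect_divergence(res.values):
        raise FloatingPointError("nutrient field diverged; reduce dt")
    state.n[state.occupied] += params.dt * f[state.occupied]
    state.c = res.values
    state.clamp_events += res.n_clamped


def attempt_division(state: ColonyState, site: int, params: HybridParams) -> int:
    """Try to divide the bacterium at ``site``; returns the daughter site
    or -1.  With no empty growth-neighbor the bacterium is left unchanged
    (and dropped from the active set, permanently: sites never empty)."""
    indptr, indices, weights = state.lattice.growth_csr(params.w_d)
    nbrs = indices[indptr[site] : indptr[site + 1]]
    wts = weights[indptr[site] : indptr[site + 1]]
    empty = ~state.occupied[nbrs]
    if not empty.any():
        state.active[site] = False
        return -1
    cand = nbrs[empty]
    w = wts[empty]
    if len(cand) == 1:
        target = int(cand[0])
    else:
        target = int(state.rng.choice(cand, p=w / w.sum()))
    n_par = state.n[site]
    n_d = state.rng.uniform(n_par / 2 - params.delta, n_par / 2 + params.delta)
    state.occupied[target] = True
    state.active[target] = True
    state.n[target] = n_d
    state.n[site] = n_par - n_d
    state.depth[target] = state.depth[site] + 1
    state.label[target] = state.label[site]
    return target


def step_colony(state: ColonyState, params: HybridParams) -> None:
    """One full time step: consume/diffuse, then process all
    ready-to-divide bacteria in a fresh random order (placements are
    visible to later divisions within the same step)."""
    consume_step(state, params)
    ready = np.nonzero(state.active & (state.n > params.n_g))[0]
    if len(ready):
        for site in state.rng.permutation(ready):
            if state.n[site] > params.n_g:  # may drop below after a split
                attempt_division(state, int(site), params)
    state.step_count += 1


def _run(state: ColonyState, params: HybridParams, record_every: int) -> RunResult:
    result = RunResult(state)

    def record():
        result.steps.append(state.step_count)
        result.population.append(state.population)
        result.mean_c.append(state.mean_concentration())
        result.occupancy.append(state.occupancy_fraction)

    record()
    for _ in range(params.max_steps):
        step_colony(state, params)
        if state.step_count % record_every == 0:
            record()
        if state.mean_concentration() < params.stop_mean_c:
            result.stop_reason = "mean_c"
            break
        if state.occupancy_fraction >= params.stop_occupancy:
            result.stop_reason = "occupancy"
            break
    if result.steps[-1] != state.step_count:
        record()
    return result


def run_colony(
    lattice: Lattice,
    params: HybridParams,
    seed=None,
    founder_sites=None,
    founder_labels=None,
    record_every: int = 50,
) -> RunResult:
    """Run from founders until a stop criterion (mean concentration below
    ``stop_mean_c``, occupancy at least ``stop_occupancy``) or step cap."""
    rng = np.random.default_rng(seed)
    state = init_colony(lattice, params, rng, founder_sites, founder_labels)
    return _run(state, params, record_every)


def run_channel_benchmark(
    params: HybridParams,
    width: int,
    height: int,
    n_founders: int = 200,
    seed=None,
    record_every: int = 50,
) -> RunResult:
    """Channel geometry: periodic left/right boundaries, zero-flux walls
    top and bottom; ``n_founders`` bacteria seeded on the bottom row,
    labeled half 0 ("blue") and half 1 ("red"), labels inherited."""
    if n_founders > width:
        raise ValueError("more founders than bottom-row sites")
    lattice = build_square_lattice(width, height, 1.0, periodic=(True, False))
    rng = np.random.default_rng(seed)
    cols = rng.choice(width, size=n_founders, replace=False)
    sites = cols * height  # iy = 0 row
    labels = rng.permutation(
        np.repeat([0, 1], [n_founders - n_founders // 2, n_founders // 2])
    )
    state = init_colony(lattice, params, rng, sites, labels)
    return _run(state, params, record_every)
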