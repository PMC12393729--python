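"""Continuum colony model with degenerate nonlinear diffusion.

Three fields live on the lattice sites: active bacteria ``b`` (mobile,
with density-dependent diffusivity ``D0 * b``), inactive bacteria ``s``
(immobile, produced from ``b`` at rate ``mu``), and a nutrient ``n``
(linear diffusion with unit coefficient, consumed at rate ``b * n``):

    db/dt = div(D0 b grad b) + n b - mu b
    dn/dt = lap n - b n
    ds/dt = mu b

Forward Euler in time, finite volumes in space.  The interface value of
``b`` in the nonlinear flux is the arithmetic mean by default (harmonic
and upwind variants are provided for sensitivity checks).  All boundaries
are zero flux.  The sum ``sum_i A_i (b + s + n)`` is conserved exactly
per step, before clamping of negative undershoots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import Lattice
from .rd import detect_divergence

__all__ = [
    "KitsunezakiParams",
    "KitsunezakiState",
    "init_kitsunezaki",
    "step_kitsunezaki",
    "run_kitsunezaki",
    "total_mass",
    "instability_sweep",
]


@dataclass(frozen=True)
class KitsunezakiParams:
    D0: float = 0.1
    mu: float = 0.15
    dt: float = 0.1
    interface: str = "arithmetic"  # or "harmonic", "upwind"
    divergence_bound: float = 1e6
    # Clamping negative undershoots stabilizes even a linearly unstable
    # scheme, so instability scans must run with clamp=False.
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.D0 < 0 or self.mu < 0 or self.dt <= 0:
            raise ValueError("require D0, mu >= 0 and dt > 0")
        if self.interface not in ("arithmetic", "harmonic", "upwind"):
            raise ValueError(f"unknown interface scheme {self.interface!r}")


@dataclass
class KitsunezakiState:
    lattice: Lattice
    b: np.ndarray
    s: np.ndarray
    n: np.ndarray
    params: KitsunezakiParams
    step_count: int = 0
    clamp_events: int = 0
    diverged: bool = False
    first_divergence_step: int | None = None


def total_mass(state: KitsunezakiState) -> float:
    """``sum_i A_i (b_i + s_i + n_i)`` -- conserved by the dynamics."""
    return float(np.dot(state.lattice.cell_area, state.b + state.s + state.n))


def init_kitsunezaki(
    lattice: Lattice,
    params: KitsunezakiParams | None = None,
    init_disk_radius: float = 5.0,
    n0: float = 1.0,
    center: tuple[float, float] | None = None,
) -> KitsunezakiState:
    """Disk of ``b = 1`` of the given radius at the domain center,
    ``n = n0`` everywhere, ``s = 0``."""
    params = params or KitsunezakiParams()
    if center is None:
        center = tuple(np.asarray(lattice.points.domain) / 2.0)
    r2 = ((lattice.coords - np.asarray(center)) ** 2).sum(axis=1)
    b = np.where(r2 <= init_disk_radius**2, 1.0, 0.0)
    if b.sum() == 0:
        raise ValueError("initial disk contains no lattice site")
    return KitsunezakiState(
        lattice=lattice,
        b=b,
        s=np.zeros(lattice.n_sites),
        n=np.full(lattice.n_sites, float(n0)),
        params=params,
    )


def _interface_value(bi: np.ndarray, bj: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "arithmetic":
        return 0.5 * (bi + bj)
    if scheme == "harmonic":
        tot = bi + bj
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(tot > 0, 2.0 * bi * bj / np.where(tot > 0, tot, 1.0), 0.0)
        return out
    # upwind: donor cell is the one material flows out of (the larger b)
    return np.maximum(bi, bj)


def step_kitsunezaki(state: KitsunezakiState, *, clamp: bool | None = None) -> None:
    """One forward-Euler update of all three fields (in place)."""
    p = state.params
    if clamp is None:
        clamp = p.clamp
    lat = state.lattice
    b, s, n = state.b, state.s, state.n
    i, j = lat.edges[:, 0], lat.edges[:, 1]
    coef = lat.wall_length / lat.distance

    bbar = _interface_value(b[i], b[j], p.interface)
    flux = p.D0 * bbar * (b[j] - b[i]) * coef  # flow into i when b_j > b_i
    db = np.zeros_like(b)
    np.add.at(db, i, flux)
    np.add.at(db, j, -flux)

    b_new = b + p.dt / lat.cell_area * db + p.dt * (n * b - p.mu * b)
    n_new = n + p.dt / lat.cell_area * (lat.laplacian() @ n) - p.dt * b * n
    s_new = s + p.dt * p.mu * b

    if clamp:
        for arr in (b_new, n_new, s_new):
            neg = arr < 0
            cnt = int(np.count_nonzero(neg))
            if cnt:
                arr[neg] = 0.0
                state.clamp_events += cnt
    state.b, state.s, state.n = b_new, s_new, n_new
    state.step_count += 1
    if not state.diverged and (
        detect_divergence(b_new, p.divergence_bound)
        or detect_divergence(n_new, p.divergence_bound)
    ):
        state.diverged = True
        state.first_divergence_step = state.step_count


def run_kitsunezaki(
    lattice: Lattice,
    steps: int,
    params: KitsunezakiParams | None = None,
    init_disk_radius: float = 5.0,
    n0: float = 1.0,
    center: tuple[float, float] | None = None,
    stop_on_divergence: bool = True,
) -> KitsunezakiState:
    """Integrate for ``steps`` steps (stopping early once divergence is
    flagged, by default)."""
    state = init_kitsunezaki(lattice, params, init_disk_radius, n0, center)
    for _ in range(steps):
        step_kitsunezaki(state)
        if state.diverged and stop_on_divergence:
            break
    return state


def instability_sweep(
    l0_values=(0.3, 0.4, 0.5),
    n_seeds: int = 5,
    n_cells: int = 64,
    dt: float = 0.1,
    steps: int = 2000,
    master_seed: int = 0,
) -> dict[float, list[bool]]:
    """Forward-Euler stability scan over restricted-VRL minimum
    separations.

    For each ``l0``, generate ``n_seeds`` fresh restricted VRLs
    (``n_cells`` x ``n_cells`` reference cells, rescaled to unit mean
    spacing) and integrate the standard initial condition with time step
    ``dt`` for up to ``steps`` steps, *without* clamping (clamping
    suppresses the oscillatory blow-up).  Returns the per-seed divergence
    flags keyed by ``l0``.
    """
    from .lattice import VrlParams, build_restricted_vrl, rescale_to_unit_spacing

    seeds = np.random.SeedSequence(master_seed).spawn(len(l0_values) * n_seeds)
    out: dict[float, list[bool]] = {}
    k = 0
    for l0 in l0_values:
        flags = []
        for _ in range(n_seeds):
            lat = rescale_to_unit_spacing(
                build_restricted_vrl(VrlParams(n_cells, n_cells, l0, seed=seeds[k]))
            )
            k += 1
            state = run_kitsunezaki(
                lat, steps, KitsunezakiParams(dt=dt, clamp=False)
            )
            flags.append(bool(state.diverged))
        out[float(l0)] = flags
    return out
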