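"""Dense 2D bidisperse WCA fluid, snapshotted into lattice point sets.

A 1:1 mixture of soft disks (diameter ratio 1.25, equal masses) is
equilibrated with velocity-Verlet molecular dynamics and a Langevin
thermostat in a periodic square box at area fraction ``phi``.  The
purely repulsive WCA pair potential is

    u(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ] + eps,   r < 2^(1/6) sigma,

and zero beyond the cutoff, with ``sigma = (d_i + d_j) / 2``.  The
bidispersity frustrates crystallization at high density, so a snapshot
of particle centers makes an isotropic, liquid-like disordered point set
with a well-behaved minimum separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .lattice import PointSet, lattice_from_points

__all__ = [
    "FluidParams",
    "FluidState",
    "wca_energy_force",
    "run_fluid",
    "snapshot_to_points",
    "hexatic_order",
]

RCUT_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class FluidParams:
    """MD run parameters (reduced units: small diameter, eps, mass = 1)."""

    n_particles: int = 40_000
    size_ratio: float = 1.25
    area_fraction: float = 0.7
    kT_over_eps: float = 2.5
    dt: float = 2e-3
    equilibration_steps: int = 200_000
    friction: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles % 2:
            raise ValueError("n_particles must be even (1:1 stoichiometry)")
        if not 0 < self.area_fraction < 0.9:
            raise ValueError("area fraction must lie in (0, 0.9)")
        if self.size_ratio < 1:
            raise ValueError("size ratio must be >= 1")

    @property
    def box_side(self) -> float:
        n = self.n_particles
        disk_area = (math.pi / 4.0) * (n / 2) * (1.0 + self.size_ratio**2)
        return math.sqrt(disk_area / self.area_fraction)


@dataclass
class FluidState:
    """Positions/velocities wrapped into the periodic box ``[0, L)^2``."""

    positions: np.ndarray
    velocities: np.ndarray
    diameters: np.ndarray
    box_side: float
    kinetic_temperature_trace: np.ndarray
    potential_energy: float

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def kinetic_temperature(self) -> float:
        return float((self.velocities**2).sum() / (2.0 * self.n))


def wca_energy_force(r, sigma, eps: float = 1.0):
    """WCA pair energy and scalar force ``-du/dr`` at separation ``r``.

    Both are zero at and beyond the cutoff ``2^(1/6) sigma``; the energy
    is continuous there by the ``+eps`` shift.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    sigma = np.asarray(sigma, dtype=float)
    s6 = (sigma / r) ** 6
    inside = r < RCUT_FACTOR * sigma
    u = np.where(inside, 4.0 * eps * (s6**2 - s6) + eps, 0.0)
    f = np.where(inside, 24.0 * eps * (2.0 * s6**2 - s6) / r, 0.0)
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


@njit(cache=True)
def _forces(pos, diam, L, rcut_max, forces):
    """WCA forces via a linked-cell list; returns total potential energy."""
    n = pos.shape[0]
    forces[:] = 0.0
    pe = 0.0
    ncx = int(L / rcut_max)
    if ncx < 4:
        # tiny box: all pairs
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dx -= L * round(dx / L)
                dy -= L * round(dy / L)
                sigma = 0.5 * (diam[i] + diam[j])
                rc = RCUT_FACTOR * sigma
                r2 = dx * dx + dy * dy
                if r2 < rc * rc:
                    s2 = sigma * sigma / r2
                    s6 = s2 * s2 * s2
                    pe += 4.0 * (s6 * s6 - s6) + 1.0
                    fr = 24.0 * (2.0 * s6 * s6 - s6) / r2
                    forces[i, 0] += fr * dx
                    forces[i, 1] += fr * dy
                    forces[j, 0] -= fr * dx
                    forces[j, 1] -= fr * dy
        return pe
    cs = L / ncx
    head = np.full(ncx * ncx, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cs) % ncx
        cy = int(pos[i, 1] / cs) % ncx
        c = cx * ncx + cy
        nxt[i] = head[c]
        head[c] = i
    for cx in range(ncx):
        for cy in range(ncx):
            i = head[cx * ncx + cy]
            while i >= 0:
                for ox in range(-1, 2):
                    for oy in range(-1, 2):
                        c2 = ((cx + ox) % ncx) * ncx + (cy + oy) % ncx
                        j = head[c2]
                        while j >= 0:
                            if j > i:
                                dx = pos[i, 0] - pos[j, 0]
                                dy = pos[i, 1] - pos[j, 1]
                                dx -= L * round(dx / L)
                                dy -= L * round(dy / L)
                                sigma = 0.5 * (diam[i] + diam[j])
                                rc = RCUT_FACTOR * sigma
                                r2 = dx * dx + dy * dy
                                if r2 < rc * rc:
                                    s2 = sigma * sigma / r2
                                    s6 = s2 * s2 * s2
                                    pe += 4.0 * (s6 * s6 - s6) + 1.0
                                    fr = 24.0 * (2.0 * s6 * s6 - s6) / r2
                                    forces[i, 0] += fr * dx
                                    forces[i, 1] += fr * dy
                                    forces[j, 0] -= fr * dx
                                    forces[j, 1] -= fr * dy
                            j = nxt[j]
                i = nxt[i]
    return pe


@njit(cache=True)
def _md_run(pos, vel, diam, L, kT, gamma, dt, nsteps, seed, sample_every):
    """Velocity-Verlet + Langevin (OU velocity update after each step).

    Returns per-sample kinetic temperature and total (kinetic+potential)
    energy traces and the final potential energy.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    rcut_max = RCUT_FACTOR * diam.max()
    forces = np.zeros((n, 2))
    pe = _forces(pos, diam, L, rcut_max, forces)
    c1 = math.exp(-gamma * dt) if gamma > 0 else 1.0
    c2 = math.sqrt(kT * (1.0 - c1 * c1)) if gamma > 0 else 0.0
    nsamp = nsteps // sample_every if sample_every > 0 else 0
    temp_trace = np.empty(nsamp)
    etot_trace = np.empty(nsamp)
    for step in range(nsteps):
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            pos[i, 0] = (pos[i, 0] + dt * vel[i, 0]) % L
            pos[i, 1] = (pos[i, 1] + dt * vel[i, 1]) % L
        pe = _forces(pos, diam, L, rcut_max, forces)
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
        if gamma > 0:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * np.random.normal()
                vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.normal()
        if sample_every > 0 and (step + 1) % sample_every == 0:
            ke = 0.0
            for i in range(n):
                ke += 0.5 * (vel[i, 0] ** 2 + vel[i, 1] ** 2)
            k = (step + 1) // sample_every - 1
            temp_trace[k] = ke / n  # 2D, unit mass: kT = KE / N
            etot_trace[k] = ke + pe
        if pe > 1e3 * n:
            return temp_trace, etot_trace, pe, step + 1
    return temp_trace, etot_trace, pe, nsteps


def _initial_configuration(params: FluidParams, rng: np.random.Generator):
    n = params.n_particles
    L = params.box_side
    ngrid = math.ceil(math.sqrt(n))
    spacing = L / ngrid
    ij = np.arange(ngrid)
    gx, gy = np.meshgrid(ij, ij, indexing="ij")
    grid = (np.column_stack([gx.ravel(), gy.ravel()])[:n] + 0.5) * spacing
    pos = np.mod(grid + rng.uniform(-0.1, 0.1, size=(n, 2)) * spacing, L)
    diam = np.full(n, 1.0)
    diam[rng.permutation(n)[: n // 2]] = params.size_ratio
    vel = rng.normal(0.0, math.sqrt(params.kT_over_eps), size=(n, 2))
    vel -= vel.mean(axis=0)
    return pos, vel, diam


def run_fluid(
    params: FluidParams, sample_every: int = 100, *, check_equilibration: bool = True
) -> FluidState:
    """Equilibrate a fluid at ``kT/eps`` and return the final state.

    Raises ``FloatingPointError`` if the integration blows up (potential
    energy above ``1e3 eps`` per particle), and ``RuntimeError`` if the
    mean kinetic temperature over the last 20% of the run deviates from
    the target by more than 2%.
    """
    rng = np.random.default_rng(params.seed)
    pos, vel, diam = _initial_configuration(params, rng)
    seed = int(rng.integers(0, 2**31 - 1))
    temp, etot, pe, steps_done = _md_run(
        pos,
        vel,
        diam,
        params.box_side,
        params.kT_over_eps,
        params.friction,
        params.dt,
        params.equilibration_steps,
        seed,
        sample_every,
    )
    if steps_done < params.equilibration_steps:
        raise FloatingPointError(
            "fluid integration unstable; decrease the time step"
        )
    if check_equilibration and len(temp) >= 5:
        tail = temp[-max(1, len(temp) // 5) :]
        if abs(tail.mean() - params.kT_over_eps) > 0.02 * params.kT_over_eps:
            raise RuntimeError(
                f"kinetic temperature {tail.mean():.3f} not within 2% of "
                f"target {params.kT_over_eps}"
            )
    return FluidState(pos, vel, diam, params.box_side, temp, pe)


def snapshot_to_points(state: FluidState) -> PointSet:
    """Particle centers as a periodic point set (diameters discarded)."""
    L = state.box_side
    return PointSet(np.mod(state.positions, L), (L, L), (True, True))


def hexatic_order(points: PointSet) -> float:
    """Global bond-orientational order ``|mean_i psi6_i|`` with
    ``psi6_i = mean over Voronoi neighbors of exp(6 i theta_ij)``;
    near 1 for a crystal, small for a liquid."""
    lat = lattice_from_points(points)
    indptr, indices, _ = lat.adjacency_csr()
    coords = lat.coords
    psi = np.zeros(points.n, dtype=complex)
    from .lattice import minimum_image

    for i in range(points.n):
        nbrs = indices[indptr[i] : indptr[i + 1]]
        disp = minimum_image(coords[nbrs] - coords[i], points.domain, points.periodic)
        theta = np.arctan2(disp[:, 1], disp[:, 0])
        psi[i] = np.exp(6j * theta).mean()
    return float(abs(psi.mean()))
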