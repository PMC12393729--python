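"""Equilibrium Monte Carlo of motile, mutually adhesive bacteria.

A fixed number of bacteria occupy lattice sites (at most one per site;
no division).  The configuration energy, in units of the thermal energy,
is ``H = -J * sum of shared Voronoi wall lengths over occupied neighbor
pairs`` (each pair counted once).  Trial moves pick a uniform bacterium
and a uniform neighbor site of its current site; moves to occupied sites
are rejected outright, otherwise accepted with the degree-corrected
Metropolis-Hastings probability

    acc(o -> n) = min[1, (N_o / N_n) * exp(-dH)],

where ``N_o`` and ``N_n`` are the lattice neighbor counts of the old and
new site.  The ``N_o/N_n`` factor compensates the asymmetric proposal on
graphs of variable degree and restores detailed balance with respect to
the Boltzmann distribution.  A literal variant with the ratio inside the
exponent is available behind a flag for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .lattice import Lattice

__all__ = [
    "AdhesionConfig",
    "MCResult",
    "adhesion_energy",
    "delta_energy",
    "acceptance_probability",
    "mc_run",
    "disk_sites",
    "square_sites",
]


@dataclass
class AdhesionConfig:
    """Occupancy set on a fixed lattice with adhesion strength ``J``
    (energy per unit contact length, in units of kT)."""

    lattice: Lattice
    occupied: np.ndarray
    J: float = 4.0
    trials_done: int = 0

    def __post_init__(self) -> None:
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.occupied.shape != (self.lattice.n_sites,):
            raise ValueError("occupied must be a boolean per-site array")

    @property
    def n_bacteria(self) -> int:
        return int(np.count_nonzero(self.occupied))

    def sites(self) -> np.ndarray:
        return np.nonzero(self.occupied)[0]


def adhesion_energy(config: AdhesionConfig) -> float:
    """Total energy ``-J * sum L_ij`` over occupied neighbor pairs."""
    occ = config.occupied
    e = config.lattice.edges
    both = occ[e[:, 0]] & occ[e[:, 1]]
    return float(-config.J * config.lattice.wall_length[both].sum())


def delta_energy(config: AdhesionConfig, site_old: int, site_new: int) -> float:
    """Energy change of moving the bacterium at ``site_old`` to the empty
    site ``site_new``, computed from local contacts only."""
    if config.occupied[site_new]:
        raise ValueError("target site is occupied")
    if not config.occupied[site_old]:
        raise ValueError("no bacterium at the source site")
    indptr, indices, eid = config.lattice.adjacency_csr()
    walls = config.lattice.wall_length
    dH = 0.0
    for k in range(indptr[site_old], indptr[site_old + 1]):
        if config.occupied[indices[k]]:
            dH += config.J * walls[eid[k]]  # contacts lost
    for k in range(indptr[site_new], indptr[site_new + 1]):
        nb = indices[k]
        if config.occupied[nb] and nb != site_old:
            dH -= config.J * walls[eid[k]]  # contacts gained
    return dH


def acceptance_probability(
    dH: float, N_o: int, N_n: int, *, literal_exponent: bool = False
) -> float:
    """Degree-corrected acceptance probability.

    Default: Hastings prefactor ``min[1, (N_o/N_n) exp(-dH)]``.  With
    ``literal_exponent`` the ratio multiplies the energy difference
    inside the exponential instead.
    """
    if N_o <= 0 or N_n <= 0:
        raise ValueError("neighbor counts must be positive")
    if literal_exponent:
        return min(1.0, math.exp(-dH * N_o / N_n))
    return min(1.0, (N_o / N_n) * math.exp(-dH))


@dataclass
class MCResult:
    config: AdhesionConfig
    energy: float
    energy_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    accepted: int = 0
    state_visits: dict | None = None


@njit(cache=True)
def _mc_kernel(
    indptr,
    indices,
    walls,
    occ,
    sites,
    J,
    n_trials,
    seed,
    sample_every,
    literal_exponent,
    count_states,
):
    np.random.seed(seed)
    Nb = sites.shape[0]
    E = 0.0
    accepted = 0
    n_samples = n_trials // sample_every if sample_every > 0 else 0
    trace = np.empty(n_samples)
    visits = np.zeros(1 << occ.shape[0] if count_states else 1, dtype=np.int64)
    code = 0
    if count_states:
        for s in range(occ.shape[0]):
            if occ[s]:
                code += 1 << s
    for t in range(n_trials):
        b = np.random.randint(0, Nb)
        so = sites[b]
        deg_o = indptr[so + 1] - indptr[so]
        sn = indices[indptr[so] + np.random.randint(0, deg_o)]
        if not occ[sn]:
            dH = 0.0
            for k in range(indptr[so], indptr[so + 1]):
                if occ[indices[k]]:
                    dH += J * walls[k]
            for k in range(indptr[sn], indptr[sn + 1]):
                nb = indices[k]
                if occ[nb] and nb != so:
                    dH -= J * walls[k]
            deg_n = indptr[sn + 1] - indptr[sn]
            if literal_exponent:
                a = math.exp(-dH * deg_o / deg_n)
            else:
                a = (deg_o / deg_n) * math.exp(-dH)
            if a >= 1.0 or np.random.random() < a:
                occ[so] = False
                occ[sn] = True
                sites[b] = sn
                E += dH
                accepted += 1
                if count_states:
                    code += (1 << sn) - (1 << so)
        if count_states:
            visits[code] += 1
        if sample_every > 0 and (t + 1) % sample_every == 0:
            trace[(t + 1) // sample_every - 1] = E
    return E, accepted, trace, visits


def mc_run(
    config: AdhesionConfig,
    n_trials: int,
    seed: int | None = None,
    sample_every: int = 0,
    *,
    literal_exponent: bool = False,
    count_states: bool = False,
) -> MCResult:
    """Run ``n_trials`` trial moves; returns the updated configuration,
    the incremental energy trace (relative energies are exact; the trace
    is offset so its last entry matches a full recomputation), and,
    optionally (small lattices only), per-state visit counts keyed by
    occupancy bitmask."""
    if count_states and config.lattice.n_sites > 20:
        raise ValueError("state counting is only supported on small lattices")
    indptr, indices, eid = config.lattice.adjacency_csr()
    walls = config.lattice.wall_length[eid]
    occ = config.occupied.copy()
    sites = np.nonzero(occ)[0].astype(np.int64)
    e0 = adhesion_energy(config)
    seed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    dE, accepted, trace, visits = _mc_kernel(
        indptr,
        indices,
        walls,
        occ,
        sites,
        float(config.J),
        int(n_trials),
        seed,
        int(sample_every),
        literal_exponent,
        count_states,
    )
    out = AdhesionConfig(
        config.lattice, occ, config.J, trials_done=config.trials_done + n_trials
    )
    state_visits = None
    if count_states:
        nz = np.nonzero(visits)[0]
        state_visits = {int(c): int(visits[c]) for c in nz}
    return MCResult(
        config=out,
        energy=e0 + dE,
        energy_trace=e0 + trace,
        accepted=accepted,
        state_visits=state_visits,
    )


def disk_sites(lattice: Lattice, radius: float, center=None) -> np.ndarray:
    """Sites within ``radius`` of the domain center (or ``center``)."""
    if center is None:
        center = np.asarray(lattice.points.domain) / 2.0
    r2 = ((lattice.coords - np.asarray(center)) ** 2).sum(axis=1)
    return np.nonzero(r2 <= radius**2)[0]


def square_sites(lattice: Lattice, radius: float, center=None) -> np.ndarray:
    """Sites in an axis-aligned square of side ``sqrt(pi) * radius``
    (same area as the disk of that radius) about the domain center."""
    if center is None:
        center = np.asarray(lattice.points.domain) / 2.0
    half = math.sqrt(math.pi) * radius / 2.0
    d = np.abs(lattice.coords - np.asarray(center))
    return np.nonzero((d[:, 0] <= half) & (d[:, 1] <= half))[0]
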