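"""Lattice-quality statistics: separation/area PDFs and pair distribution.

The angular pair distribution ``rho2(r, theta)`` estimates the density
of ordered site pairs at separation ``(r, theta)`` from minimum-image
displacements; for an isotropic point set it factorizes into
``rho^2 g(r)`` with no theta dependence.  ``anisotropy_score`` condenses
the theta dependence into a single number calibrated against counting
noise (approximately standard normal, clipped at zero, for isotropic
input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .lattice import Lattice, PointSet, minimum_image

__all__ = [
    "Histogram1D",
    "PairDistribution",
    "AnisotropyResult",
    "neighbor_distance_pdf",
    "cell_area_pdf",
    "pair_distribution",
    "anisotropy_score",
]


@dataclass(frozen=True)
class Histogram1D:
    """Normalized density over bins: ``sum(density * widths) == 1``."""

    bin_edges: np.ndarray
    density: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean(self) -> float:
        w = np.diff(self.bin_edges)
        return float(np.sum(self.bin_centers * self.density * w))

    def variance(self) -> float:
        w = np.diff(self.bin_edges)
        m = self.mean()
        return float(np.sum((self.bin_centers - m) ** 2 * self.density * w))


def neighbor_distance_pdf(lattice: Lattice, bins=60) -> Histogram1D:
    """PDF of neighbor separations ``d_ij`` (each edge counted once)."""
    if lattice.n_edges == 0:
        raise ValueError("lattice has no edges")
    dens, edges = np.histogram(lattice.distance, bins=bins, density=True)
    return Histogram1D(edges, dens)


def cell_area_pdf(lattice: Lattice, bins=60) -> Histogram1D:
    """PDF of Voronoi cell areas ``A_i``."""
    dens, edges = np.histogram(lattice.cell_area, bins=bins, density=True)
    return Histogram1D(edges, dens)


@dataclass(frozen=True)
class PairDistribution:
    """Binned ``rho2(r, theta)`` plus the raw ordered-pair counts."""

    r_edges: np.ndarray
    theta_edges: np.ndarray
    density: np.ndarray  # (nr, ntheta)
    counts: np.ndarray  # (nr, ntheta) ordered-pair counts
    rho: float  # overall number density N / A

    @property
    def g_of_r(self) -> np.ndarray:
        """Angle-averaged pair correlation ``g(r)``."""
        return self.density.mean(axis=1) / self.rho**2


def pair_distribution(
    points: PointSet, r_max: float, nr: int = 100, ntheta: int = 72
) -> PairDistribution:
    """Estimate ``rho2(r, theta)`` for a periodic point set.

    The ensemble average is taken over reference sites of the single
    configuration (self-averaging).  Both orderings of each pair are
    counted, so the theta marginal covers ``[0, 2*pi)``.
    """
    if not all(points.periodic):
        raise ValueError("pair distribution requires a periodic point set")
    w, h = points.domain
    if r_max >= min(w, h) / 2:
        raise ValueError("r_max must be below half the box side")
    coords = np.mod(points.coords, (w, h))
    tree = cKDTree(coords, boxsize=(w, h))
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    disp = minimum_image(
        coords[pairs[:, 1]] - coords[pairs[:, 0]], points.domain, points.periodic
    )
    r = np.linalg.norm(disp, axis=1)
    th = np.arctan2(disp[:, 1], disp[:, 0])
    r2 = np.concatenate([r, r])
    th2 = np.concatenate([th, np.arctan2(-disp[:, 1], -disp[:, 0])])
    th2 = np.mod(th2, 2 * np.pi)
    r_edges = np.linspace(0.0, r_max, nr + 1)
    t_edges = np.linspace(0.0, 2 * np.pi, ntheta + 1)
    counts, _, _ = np.histogram2d(r2, th2, bins=[r_edges, t_edges])
    area = w * h
    shell = 0.5 * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)  # times dtheta below
    bin_area = shell[:, None] * np.diff(t_edges)[None, :]
    density = counts / (area * bin_area)
    rho = points.n / area
    return PairDistribution(r_edges, t_edges, density, counts, rho)


@dataclass(frozen=True)
class AnisotropyResult:
    """``score`` is approximately N(0,1) clipped at zero for isotropic
    input and large for angularly structured input; shells with too few
    pairs are excluded (``warn_sparse`` if any were)."""

    score: float
    per_shell_excess: np.ndarray
    shells_used: int
    warn_sparse: bool


def anisotropy_score(pd: PairDistribution, min_mean_count: float = 5.0) -> AnisotropyResult:
    """Excess angular chi-square over r-shells, noise-calibrated.

    For each r shell with mean count ``>= min_mean_count`` per theta bin,
    compute ``chi2 = sum_theta (n - nbar)^2 / nbar``; its excess over the
    ``ntheta - 1`` degrees of freedom, standardized, is summed over
    shells and the total standardized again.  Exactly flat input scores
    zero (the clip at zero absorbs the noise-free case).
    """
    counts = pd.counts
    ntheta = counts.shape[1]
    nbar = counts.mean(axis=1)
    use = nbar >= min_mean_count
    if not use.any():
        return AnisotropyResult(0.0, np.empty(0), 0, True)
    dof = ntheta - 1
    chi2 = ((counts[use] - nbar[use, None]) ** 2 / nbar[use, None]).sum(axis=1)
    excess = (chi2 - dof) / np.sqrt(2.0 * dof)
    score = float(excess.sum() / np.sqrt(len(excess)))
    return AnisotropyResult(
        max(0.0, score), excess, int(use.sum()), bool((~use).any())
    )
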