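"""Convex-hull normal-angle statistics for colony shapes.

A colony's outline is summarized by the convex hull of its member site
coordinates.  Each hull segment contributes its outward normal angle,
weighted by the segment length; binned over ``[0, 2*pi)`` this yields a
histogram ``h_k = sum of weights in bin k`` with per-bin standard
deviation ``sigma_k = sqrt(sum of squared weights)``, normalized to a
probability density.  An isotropic shape ensemble is flat at
``1/(2*pi)``; a square/diamond lattice artifact shows up as a 4-fold
Fourier mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull

__all__ = [
    "NormalHistogram",
    "IsotropyReport",
    "extract_colony_points",
    "largest_cluster_sites",
    "hull_normal_histogram",
    "aggregate_histograms",
    "isotropy_deviation",
    "fourfold_mode",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class NormalHistogram:
    """Length-weighted angular density of convex-hull normals.

    ``density`` integrates to 1 over ``[0, 2*pi)``.  ``sigma`` is the
    per-bin root-sum-of-squared weights, normalized like the density.
    For aggregates, ``sem`` holds the across-realization standard error
    of the mean density and ``n_realizations > 1``.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    sigma: np.ndarray
    sem: np.ndarray | None = None
    n_realizations: int = 1

    @property
    def n_bins(self) -> int:
        return len(self.density)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def largest_cluster_sites(lattice, occupied: np.ndarray) -> np.ndarray:
    """Site indices of the largest connected component of occupied sites
    under lattice adjacency."""
    occ = np.nonzero(np.asarray(occupied, dtype=bool))[0]
    if len(occ) == 0:
        raise ValueError("no occupied sites")
    sub = lattice.laplacian()[occ][:, occ]
    n_comp, labels = connected_components(sub != 0, directed=False)
    counts = np.bincount(labels)
    return occ[labels == np.argmax(counts)]


def extract_colony_points(source, threshold: float = 0.1) -> np.ndarray:
    """Coordinates of a colony's member sites.

    Accepts a hybrid ``ColonyState`` (occupied sites), a continuum
    ``KitsunezakiState`` (sites with ``b + s >= threshold * max(b + s)``),
    an adhesion ``AdhesionConfig`` (largest occupied cluster), or a raw
    ``(N, 2)`` coordinate array.
    """
    from .adhesion import AdhesionConfig  # local import to avoid a cycle
    from .hybrid import ColonyState
    from .kitsunezaki import KitsunezakiState

    if isinstance(source, np.ndarray):
        return source
    if isinstance(source, ColonyState):
        return source.lattice.coords[source.occupied]
    if isinstance(source, KitsunezakiState):
        tot = source.b + source.s
        mask = tot >= threshold * tot.max()
        return source.lattice.coords[mask]
    if isinstance(source, AdhesionConfig):
        sites = largest_cluster_sites(source.lattice, source.occupied)
        return source.lattice.coords[sites]
    raise TypeError(f"cannot extract colony points from {type(source).__name__}")


def hull_normal_histogram(points: np.ndarray, n_bins: int = 36) -> NormalHistogram:
    """Histogram of outward hull-normal angles, weighted by segment length.

    Angles follow the atan2 convention, counterclockwise from +x, mapped
    to ``[0, 2*pi)``.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points for a convex hull")
    try:
        hull = ConvexHull(points)
    except Exception as exc:  # qhull raises on collinear input
        raise ValueError("degenerate (collinear) point set") from exc
    verts = points[hull.vertices]  # counterclockwise in 2D
    vec = np.roll(verts, -1, axis=0) - verts
    lengths = np.linalg.norm(vec, axis=1)
    # outward normal of a CCW polygon edge (dx, dy) is (dy, -dx)
    angles = np.mod(np.arctan2(-vec[:, 0], vec[:, 1]), TWO_PI)
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    idx = np.minimum((angles / (TWO_PI / n_bins)).astype(int), n_bins - 1)
    h = np.bincount(idx, weights=lengths, minlength=n_bins)
    sig = np.sqrt(np.bincount(idx, weights=lengths**2, minlength=n_bins))
    norm = h.sum() * (TWO_PI / n_bins)
    return NormalHistogram(edges, h / norm, sig / norm)


def aggregate_histograms(histograms) -> NormalHistogram:
    """Per-bin mean density and standard error of the mean across
    independent realizations (identical binning required)."""
    histograms = list(histograms)
    if len(histograms) < 2:
        raise ValueError("need at least 2 histograms to aggregate")
    edges = histograms[0].bin_edges
    for hgm in histograms[1:]:
        if hgm.n_bins != histograms[0].n_bins or not np.allclose(
            hgm.bin_edges, edges
        ):
            raise ValueError("histograms have mismatched binning")
    dens = np.array([hgm.density for hgm in histograms])
    sig = np.array([hgm.sigma for hgm in histograms])
    R = len(histograms)
    mean = dens.mean(axis=0)
    sem = dens.std(axis=0, ddof=1) / np.sqrt(R)
    return NormalHistogram(
        edges,
        mean,
        np.sqrt((sig**2).sum(axis=0)) / R,
        sem=sem,
        n_realizations=R,
    )


@dataclass(frozen=True)
class IsotropyReport:
    """Deviation of an aggregated histogram from the flat density.

    ``z`` are per-bin z-scores versus ``1/(2*pi)``; ``chi2`` their sum of
    squares (expected about ``n_bins`` under isotropy); ``amp4``/``amp4_se``
    the amplitude of the 4-fold Fourier mode of the density and its
    standard error; ``phase4`` the angle (radians, in ``[0, pi/2)``) of
    the corresponding density peaks.
    """

    z: np.ndarray
    chi2: float
    amp4: float
    amp4_se: float
    phase4: float
    zero_sem_bins: int


def fourfold_mode(density: np.ndarray, bin_centers: np.ndarray) -> complex:
    """Complex 4-fold Fourier coefficient ``sum_k rho_k e^{4 i theta_k} dth``."""
    dth = TWO_PI / len(density)
    return complex(np.sum(density * np.exp(4j * bin_centers)) * dth)


def isotropy_deviation(agg: NormalHistogram, per_run_densities=None) -> IsotropyReport:
    """Score an aggregated histogram against the isotropic reference.

    If the per-realization densities are supplied, the 4-fold amplitude
    and its standard error are estimated from the spread of the
    per-realization Fourier coefficients (projected on the mean mode's
    direction); otherwise the SE is propagated from the per-bin SEMs.
    """
    if agg.sem is None:
        raise ValueError("aggregate the histograms first (need SEMs)")
    flat = 1.0 / TWO_PI
    zero_sem = int(np.count_nonzero(agg.sem == 0))
    safe = np.where(agg.sem > 0, agg.sem, np.inf)
    z = (agg.density - flat) / safe
    chi2 = float(np.sum(z**2))

    centers = agg.bin_centers
    m4 = fourfold_mode(agg.density, centers)
    amp4 = abs(m4)
    if per_run_densities is not None:
        per = np.asarray(per_run_densities)
        coeffs = np.array([fourfold_mode(d, centers) for d in per])
        direction = m4 / amp4 if amp4 > 0 else 1.0
        proj = np.real(coeffs * np.conj(direction))
        amp4_se = float(proj.std(ddof=1) / np.sqrt(len(proj)))
    else:
        dth = agg.bin_width
        direction = m4 / amp4 if amp4 > 0 else 1.0
        w = np.real(np.exp(4j * centers) * np.conj(direction)) * dth
        amp4_se = float(np.sqrt(np.sum((w * agg.sem) ** 2)))
    phase4 = float(np.mod(np.angle(m4) / 4.0, np.pi / 2))
    return IsotropyReport(z, chi2, amp4, amp4_se, phase4, zero_sem_bins=zero_sem)
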