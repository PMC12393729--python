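"""Disordered and regular 2D lattices with Voronoi-derived geometry.

A :class:`Lattice` couples a point set to its Delaunay neighbor graph and
the geometric quantities used by the finite-volume solvers: Voronoi cell
areas ``A_i``, shared-wall lengths ``L_ij`` and site separations ``d_ij``.
Two sites are neighbors iff their Voronoi cells share a wall.

Generators provided here:

* :func:`build_square_lattice` -- regular grid, von Neumann adjacency,
  optionally extended with diagonal (Moore) growth-neighbors.
* :func:`build_restricted_vrl` -- one site per reference cell, drawn in a
  centered subsquare of side ``a - l0`` (guaranteed minimum separation).
* :func:`build_redrawn_vrl` -- one site per reference cell, uniform in the
  full cell, with too-close pairs redrawn until none remain.
* :func:`lattice_from_points` -- tessellate an arbitrary point set
  (periodic or box-clipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import Voronoi, cKDTree

__all__ = [
    "PointSet",
    "Lattice",
    "VrlParams",
    "build_square_lattice",
    "build_restricted_vrl",
    "build_redrawn_vrl",
    "lattice_from_points",
    "rescale_to_unit_spacing",
    "tile_lattice",
    "shift_lattice",
    "minimum_image",
]

_WALL_EPS = 1e-10  # walls shorter than this are four-cocircular degeneracies


@dataclass(frozen=True)
class PointSet:
    """Site coordinates in a rectangular domain ``[0, w) x [0, h)``."""

    coords: np.ndarray
    domain: tuple[float, float]
    periodic: tuple[bool, bool] = (True, True)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (N, 2) array")
        if coords.shape[0] < 3:
            raise ValueError("need at least 3 points")
        object.__setattr__(self, "coords", coords)
        w, h = self.domain
        if w <= 0 or h <= 0:
            raise ValueError("domain sides must be positive")
        if coords.min() < 0 or (coords[:, 0] >= w).any() or (coords[:, 1] >= h).any():
            raise ValueError("all coordinates must lie inside the domain box")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class VrlParams:
    """Parameters of a vectorizable random lattice.

    ``l0`` is the tuneable minimum separation between sites, in units of
    the reference-cell side (the cell side is 1 internally).
    """

    n_cells_x: int
    n_cells_y: int
    l0: float = 0.5
    seed: int | None = None
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.n_cells_x < 2 or self.n_cells_y < 2:
            raise ValueError("reference grid must be at least 2 x 2")
        if not 0.0 <= self.l0 <= 1.0:
            raise ValueError("l0 must lie in [0, 1] (units of the cell side)")


@dataclass(frozen=True)
class Lattice:
    """A point set plus Delaunay adjacency and Voronoi geometry.

    Attributes
    ----------
    points : PointSet
    kind : str
        One of ``square, restricted_vrl, redrawn_vrl, fluid, custom``.
    edges : (E, 2) int array
        Undirected neighbor pairs, each with ``i < j``, counted once.
    wall_length, distance : (E,) float arrays
        Shared Voronoi wall length ``L_ij`` and site separation ``d_ij``.
    cell_area : (N,) float array
    boundary : (N,) bool array
        Sites whose cell touches a closed domain boundary.
    diagonal_edges : (E2, 2) int array or None
        Extra next-nearest (Moore) neighbor pairs used by the growth
        algorithm only; the reaction-diffusion solvers ignore them.
    """

    points: PointSet
    kind: str
    edges: np.ndarray
    wall_length: np.ndarray
    distance: np.ndarray
    cell_area: np.ndarray
    boundary: np.ndarray
    spacing: float | None = None
    diagonal_edges: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.points.n

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def coords(self) -> np.ndarray:
        return self.points.coords

    @property
    def domain_area(self) -> float:
        w, h = self.points.domain
        return w * h

    def neighbors(self, i: int) -> np.ndarray:
        """Sorted neighbor indices of site ``i`` (Delaunay adjacency)."""
        indptr, indices, _ = self.adjacency_csr()
        return indices[indptr[i] : indptr[i + 1]]

    # -- derived structures (cached) -------------------------------------
    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR arrays ``(indptr, indices, edge_id)`` of the neighbor graph."""
        if "csr" not in self._cache:
            self._cache["csr"] = _edges_to_csr(self.n_sites, self.edges)
        return self._cache["csr"]

    def growth_csr(self, w_d: float | None = None):
        """CSR arrays ``(indptr, indices, weights)`` for daughter placement.

        Delaunay/von Neumann neighbors carry weight 1; in Moore mode the
        diagonal neighbors carry weight ``w_d``.
        """
        key = ("growth", w_d)
        if key not in self._cache:
            if self.diagonal_edges is not None and w_d is not None:
                if w_d <= 0:
                    raise ValueError("w_d must be positive in Moore mode")
                all_edges = np.vstack([self.edges, self.diagonal_edges])
                wts = np.concatenate(
                    [
                        np.ones(len(self.edges)),
                        np.full(len(self.diagonal_edges), float(w_d)),
                    ]
                )
            else:
                all_edges = self.edges
                wts = np.ones(len(self.edges))
            indptr, indices, eid = _edges_to_csr(self.n_sites, all_edges)
            self._cache[key] = (indptr, indices, wts[eid])
        return self._cache[key]

    def laplacian(self) -> csr_matrix:
        """Sparse finite-volume operator: off-diag ``L_ij/d_ij``, diagonal
        minus the row sum.  ``(M @ c)_i = sum_j L_ij (c_j - c_i) / d_ij``."""
        if "lap" not in self._cache:
            i, j = self.edges[:, 0], self.edges[:, 1]
            w = self.wall_length / self.distance
            rows = np.concatenate([i, j, np.arange(self.n_sites)])
            cols = np.concatenate([j, i, np.arange(self.n_sites)])
            diag = np.zeros(self.n_sites)
            np.add.at(diag, i, w)
            np.add.at(diag, j, w)
            vals = np.concatenate([w, w, -diag])
            self._cache["lap"] = csr_matrix(
                (vals, (rows, cols)), shape=(self.n_sites, self.n_sites)
            )
        return self._cache["lap"]

    def degrees(self) -> np.ndarray:
        indptr, _, _ = self.adjacency_csr()
        return np.diff(indptr)


def _edges_to_csr(n: int, edges: np.ndarray):
    if len(edges) == 0:
        indptr = np.zeros(n + 1, dtype=np.int64)
        return indptr, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    eid = np.tile(np.arange(len(edges)), 2)
    order = np.lexsort((dst, src))
    src, dst, eid = src[order], dst[order], eid[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    indptr = np.cumsum(indptr)
    return indptr, dst.astype(np.int64), eid


def minimum_image(disp: np.ndarray, domain, periodic) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    disp = np.array(disp, dtype=float, copy=True)
    for ax in range(2):
        if periodic[ax]:
            L = domain[ax]
            disp[..., ax] -= L * np.round(disp[..., ax] / L)
    return disp


# ---------------------------------------------------------------------------
# square lattice
# ---------------------------------------------------------------------------

def build_square_lattice(
    nx: int,
    ny: int,
    spacing: float = 1.0,
    *,
    periodic: tuple[bool, bool] = (False, False),
    moore: bool = False,
) -> Lattice:
    """Regular square lattice with von Neumann adjacency.

    Parameters
    ----------
    nx, ny : int
        Grid dimensions (``>= 2``).
    spacing : float
        Lattice constant; cell areas are ``spacing**2``.
    periodic : (bool, bool)
        Wrap adjacency per axis.
    moore : bool
        Additionally store the 4 diagonal neighbors per site as
        *growth-only* edges (``diagonal_edges``); the RD solvers never
        see them.
    """
    if nx < 2 or ny < 2:
        raise ValueError("nx and ny must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    h = float(spacing)
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    coords = np.column_stack([(ix.ravel() + 0.5) * h, (iy.ravel() + 0.5) * h])
    # index convention: site = ix * ny + iy
    idx = np.arange(nx * ny).reshape(nx, ny)

    def _pairs(shift_x, shift_y):
        sx = np.roll(idx, -shift_x, axis=0)
        sy = np.roll(sx, -shift_y, axis=1)
        a, b = idx, sy
        keep = np.ones_like(a, dtype=bool)
        if shift_x and not periodic[0]:
            keep[nx - shift_x :, :] = False
        if shift_y and not periodic[1]:
            keep[:, ny - shift_y :] = False
        return np.column_stack([a[keep], b[keep]])

    e_right = _pairs(1, 0)
    e_up = _pairs(0, 1)
    edges = np.vstack([e_right, e_up])
    edges = np.sort(edges, axis=1)
    E = len(edges)
    wall = np.full(E, h)
    dist = np.full(E, h)
    area = np.full(nx * ny, h * h)

    boundary = np.zeros(nx * ny, dtype=bool)
    if not periodic[0]:
        boundary[idx[0, :]] = True
        boundary[idx[-1, :]] = True
    if not periodic[1]:
        boundary[idx[:, 0]] = True
        boundary[idx[:, -1]] = True

    diag = None
    if moore:
        d1 = _pairs(1, 1)
        # down-right diagonal: shift x by +1, y by -1
        sx = np.roll(idx, -1, axis=0)
        sy = np.roll(sx, 1, axis=1)
        keep = np.ones_like(idx, dtype=bool)
        if not periodic[0]:
            keep[nx - 1 :, :] = False
        if not periodic[1]:
            keep[:, :1] = False
        d2 = np.column_stack([idx[keep], sy[keep]])
        diag = np.sort(np.vstack([d1, d2]), axis=1)

    pts = PointSet(coords, (nx * h, ny * h), periodic)
    return Lattice(
        points=pts,
        kind="square",
        edges=edges,
        wall_length=wall,
        distance=dist,
        cell_area=area,
        boundary=boundary,
        spacing=h,
        diagonal_edges=diag,
    )


def square_grid_shape(lattice: Lattice) -> tuple[int, int]:
    """Recover ``(nx, ny)`` of a square lattice (index = ix * ny + iy)."""
    if lattice.kind != "square" or lattice.spacing is None:
        raise ValueError("not a square lattice")
    w, h = lattice.points.domain
    nx = int(round(w / lattice.spacing))
    ny = int(round(h / lattice.spacing))
    return nx, ny


# ---------------------------------------------------------------------------
# vectorizable random lattices
# ---------------------------------------------------------------------------

def _reference_cell_centers(nx: int, ny: int) -> np.ndarray:
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return np.column_stack([ix.ravel() + 0.5, iy.ravel() + 0.5])


def build_restricted_vrl(params: VrlParams) -> Lattice:
    """Restricted VRL: one site per reference cell, uniform in the centered
    subsquare of side ``1 - l0``; min pairwise distance is ``>= l0`` by
    construction."""
    rng = np.random.default_rng(params.seed)
    centers = _reference_cell_centers(params.n_cells_x, params.n_cells_y)
    half = (1.0 - params.l0) / 2.0
    jitter = rng.uniform(-half, half, size=centers.shape)
    per = (params.periodic, params.periodic)
    pts = PointSet(centers + jitter, (params.n_cells_x, params.n_cells_y), per)
    lat = lattice_from_points(pts, kind="restricted_vrl")
    return lat


def build_redrawn_vrl(params: VrlParams, max_redraws: int = 10**6) -> Lattice:
    """Redrawn VRL: one site per reference cell, uniform in the full cell;
    both members of any pair closer than ``l0`` are redrawn (within their
    own cells) until no such pair remains."""
    if params.l0 > 0.9:
        raise ValueError("l0 must be <= 0.9 for the rejection loop to terminate")
    rng = np.random.default_rng(params.seed)
    nx, ny = params.n_cells_x, params.n_cells_y
    centers = _reference_cell_centers(nx, ny)
    coords = centers + rng.uniform(-0.5, 0.5, size=centers.shape)
    redraws = 0
    if params.l0 > 0:
        boxsize = (nx, ny) if params.periodic else None
        while True:
            wrapped = np.mod(coords, (nx, ny)) if params.periodic else coords
            tree = cKDTree(wrapped, boxsize=boxsize)
            pairs = tree.query_pairs(params.l0, output_type="ndarray")
            if len(pairs) == 0:
                break
            offenders = np.unique(pairs.ravel())
            redraws += len(offenders)
            if redraws > max_redraws:
                raise RuntimeError(
                    "redraw loop exceeded iteration cap; decrease l0"
                )
            coords[offenders] = centers[offenders] + rng.uniform(
                -0.5, 0.5, size=(len(offenders), 2)
            )
    per = (params.periodic, params.periodic)
    pts = PointSet(np.mod(coords, (nx, ny)), (nx, ny), per)
    return lattice_from_points(pts, kind="redrawn_vrl")


# ---------------------------------------------------------------------------
# Voronoi tessellation of arbitrary points
# ---------------------------------------------------------------------------

def _ghost_points(points: PointSet):
    """Ghost copies implementing periodic images and/or mirror walls.

    Returns ``(ghost_coords, ghost_map)`` where ``ghost_map[k]`` is the
    original index for pure-shift images and ``-1`` for mirrored ghosts.
    """
    coords = points.coords
    w, h = points.domain
    n = points.n

    def axis_ops(ax, L):
        if points.periodic[ax]:
            return [("id", 0.0), ("shift", -L), ("shift", +L)]
        return [("id", 0.0), ("mlo", 0.0), ("mhi", 0.0)]

    gcoords, gmap = [], []
    for (opx, vx), (opy, vy) in product(axis_ops(0, w), axis_ops(1, h)):
        if opx == "id" and opy == "id":
            continue
        c = coords.copy()
        mirrored = False
        if opx == "shift":
            c[:, 0] += vx
        elif opx == "mlo":
            c[:, 0] = -c[:, 0]
            mirrored = True
        elif opx == "mhi":
            c[:, 0] = 2 * w - c[:, 0]
            mirrored = True
        if opy == "shift":
            c[:, 1] += vy
        elif opy == "mlo":
            c[:, 1] = -c[:, 1]
            mirrored = True
        elif opy == "mhi":
            c[:, 1] = 2 * h - c[:, 1]
            mirrored = True
        gcoords.append(c)
        gmap.append(np.full(n, -1, dtype=np.int64) if mirrored
                    else np.arange(n, dtype=np.int64))
    return np.vstack(gcoords), np.concatenate(gmap)


def _polygon_area(verts: np.ndarray, about: np.ndarray) -> float:
    """Area of a convex polygon given unordered vertices and an interior
    point; vertices are angle-sorted about that point (exact for convex
    cells containing their site)."""
    rel = verts - about
    order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
    v = verts[order]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def lattice_from_points(points: PointSet, kind: str = "custom") -> Lattice:
    """Voronoi tessellation of a point set into a :class:`Lattice`.

    Periodic axes are handled by tiling image copies and retaining the
    central copy's cells; closed axes by mirroring across the box walls,
    which clips boundary cells to the domain exactly.
    """
    coords = points.coords
    n = points.n
    tree = cKDTree(coords)
    dmin, _ = tree.query(coords, k=2)
    if dmin[:, 1].min() < 1e-12:
        raise ValueError("duplicate points")

    ghosts, gmap = _ghost_points(points)
    allpts = np.vstack([coords, ghosts])
    vor = Voronoi(allpts)

    # cell areas for the central copy
    area = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:
            raise RuntimeError("unbounded central cell; degenerate input")
        area[i] = _polygon_area(vor.vertices[region], coords[i])

    boundary = np.zeros(n, dtype=bool)
    edge_wall: dict[tuple[int, int], float] = {}
    rp = vor.ridge_points
    rv = vor.ridge_vertices
    central_mask = (rp < n).any(axis=1)
    for k in np.nonzero(central_mask)[0]:
        p, q = rp[k]
        v1, v2 = rv[k]
        if v1 == -1 or v2 == -1:
            continue
        wall = float(np.linalg.norm(vor.vertices[v1] - vor.vertices[v2]))
        if wall < _WALL_EPS:
            continue
        a, b = (p, q) if p < n else (q, p)
        if b < n:
            j = int(b)
        else:
            j = int(gmap[b - n])
            if j < 0:  # mirror ghost: a closed-boundary wall
                boundary[int(a)] = True
                continue
        a = int(a)
        if j == a:
            continue  # self-image (pathologically small periodic domains)
        key = (min(a, j), max(a, j))
        edge_wall.setdefault(key, wall)

    edges = np.array(sorted(edge_wall), dtype=np.int64).reshape(-1, 2)
    wall = np.array([edge_wall[tuple(e)] for e in edges])
    disp = minimum_image(
        coords[edges[:, 1]] - coords[edges[:, 0]], points.domain, points.periodic
    )
    dist = np.linalg.norm(disp, axis=1)
    return Lattice(
        points=points,
        kind=kind,
        edges=edges,
        wall_length=wall,
        distance=dist,
        cell_area=area,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def rescale_to_unit_spacing(lattice: Lattice) -> Lattice:
    """Rescale so the mean neighbor separation equals 1 (the unit of
    distance): coordinates, walls and distances scale by ``1/mean(d)``;
    areas by its square."""
    if lattice.n_edges == 0:
        raise ValueError("lattice has no edges")
    f = 1.0 / lattice.distance.mean()
    w, h = lattice.points.domain
    pts = PointSet(lattice.coords * f, (w * f, h * f), lattice.points.periodic)
    return Lattice(
        points=pts,
        kind=lattice.kind,
        edges=lattice.edges,
        wall_length=lattice.wall_length * f,
        distance=lattice.distance * f,
        cell_area=lattice.cell_area * f * f,
        boundary=lattice.boundary,
        spacing=None if lattice.spacing is None else lattice.spacing * f,
        diagonal_edges=lattice.diagonal_edges,
    )


def tile_lattice(lattice: Lattice, mx: int, my: int) -> Lattice:
    """Copy a fully periodic lattice ``mx x my`` times and re-tessellate
    on the enlarged periodic domain."""
    if not all(lattice.points.periodic):
        raise ValueError("tiling requires a fully periodic lattice")
    if mx < 1 or my < 1:
        raise ValueError("tile counts must be >= 1")
    w, h = lattice.points.domain
    offs = [(i * w, j * h) for i in range(mx) for j in range(my)]
    coords = np.vstack([lattice.coords + off for off in offs])
    pts = PointSet(coords, (mx * w, my * h), (True, True))
    return lattice_from_points(pts, kind=lattice.kind)


def shift_lattice(lattice: Lattice, shift: tuple[float, float]) -> Lattice:
    """Rigid translation (modulo the box) of a fully periodic lattice.

    Geometry and adjacency are translation invariant, so they are reused
    without re-tessellation.
    """
    if not all(lattice.points.periodic):
        raise ValueError("rigid shift requires a fully periodic lattice")
    w, h = lattice.points.domain
    coords = np.mod(lattice.coords + np.asarray(shift), (w, h))
    pts = PointSet(coords, (w, h), (True, True))
    return replace(lattice, points=pts, _cache={})
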