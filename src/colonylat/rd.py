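"""Forward-Euler reaction-diffusion stepping on lattices.

Two spatial discretizations of the same diffusion-with-point-sinks
equation are provided:

* :func:`step_square` -- five-point central differences on a regular
  square grid, with zero-flux walls via mirrored ghost values (wrapped
  ghosts on periodic axes).
* :func:`step_finite_volume` -- finite volumes on an arbitrary lattice,
  with fluxes ``D * L_ij * (c_j - c_i) / d_ij`` through shared Voronoi
  walls; closed boundaries carry no flux terms, so zero-flux is implicit.

On square geometry the two schemes coincide exactly.  Sinks enter as
point terms: a site consuming at amount-rate ``f`` removes ``dt * f / A_i``
of concentration per step.  Steps that would drive a concentration
negative are clamped to zero and the clamp events counted.
"""

from __future__ import annotations

import numpy as np

from .lattice import Lattice, square_grid_shape

__all__ = [
    "step_square",
    "step_finite_volume",
    "detect_divergence",
    "field_mass",
    "StepResult",
]


class StepResult:
    """Updated field plus bookkeeping of clamped (negative) sites."""

    __slots__ = ("values", "n_clamped")

    def __init__(self, values: np.ndarray, n_clamped: int):
        self.values = values
        self.n_clamped = n_clamped


def field_mass(lattice: Lattice, c: np.ndarray) -> float:
    """Total amount of material in the field: ``sum_i A_i c_i``."""
    return float(np.dot(lattice.cell_area, c))


def _clamp(c: np.ndarray) -> tuple[np.ndarray, int]:
    neg = c < 0.0
    n = int(np.count_nonzero(neg))
    if n:
        c = np.where(neg, 0.0, c)
    return c, n


def step_square(
    lattice: Lattice,
    c: np.ndarray,
    D: float,
    dt: float,
    sink: np.ndarray | None = None,
    *,
    clamp: bool = True,
) -> StepResult:
    """One explicit five-point step on a square lattice.

    ``sink`` is a per-site amount-rate (already multiplied by the
    occupancy indicator); it is divided by the cell area internally.
    Callers should respect the stability bound ``D*dt/dx**2 <= 0.25``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nx, ny = square_grid_shape(lattice)
    h = lattice.spacing
    A = h * h
    grid = np.asarray(c, dtype=float).reshape(nx, ny)
    px, py = lattice.points.periodic
    padded = np.pad(grid, 1, mode="edge")
    if px:
        padded[0, 1:-1] = grid[-1]
        padded[-1, 1:-1] = grid[0]
    if py:
        padded[1:-1, 0] = grid[:, -1]
        padded[1:-1, -1] = grid[:, 0]
    lap = (
        padded[:-2, 1:-1]
        + padded[2:, 1:-1]
        + padded[1:-1, :-2]
        + padded[1:-1, 2:]
        - 4.0 * grid
    )
    out = grid + (dt / A) * (D * lap)
    if sink is not None:
        out = out - (dt / A) * np.asarray(sink, dtype=float).reshape(nx, ny)
    out = out.ravel()
    n_clamped = 0
    if clamp:
        out, n_clamped = _clamp(out)
    return StepResult(out, n_clamped)


def step_finite_volume(
    lattice: Lattice,
    c: np.ndarray,
    D: float,
    dt: float,
    sink: np.ndarray | None = None,
    *,
    clamp: bool = True,
) -> StepResult:
    """One explicit finite-volume step on an arbitrary lattice."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    c = np.asarray(c, dtype=float)
    flux = D * (lattice.laplacian() @ c)
    if sink is not None:
        flux = flux - np.asarray(sink, dtype=float)
    out = c + (dt / lattice.cell_area) * flux
    n_clamped = 0
    if clamp:
        out, n_clamped = _clamp(out)
    return StepResult(out, n_clamped)


def detect_divergence(c: np.ndarray, bound: float = 1e6) -> bool:
    """True if any field value is non-finite or exceeds ``bound`` in
    magnitude."""
    c = np.asarray(c)
    if not np.all(np.isfinite(c)):
        return True
    return bool(np.any(np.abs(c) > bound))
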