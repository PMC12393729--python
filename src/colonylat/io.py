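"""Plain-text serialization: lattices, colonies, histograms, snapshots.

All tabular output is CSV with headers; metadata sidecars are YAML.
A lattice round-trips through a sites file (index, x, y, cell_area), an
edges file (i, j, wall_length, distance) and a metadata sidecar.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import yaml

from .lattice import Lattice, PointSet

__all__ = [
    "save_lattice",
    "load_lattice",
    "save_colony",
    "save_field",
    "save_histogram",
    "load_histogram",
    "save_fluid_snapshot",
    "load_fluid_snapshot",
]


def save_lattice(lattice: Lattice, basepath) -> None:
    """Write ``<base>.sites.csv``, ``<base>.edges.csv``, ``<base>.meta.yaml``."""
    base = Path(basepath)
    with open(f"{base}.sites.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["index", "x", "y", "cell_area"])
        for i, ((x, y), a) in enumerate(zip(lattice.coords, lattice.cell_area)):
            wr.writerow([i, repr(float(x)), repr(float(y)), repr(float(a))])
    with open(f"{base}.edges.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["i", "j", "wall_length", "distance"])
        for (i, j), L, d in zip(lattice.edges, lattice.wall_length, lattice.distance):
            wr.writerow([int(i), int(j), repr(float(L)), repr(float(d))])
    meta = {
        "kind": lattice.kind,
        "domain": [float(v) for v in lattice.points.domain],
        "periodic": [bool(v) for v in lattice.points.periodic],
        "spacing": lattice.spacing,
        "n_sites": lattice.n_sites,
    }
    with open(f"{base}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_lattice(basepath) -> Lattice:
    base = Path(basepath)
    with open(f"{base}.meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    sites = np.genfromtxt(f"{base}.sites.csv", delimiter=",", names=True)
    edges = np.genfromtxt(f"{base}.edges.csv", delimiter=",", names=True)
    edges = np.atleast_1d(edges)
    coords = np.column_stack([sites["x"], sites["y"]])
    pts = PointSet(coords, tuple(meta["domain"]), tuple(meta["periodic"]))
    return Lattice(
        points=pts,
        kind=meta["kind"],
        edges=np.column_stack([edges["i"], edges["j"]]).astype(np.int64),
        wall_length=np.asarray(edges["wall_length"], dtype=float),
        distance=np.asarray(edges["distance"], dtype=float),
        cell_area=np.asarray(sites["cell_area"], dtype=float),
        boundary=np.zeros(len(coords), dtype=bool),
        spacing=meta.get("spacing"),
    )


def save_colony(state, path) -> None:
    """Bacterium table: id, site_index, x, y, n, division_depth, label."""
    sites = state.bacteria_sites()
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["bacterium_id", "site_index", "x", "y", "n", "division_depth", "label"])
        for bid, s in enumerate(sites):
            x, y = state.lattice.coords[s]
            wr.writerow(
                [bid, int(s), repr(float(x)), repr(float(y)), repr(float(state.n[s])),
                 int(state.depth[s]), int(state.label[s])]
            )


def save_field(values, path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["site_index", "value"])
        for i, v in enumerate(values):
            wr.writerow([i, repr(float(v))])


def save_histogram(hist, path) -> None:
    """Histogram CSV: bin_left, bin_right, density[, sem, sigma]."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["bin_left", "bin_right", "density", "sem", "sigma"])
        sem = hist.sem if getattr(hist, "sem", None) is not None else [""] * hist.n_bins
        for lo, hi, d, se, sg in zip(
            hist.bin_edges[:-1], hist.bin_edges[1:], hist.density, sem, hist.sigma
        ):
            wr.writerow([repr(float(lo)), repr(float(hi)), repr(float(d)),
                         "" if se == "" else repr(float(se)), repr(float(sg))])


def load_histogram(path):
    from .shape import NormalHistogram

    data = np.genfromtxt(path, delimiter=",", names=True)
    edges = np.append(data["bin_left"], data["bin_right"][-1])
    sem = data["sem"]
    sem = None if np.isnan(sem).all() else sem
    return NormalHistogram(edges, data["density"], data["sigma"], sem=sem)


def save_fluid_snapshot(state, path) -> None:
    """XYZ-like text: a box metadata line, then id, species, diameter, x, y."""
    dmin = state.diameters.min()
    with open(path, "w") as fh:
        fh.write(f"# box_side {float(state.box_side)!r} n {state.n}\n")
        fh.write("id species diameter x y\n")
        for i in range(state.n):
            sp = 0 if state.diameters[i] == dmin else 1
            fh.write(
                f"{i} {sp} {float(state.diameters[i])!r} "
                f"{float(state.positions[i, 0])!r} {float(state.positions[i, 1])!r}\n"
            )


def load_fluid_snapshot(path) -> PointSet:
    with open(path) as fh:
        header = fh.readline().split()
        box = float(header[2])
        fh.readline()
        coords = []
        for line in fh:
            parts = line.split()
            coords.append((float(parts[3]), float(parts[4])))
    return PointSet(np.mod(np.array(coords), box), (box, box), (True, True))
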