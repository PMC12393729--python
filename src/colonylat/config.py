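"""Run configuration, hierarchical seeding and experiment orchestration.

A :class:`RunConfig` gathers every knob of a multi-realization
experiment with model-parameter defaults matching the standard
simulation-unit values (``n_g = 1``, ``v_max = 0.04``, ``K = 1``,
``D_c = 0.04``, ``delta = 0.2``; Kitsunezaki ``D0 = 0.1``, ``mu = 0.15``,
``dt = 0.1``; adhesion ``J = 4``).  Configs load from YAML; unknown keys
are rejected.  A single master seed deterministically derives one
independent stream per realization, so any run can be reproduced in
isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import adhesion as adhesion_mod
from . import hybrid as hybrid_mod
from . import io as io_mod
from . import kitsunezaki as kitz_mod
from . import shape as shape_mod
from .fluid import FluidParams, run_fluid, snapshot_to_points
from .lattice import (
    VrlParams,
    build_redrawn_vrl,
    build_restricted_vrl,
    build_square_lattice,
    lattice_from_points,
    rescale_to_unit_spacing,
    shift_lattice,
    tile_lattice,
)

__all__ = ["RunConfig", "load_config", "run_experiment", "build_lattice", "spawn_seeds"]

_LATTICE_KINDS = ("square", "rvrl", "dvrl", "fluid")
_MODELS = ("hybrid", "kitsunezaki", "adhesion")


@dataclass(frozen=True)
class RunConfig:
    """Flat experiment configuration; defaults are the printed values."""

    model: str = "hybrid"
    lattice_kind: str = "square"
    nx: int = 64
    ny: int = 64
    l0: float = 0.5
    realizations: int = 2
    seed: int = 0
    bins: int = 36
    record_every: int = 50
    # hybrid model
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
    # Kitsunezaki model
    D0: float = 0.1
    mu: float = 0.15
    kitsunezaki_dt: float = 0.1
    kitsunezaki_steps: int = 2000
    init_disk_radius: float = 5.0
    n0: float = 1.0
    # adhesion model
    J: float = 4.0
    mc_trials: int = 1_000_000
    init_shape: str = "disk"
    init_radius: float = 12.0
    # fluid lattice generation
    fluid_n: int = 1600
    fluid_equilibration_steps: int = 20_000
    fluid_tile: int = 1
    # support threshold for continuum hulls
    support_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.lattice_kind not in _LATTICE_KINDS:
            raise ValueError(f"unknown lattice kind {self.lattice_kind!r}")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")
        if self.init_shape not in ("disk", "square"):
            raise ValueError("init_shape must be 'disk' or 'square'")
        # constructing the parameter objects validates ranges
        self.hybrid_params()
        kitz_mod.KitsunezakiParams(self.D0, self.mu, self.kitsunezaki_dt)

    def hybrid_params(self) -> hybrid_mod.HybridParams:
        return hybrid_mod.HybridParams(
            n_g=self.n_g,
            v_max=self.v_max,
            K=self.K,
            c0=self.c0,
            D_c=self.D_c,
            delta=self.delta,
            w_d=self.w_d,
            dt=self.dt,
            stop_mean_c=self.stop_mean_c,
            stop_occupancy=self.stop_occupancy,
            max_steps=self.max_steps,
        )


def load_config(path_or_dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from YAML (or a dict);
    unknown keys raise."""
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent per-run seed sequences from a master seed."""
    return np.random.SeedSequence(master_seed).spawn(n)


def build_lattice(config: RunConfig, seed, base_fluid=None):
    """Construct the per-run lattice (rescaled to unit mean spacing for
    the disordered kinds).  For fluid lattices, pass the shared
    ``base_fluid`` lattice; it is rigidly shifted at random per run."""
    rng = np.random.default_rng(seed)
    k = config.lattice_kind
    if k == "square":
        return build_square_lattice(config.nx, config.ny, 1.0)
    if k == "rvrl":
        params = VrlParams(config.nx, config.ny, config.l0, seed=rng)
        return rescale_to_unit_spacing(build_restricted_vrl(params))
    if k == "dvrl":
        params = VrlParams(config.nx, config.ny, config.l0, seed=rng)
        return rescale_to_unit_spacing(build_redrawn_vrl(params))
    if base_fluid is None:
        raise ValueError("fluid lattice requires a prebuilt base lattice")
    w, h = base_fluid.points.domain
    return shift_lattice(base_fluid, (rng.uniform(0, w), rng.uniform(0, h)))


def build_fluid_base_lattice(config: RunConfig, seed):
    """Equilibrate a fluid, tessellate the snapshot, optionally tile, and
    rescale to unit mean spacing."""
    params = FluidParams(
        n_particles=config.fluid_n,
        equilibration_steps=config.fluid_equilibration_steps,
        seed=int(np.random.default_rng(seed).integers(0, 2**31 - 1)),
    )
    # the 2% temperature postcondition is too noisy for small presets;
    # instability still raises
    pts = snapshot_to_points(run_fluid(params, check_equilibration=False))
    lat = lattice_from_points(pts, kind="fluid")
    if config.fluid_tile > 1:
        lat = tile_lattice(lat, config.fluid_tile, config.fluid_tile)
    return rescale_to_unit_spacing(lat)


def _run_single(config: RunConfig, lattice, seed):
    """One realization; returns (colony point coords, final object)."""
    rng_seed = np.random.default_rng(seed)
    if config.model == "hybrid":
        result = hybrid_mod.run_colony(
            lattice, config.hybrid_params(), seed=rng_seed,
            record_every=config.record_every,
        )
        return shape_mod.extract_colony_points(result.state), result
    if config.model == "kitsunezaki":
        state = kitz_mod.run_kitsunezaki(
            lattice,
            config.kitsunezaki_steps,
            kitz_mod.KitsunezakiParams(config.D0, config.mu, config.kitsunezaki_dt),
            config.init_disk_radius,
            config.n0,
        )
        return (
            shape_mod.extract_colony_points(state, config.support_threshold),
            state,
        )
    # adhesion
    if config.init_shape == "disk":
        sites = adhesion_mod.disk_sites(lattice, config.init_radius)
    else:
        sites = adhesion_mod.square_sites(lattice, config.init_radius)
    occ = np.zeros(lattice.n_sites, dtype=bool)
    occ[sites] = True
    cfg = adhesion_mod.AdhesionConfig(lattice, occ, J=config.J)
    res = adhesion_mod.mc_run(
        cfg, config.mc_trials, seed=int(rng_seed.integers(0, 2**31 - 1))
    )
    return shape_mod.extract_colony_points(res.config), res


def run_experiment(config: RunConfig, out_dir) -> shape_mod.NormalHistogram:
    """Run ``config.realizations`` independent realizations (fresh VRL per
    run; random rigid shift per run for fluid lattices), aggregate the
    hull-normal histograms, and write colony CSVs, the aggregate
    histogram and a log to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(config.seed, config.realizations + 1)
    base_fluid = None
    if config.lattice_kind == "fluid":
        base_fluid = build_fluid_base_lattice(config, seeds[-1])
    hists = []
    log_lines = [f"config: {dataclasses.asdict(config)}"]
    for r in range(config.realizations):
        run_seeds = seeds[r].spawn(2)
        lattice = build_lattice(config, run_seeds[0], base_fluid)
        points, obj = _run_single(config, lattice, run_seeds[1])
        hists.append(shape_mod.hull_normal_histogram(points, config.bins))
        if hasattr(obj, "state"):
            io_mod.save_colony(obj.state, out / f"colony_{r:04d}.csv")
            with open(out / f"series_{r:04d}.csv", "w") as fh:
                fh.write("step,population,mean_c,occupancy\n")
                for row in zip(obj.steps, obj.population, obj.mean_c, obj.occupancy):
                    fh.write(f"{row[0]},{row[1]},{row[2]!r},{row[3]!r}\n")
        extra = ""
        if hasattr(obj, "state") and hasattr(obj.state, "clamp_events"):
            extra = f" clamps={obj.state.clamp_events}"
        if getattr(obj, "diverged", False):
            extra += f" DIVERGED@{obj.first_divergence_step}"
        log_lines.append(f"run {r}: colony_points={len(points)}{extra}")
    if len(hists) >= 2:
        agg = shape_mod.aggregate_histograms(hists)
    else:
        agg = hists[0]
    io_mod.save_histogram(agg, out / "aggregate_histogram.csv")
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return agg
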