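# colonylat

Hybrid lattice-based simulation of bacterial colony growth on regular and
disordered 2D lattices, built to study (and remove) lattice-induced
orientational artifacts in colony shapes.

The package provides:

- **Lattice generation** (`colonylat.lattice`): square lattices (von
  Neumann adjacency, optional Moore growth-neighbors), restricted and
  redrawn vectorizable random lattices (VRLs) with a tunable minimum site
  separation `l0`, and arbitrary point sets tessellated into
  Voronoi/Delaunay lattices with cell areas, shared-wall lengths and
  neighbor distances. Fully periodic, closed, and mixed boundaries;
  tiling and rigid shifts of periodic lattices.
- **Fluid-derived lattices** (`colonylat.fluid`): Langevin molecular
  dynamics of a dense bidisperse WCA soft-disk fluid (numba-accelerated);
  equilibrated snapshots become isotropic disordered lattices with
  liquid-like short-range order.
- **Reaction-diffusion solvers** (`colonylat.rd`): forward-Euler with a
  five-point stencil on square grids and a finite-volume scheme
  (`L_ij (c_j - c_i) / d_ij` fluxes through Voronoi walls) on disordered
  lattices; zero-flux boundaries, point sinks, mass-conservation
  guarantees, divergence detection.
- **Hybrid colony model** (`colonylat.hybrid`): discrete bacteria (one
  per site) coupled to a nutrient field via Monod uptake
  `f(c) = v_max c / (K + c)`; threshold-triggered division with a
  stochastic nutrient split and randomized per-step division order;
  single-colony runs and a channel benchmark with inherited labels.
- **Continuum model** (`colonylat.kitsunezaki`): the three-field
  (active/inactive/nutrient) colony model with degenerate nonlinear
  diffusion, solved with the finite-volume machinery on any lattice,
  plus a forward-Euler stability sweep over VRL separations.
- **Adhesion Monte Carlo** (`colonylat.adhesion`): motile bacteria with
  contact-length adhesion energy `H = -J * sum L_ij`, sampled with a
  degree-corrected Metropolis-Hastings rule (`min[1, (N_o/N_n) e^{-dH}]`)
  that satisfies detailed balance on irregular graphs; numba kernel
  (~10^7 trials/s).
- **Shape statistics** (`colonylat.shape`, `colonylat.diagnostics`):
  length-weighted convex-hull normal-angle histograms with per-bin
  uncertainties, ensemble aggregation, 4-fold Fourier-mode isotropy
  scoring; neighbor-distance/cell-area PDFs and the angular pair
  distribution function with a noise-calibrated anisotropy score.
- **Orchestration** (`colonylat.config`, `colonylat.cli`,
  `colonylat.io`): YAML run configs (validated, unknown keys rejected),
  hierarchical seeding (any realization reproducible in isolation),
  multi-realization experiments, CSV/YAML serialization.

## CLI

A single entry point with subcommands:

```sh
colonylat lattice --kind rvrl --n 64 --l0 0.5 --seed 1 --out out/lat
colonylat fluid --n 1600 --steps 20000 --seed 1 --out out/snapshot.txt
colonylat colony --lattice-kind square --n 200 --c0 3.0 --seed 1 --out out/colony.csv
colonylat kitsunezaki --lattice-kind rvrl --n 64 --l0 0.5 --dt 0.1 --steps 2000 --out out/field.csv
colonylat adhesion --lattice-kind rvrl --n 48 --j 4 --trials 1000000 --init disk --out out/final.csv
colonylat shape --colonies 'out/colony_*.csv' --bins 36 --out out/hist.csv
colonylat experiment --config run.yaml --out out/experiment
```

An experiment config is flat YAML; unset keys take the standard
simulation-unit defaults (`n_g=1`, `v_max=0.04`, `K=1`, `D_c=0.04`,
`delta=0.2`, ...):

```yaml
model: hybrid          # hybrid | kitsunezaki | adhesion
lattice_kind: fluid    # square | rvrl | dvrl | fluid
c0: 3.0
realizations: 50
seed: 7
```

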