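# nanopost

Coarse-grained molecular dynamics of flexible / semi-flexible bead-spring
polymers confined in a square-lattice array of parallel nanoposts, plus the
free-energy theory of the single-to-multiple interstitial-occupancy
(penetration) transition.

The model is a touching-bead discretized wormlike chain: WCA excluded
volume (cut at 2^(1/6) σ), WCA+FENE bonds (κ = 30 ε/σ², R_o = 1.5 σ,
equilibrium bond ≈ 0.97 σ), and a bending energy b·kT·(1 + cos θ) per
valence angle (b = 20 for semi-flexible blocks, giving a persistence
length ≈ 19 σ).  Posts are infinite x-aligned cylinders on a square
lattice of spacing `S_p`; a bead feels a radially shifted WCA from the
post surface.  Derived confinement parameters follow the standard
geometry relations: effective post diameter `d_p = D_p + 0.9`, passage
width `w = S_p − d_p`, interstitial channel diameter
`d_c = √2·S_p − d_p`, filling fraction `F = π d_p²/(4 S_p²)`.

## Layout

| module | purpose |
| --- | --- |
| `nanopost.array_geometry` | lattice geometry, derived confinement parameters, interstitial cell indexing |
| `nanopost.polymer_model` | chain topology (homopolymer / diblock), initial conformations |
| `nanopost.forcefield` | the four potential terms and exact forces (numba-accelerated kernels) |
| `nanopost.md_engine` | NVT leap-frog integrator (Langevin default, Nosé–Hoover optional), trajectories |
| `nanopost.observables` | axial span, gyration anisotropy, occupation number, structure factor, persistence length, scaling fits |
| `nanopost.confinement_theory` | Odijk / de Gennes channel free energies, slit approximation, predicted penetration transitions, transition detection |
| `nanopost.experiment_io` | YAML run configs, extended-XYZ trajectories, analytic fixtures, geometry-sweep driver, manifests |

## CLI

```sh
nanopost theory geometry --Sp 12 --dp 11.1      # derived parameter table (CSV)
nanopost theory transition --P 19.23 --w 2 --a 0.97
nanopost simulate config.yaml --outdir runs/
nanopost analyze runs/traj_rep0.xyz --observables span,rg,occupation,sq
nanopost sweep --protocol constant_Sp --config base.yaml --grid 1.9,3.9,5.9
```

Run configurations are YAML mappings with the keys
`N, blocks, b, S_p, D_p|d_p, n_y, n_z, dt, T, thermostat, gamma_or_tau,
n_equil, n_prod, sample_interval, seed, replicas, orientation`.
Trajectories are extended XYZ (species column = block label, comment-line
metadata carries time and array geometry); results are CSV tables and
JSON manifests sufficient to reproduce a run bit-for-bit.

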