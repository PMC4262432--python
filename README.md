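# hexaheart

A finite element simulator of electrical wave propagation in ventricular
myocardium, built to stay accurate on coarse meshes.

Cardiac tissue simulations solve the monodomain reaction–diffusion
equation: a detailed ionic model of the ventricular cell membrane coupled
to anisotropic diffusion of transmembrane voltage. Conventional schemes
artificially slow the propagating wavefront unless the mesh is refined to
~100 µm, which makes whole-ventricle studies expensive. This package uses
trilinear hexahedral elements with a lumped capacitance matrix for the
time-derivative term and a consistent mass matrix for the ionic current
load — a combination that keeps conduction velocity accurate at 200–425 µm
edge lengths, cutting node counts by one to two orders of magnitude.

Included:

* 26-state rabbit ventricular membrane model (numba-compiled), a
  two-variable excitable surrogate, and a passive model
* nine calibrated regional cell variants (endo/M/epi × apex/center/base)
  with a transmural transient-outward current gradient
* structured slab and biventricular-phantom meshing, graded meshes,
  fiber-tensor lattices with log-Euclidean interpolation
* operator splitting (Godunov/Strang) with theta-method diffusion
* a synthetic Purkinje tree coupled 1D/3D through discrete
  Purkinje-myocardial junctions, bidirectionally conducting
* activation maps, pseudo-ECG lead fields, ECG morphology metrics
* pacing and S1–S2 protocols, including a reentry-induction fixture
* lossless ASCII file formats (VTU/VTK/NRRD/CSV/HDF5) and a `hexaheart`
  CLI

## Worked example

Pace a single cell and calibrate the regional variants
(`examples/single_cell_apd.py`):

```
baseline cell: peak V = 42.8 mV, rest V = -87.5 mV, APD90 = 241.8 ms
calcium transient: 0.19 -> 0.36 uM

calibrating nine regional variants (20 beats each) ...
region           gto     gks   target  achieved
endo/apex       0.85   2.597    189.0    189.00
endo/center     0.85   1.928    199.0    199.00
endo/base       0.85   1.439    209.0    209.00
M/apex          1.00   1.985    195.0    195.00
M/center        1.00   1.442    205.0    205.00
M/base          1.00   1.015    216.0    216.00
epi/apex        1.00   4.814    168.0    168.00
epi/center      1.00   3.562    177.0    177.00
epi/base        1.00   2.653    186.0    186.00

peak I_to under clamp: epi 8.412, endo 7.150 uA/uF (15% reduction)
```

Conduction velocity vs mesh resolution (`examples/slab_conduction.py`),
on a 9.6 mm strand paced from one end:

```
longitudinal conduction velocity vs mesh edge length
  edge    50 um: CV =  731.9 um/ms (+0.0% vs 50 um)
  edge   100 um: CV =  738.5 um/ms (+0.9% vs 50 um)
  edge   200 um: CV =  756.3 um/ms (+3.3% vs 50 um)
  edge   400 um: CV =  778.5 um/ms (+6.4% vs 50 um)
  graded 184-425 um: CV =  749.4 um/ms (+2.4% vs 50 um)
```

Other examples: `examples/paced_phantom.py` (AV-paced biventricular
phantom with Purkinje tree, activation map and pseudo-ECG) and
`examples/reentry_sheet.py` (S1–S2 spiral-wave induction; sustained
activity over a 1000-unit window with up to 4 simultaneous wavefronts).

## Command line

```sh
hexaheart phantom --out out/geo --edge 400          # mesh + mask (+ fibers)
hexaheart calibrate-cells --out cells.json          # regional variant table
hexaheart tree --mesh out/geo/mesh.vtu --out out/pk # Purkinje tree + PMJs
hexaheart run --config run.yaml --out out/run       # full simulation
hexaheart ecg --series out/run/series.h5 --mesh out/run/mesh.vtu --out ecg.csv
hexaheart activation --series out/run/series.h5 --mesh out/run/mesh.vtu --out act.vtu
hexaheart compare --a a.h5 --b b.h5                 # per-frame RMSD
hexaheart validate --out report.json                # six-criteria battery
```

`run.yaml` is a validated YAML config (unknown keys are rejected); see
`hexaheart.io.RunConfig` for the schema and defaults.

## Reproduction

The acceptance metrics (regional APDs, I_to gradient, coarse- and
graded-mesh CV error) are computed from scratch by:

```sh
python scripts/acceptance.py --seed 0 --out acceptance.json
```

(~4 minutes; the 50 µm reference slab dominates.) The full validation
battery, `hexaheart validate`, takes ~20 minutes and exits nonzero if any
criterion fails. Everything is deterministic: meshes, trees, and
calibration use fixed seeds and bracketed root finding, and simulations
are bitwise reproducible.

See `docs/methods.md` for assumptions, parameters, numerics, and
limitations.
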