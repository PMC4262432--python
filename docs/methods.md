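# Methods

## Model

The simulator solves the monodomain reaction–diffusion equation for the
transmembrane voltage V on ventricular tissue:

    beta * cm * dV/dt = div(sigma grad V) - beta * cm * (I_ion - I_stim)

with sigma an element-wise symmetric positive-definite conductivity tensor
expressed in diffusivity form, so its entries carry µm²/ms and the
surface-to-volume ratio `beta` and membrane capacitance `cm` scale the
lumped mass rather than the flux term. Homogeneous Neumann (no-flux)
boundaries are assumed on all surfaces.

### Units

| quantity | unit |
|---|---|
| length | µm |
| time | ms |
| voltage | mV |
| membrane current | µA/µF |
| capacitance `cm` | 1 µF/cm² (normalized) |
| diffusivity `sigma` | µm²/ms |

All model I/O is ASCII with `%.17g` floats, so stored artifacts round-trip
to bitwise-identical float64 values.

## Membrane models

* **Rabbit ventricular model** — a 26-state ionic model (sodium, L-type
  calcium with Markovian gating, transient outward, rapid and slow delayed
  rectifiers, inward rectifier, exchanger and SERCA pumps, intracellular
  calcium cycling). State stepping is a numba-compiled explicit update at
  the reaction substep, with Rush–Larsen updates for gating variables.
* **Two-variable excitable model** — a dimensionless cubic
  reaction–recovery pair used for fixtures where wave phenomenology (not
  ion-channel realism) is the point, e.g. the S1–S2 reentry sheet;
  parameters (K, A, EPS, G) = (4.0, 0.1, 0.01, 0.5) by default.
* **Passive model** — zero ionic current; isolates the diffusion operator
  for conservation and null-space checks.

### Regional heterogeneity

Nine regional variants arise from three transmural zones (endo, M, epi)
crossed with three apex–base zones. The transient-outward conductance is
scaled 0.85 in endocardial cells (peak I_to 15% below epicardial, exact by
construction under a voltage-clamp probe). The slow delayed-rectifier
conductance of each variant is calibrated by Brent root-finding (log
scale, fixed bracket, deterministic) so the steady-state APD90 after 20
paced beats at a 400 ms cycle length hits the regional target:

| ms | apex | center | base |
|---|---|---|---|
| epi | 168 | 177 | 186 |
| M | 195 | 205 | 216 |
| endo | 189 | 199 | 209 |

## Spatial discretization

Structured trilinear hexahedral elements with 2×2×2 Gauss quadrature.
The time-derivative term uses a **lumped** (row-sum) capacitance matrix,
so total lumped capacitance equals `cm * beta *` domain volume exactly;
the ionic-current load vector uses the **consistent** mass matrix. This
combination is what keeps planar conduction velocity accurate on coarse
(200–425 µm) meshes: the acceptance battery measures ≤5% CV error on a
uniform 200 µm slab and ≤20% on a slab graded up to 425 µm edges, both
against a 50 µm reference.

Meshes are either slabs (uniform or per-axis graded edge sequences) or a
stair-stepped biventricular phantom voxelized from truncated ellipsoidal
shells, with surface tagging (endo LV/RV, epi, base) and the nine-region
labeling derived from transmural depth and apex–base position.

Fiber fields enter as lattices of symmetric positive-definite tensors
with per-voxel validity; interpolation to element centroids supports
nearest-neighbor, Euclidean, and log-Euclidean schemes with weight
renormalization over valid neighbors. Conductivity tensors are built by
rotating an anisotropic diagonal (ratios configurable, longitudinal value
`d_l`) into the local eigenframe.

## Time integration

Operator splitting (Godunov first-order or Strang second-order) between
reaction and diffusion. The diffusion solve is a theta-method (backward
Euler by default, Crank–Nicolson with `theta = 0.5`) with a sparse direct
or conjugate-gradient solver. Reaction substeps subdivide the PDE step.
Defaults: `dt_pde = 0.1 ms`, `dt_ode = 0.02 ms`. The scheme conserves
total lumped charge exactly in the absence of ionic/stimulus currents and
leaves spatially uniform states invariant.

## Purkinje system

A synthetic fractal-like tree is grown on the endocardial surfaces from a
root at the base; terminals lie on endocardial mesh nodes with a
configurable minimum separation. Segments are 1D bar (cable) elements
with cross-sectional area `pi * radius²`; the Purkinje diffusivity is
calibrated so a straight cable conducts at 2000 µm/ms. At each
Purkinje–myocardial junction (PMJ) the terminal couples to all myocardial
nodes within a search radius (nearest-node fallback) through bar elements
of equal split area A/k, which conserves the cable cross-section exactly.
The coupled 1D/3D system is one global operator with mesh DOFs first and
tree DOFs appended; conduction is bidirectional (orthograde and
retrograde) by construction, and constants remain in the null space of
the coupled stiffness.

## Observables

* **Activation maps** — first upward crossing of a threshold (−40 mV for
  ionic models), linearly interpolated between samples; absolute times.
* **Pseudo-ECG** — infinite-homogeneous-medium lead fields: the signal at
  an electrode is the current-dipole integral of sigma grad V against the
  gradient of 1/r, assembled once as a lead-field matrix. A uniform field
  yields zero signal; a dipole layer gives antisymmetric signals across
  its plane and far-field 1/r² decay. Sign convention: a depolarization
  wavefront approaching an electrode deflects the signal there.
* **Morphology** — QRS amplitude/width, T-wave amplitude, polarity, and
  asymmetry from the trace alone.
* **RMSD** — per-frame root-mean-square difference between voltage
  fields, for solution comparisons.

## Validation battery

Six always-on criteria (run by `hexaheart validate`) on reduced-scale
fixtures: calibrated regional APDs; planar CV accuracy and mesh
insensitivity; S2-induced wavebreak vulnerability; an AV-paced activation
sequence (endocardium before epicardium, apex before base, LV/RV
synchrony); pseudo-ECG sanity (finite position-discriminating leads,
bounded QRS, T-wave concordance controlled by the transmural APD gradient
on a strand fixture, flipping when the gradient is reversed); and
sustained reentry (≥1 s) after cross-field S1–S2 on a
reduced-conductivity sheet.

## Limitations

* Monodomain only; no bath, no bidomain effects on stimulation or ECG.
* Pseudo-ECG assumes an infinite homogeneous volume conductor; no torso
  inhomogeneity. Amplitudes are relative, not calibrated to mV at the
  body surface.
* The phantom is a stair-stepped voxelization; surfaces are not smooth,
  and the default validation geometry is a reduced-scale two-cavity
  phantom, not an anatomical heart.
* The synthetic Purkinje tree reproduces insertion-site physiology
  (discrete PMJs, endocardial coverage, bidirectional conduction), not
  the anatomical branching pattern; PMJs introduce no explicit
  junctional delay beyond the resistive coupling.
* The two-variable model is dimensionless and used only where wave
  phenomenology suffices (reentry fixture, fast tests).
* Cell calibration adjusts a single conductance (slow delayed rectifier)
  per region; other currents keep baseline kinetics.
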