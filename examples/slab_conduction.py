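"""Plane-wave conduction on a 3D slab and its mesh-size sensitivity.

A 9.6 mm strand of ventricular tissue is paced from one end; the
longitudinal diffusivity is calibrated so a planar wavefront travels at
700 um/ms (0.7 m/s) on a fine mesh. Coarser and spatially graded meshes
reproduce that speed to within a few percent, which is the point of the
lumped-capacitance finite element formulation: accuracy is retained at
400+ um edge lengths where conventional schemes need ~100 um.
"""

from hexaheart.fem import SolverConfig, slab_cv

D_L = 1.84376225e5                    # um^2/ms
EXTENT = (9600.0, 600.0, 600.0)
CFG = SolverConfig(dt_pde=0.05, dt_ode=0.01, splitting="strang", theta=0.5)

print("longitudinal conduction velocity vs mesh edge length")
ref = None
for edge in (50.0, 100.0, 200.0, 400.0):
    cv = slab_cv(D_L, EXTENT, edge, CFG)
    ref = ref or cv
    print(f"  edge {edge:>5.0f} um: CV = {cv:6.1f} um/ms "
          f"({100 * (cv - ref) / ref:+.1f}% vs 50 um)")

graded = {"x": [425.0, 184.0, 191.0], "y": 200.0, "z": 200.0}
cv = slab_cv(D_L, EXTENT, graded, CFG)
print(f"  graded 184-425 um: CV = {cv:6.1f} um/ms "
      f"({100 * (cv - ref) / ref:+.1f}% vs 50 um)")
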