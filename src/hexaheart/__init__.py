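"""hexaheart: monodomain cardiac electrophysiology on hexahedral meshes.

Rabbit-scale ventricular simulation toolkit: regional ionic cell models,
stair-stepped voxel FEM with operator splitting, a 1D Purkinje network coupled
through Purkinje-muscle junctions, anisotropic conduction from tensor fields,
pseudo-ECG / activation-map observables and an automated validation battery.

Subpackages and modules
-----------------------
- :mod:`hexaheart.cells`     membrane models, regional variants, calibration
- :mod:`hexaheart.mesh`      voxel masks, stair-stepped hexahedral meshes
- :mod:`hexaheart.tensors`   tensor lattices, interpolation, conductivity
- :mod:`hexaheart.fem`       semidiscrete assembly and operator splitting
- :mod:`hexaheart.purkinje`  1D tree, PMJ coupling, coupled assembly
- :mod:`hexaheart.ecg`       pseudo-ECG, activation maps, morphology
- :mod:`hexaheart.protocols` pacing protocols and the validation battery
- :mod:`hexaheart.io`        file formats and run configuration
- :mod:`hexaheart.cli`       command-line interface

Heavy submodules are imported lazily; ``import hexaheart`` is cheap.
"""

import importlib

__version__ = "0.1.0"

_SUBMODULES = ("cells", "mesh", "tensors", "fem", "purkinje", "ecg",
               "protocols", "io", "cli")

__all__ = ["__version__", *_SUBMODULES]


def __getattr__(name):
    if name in _SUBMODULES:
        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
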