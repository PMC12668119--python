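"""Derive DTI/DKI/NODDI-style scalars from matched voxel configurations.

Constructs three canonical voxels — pure free water, a coherent single
fiber, and a dispersed 60-degree crossing with partial volume — and prints
the full scalar panel each would contribute to the output maps.
"""

import numpy as np

from fibermatch import Diffusivities, MicrostructureConfig, compute_voxel_maps, default_grid

grid = default_grid()


def show(name, cfg):
    vm = compute_voxel_maps(cfg, grid)
    print(f"\n{name}")
    print(f"  DTI : FA={vm.fa:.3f}  MD={vm.md * 1e3:.3f}e-3  AD={vm.ad * 1e3:.3f}e-3  "
          f"RD={vm.rd * 1e3:.3f}e-3 mm^2/s")
    print(f"  DKI : MK={vm.mk:.3f}  AK={vm.ak:.3f}  RK={vm.rk:.3f}  KFA={vm.kfa:.3f}")
    print(f"  NODDI-style: NDI={vm.ndi:.3f}  ODI={vm.odi:.3f}  FW={vm.fw:.3f}")
    print(f"  tissue: WM={vm.f_wm:.2f}  GM={vm.f_gm:.2f}  CSF={vm.f_csf:.2f}")
    n_peaks = int(np.sum(np.linalg.norm(vm.peaks, axis=1) > 0))
    print(f"  peaks reported: {n_peaks}")


show("pure free water (ventricle-like)", MicrostructureConfig(
    n_fibers=0, f_wm=0.0, f_gm=0.0, f_fw=1.0,
    fiber_axes=np.zeros((0, 3)), fiber_weights=np.zeros(0), odis=np.zeros(0),
    intra_fraction=0.75, diffusivities=Diffusivities(2.5e-3, 0.5e-3),
))

show("coherent single fiber (corpus-callosum-like)", MicrostructureConfig(
    n_fibers=1, f_wm=1.0, f_gm=0.0, f_fw=0.0,
    fiber_axes=grid.vertices[:1], fiber_weights=np.array([1.0]),
    odis=np.array([0.04]), intra_fraction=0.8,
    diffusivities=Diffusivities(2.5e-3, 0.5e-3),
))

half = np.radians(30.0)
axes = np.array([[np.sin(half), 0, np.cos(half)], [-np.sin(half), 0, np.cos(half)]])
show("dispersed 60-deg crossing with CSF partial volume", MicrostructureConfig(
    n_fibers=2, f_wm=0.7, f_gm=0.0, f_fw=0.3,
    fiber_axes=axes, fiber_weights=np.array([0.5, 0.5]),
    odis=np.array([0.2, 0.2]), intra_fraction=0.75,
    diffusivities=Diffusivities(2.5e-3, 0.5e-3),
))

print(
    "\nFree water is fully isotropic (FA=0, MD=3e-3, zero kurtosis); the"
    "\ncoherent fiber is strongly anisotropic with high NDI; the crossing"
    "\nkeeps MD tissue-like but raises kurtosis (mixture of unlike Gaussian"
    "\ncompartments) and reports two peaks."
)
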