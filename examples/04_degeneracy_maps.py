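"""Uncertainty and ambiguity of the match, voxel by voxel.

Matches a coherent single-fiber voxel and a noisy shallow crossing against a
dictionary and prints the two degeneracy measures computed from each voxel's
top-50 penalized similarity profile: the interquartile range (uncertainty)
and the normalized width of the similarity peak at half maximum (ambiguity).
"""

import numpy as np

from fibermatch import (
    Diffusivities,
    FitConfig,
    MicrostructureConfig,
    add_rician_noise,
    ambiguity,
    build_dictionary,
    default_grid,
    make_gradient_table,
    uncertainty,
)
from fibermatch.dictionary import synthesize_signal
from fibermatch.matching import fit_signals

gtab = make_gradient_table()
grid = default_grid()
dictionary = build_dictionary(20_000, gtab, grid, seed=3)
rng = np.random.default_rng(4)

single = MicrostructureConfig(
    n_fibers=1, f_wm=1.0, f_gm=0.0, f_fw=0.0,
    fiber_axes=grid.vertices[:1], fiber_weights=np.array([1.0]),
    odis=np.array([0.04]), intra_fraction=0.8,
    diffusivities=Diffusivities(2.5e-3, 0.5e-3),
)
half = np.radians(12.5)
crossing = MicrostructureConfig(
    n_fibers=2, f_wm=1.0, f_gm=0.0, f_fw=0.0,
    fiber_axes=np.array([[np.sin(half), 0, np.cos(half)], [-np.sin(half), 0, np.cos(half)]]),
    fiber_weights=np.array([0.5, 0.5]), odis=np.array([0.25, 0.25]),
    intra_fraction=0.75, diffusivities=Diffusivities(2.5e-3, 0.5e-3),
)

signals = np.vstack([
    synthesize_signal(single, gtab, grid),
    add_rician_noise(synthesize_signal(crossing, gtab, grid), snr=10.0, rng=rng),
])
labels = ["coherent single fiber, noiseless", "25-deg dispersed crossing, SNR 10"]

_, _, _, profiles = fit_signals(signals, dictionary, FitConfig(K=50, alpha=1e-5))
print("voxel                                   uncertainty (IQR)  ambiguity (FWHM/K)")
for label, s in zip(labels, profiles):
    print(f"{label:38s}  {uncertainty(s):17.5f}  {ambiguity(s):18.3f}")
print(
    "\nA sharp, unique match gives a low IQR; many near-tied candidates"
    "\n(degenerate configurations under noise) widen the similarity peak and"
    "\nraise both measures.  Ambiguity is bounded below by 1/K = 0.02."
)
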