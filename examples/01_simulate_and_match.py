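"""Simulate a small signal dictionary and match noisy voxels against it.

Builds a single-shell (b = 2000 s/mm^2, 150 directions + 1 b0) acquisition,
simulates 5,000 multi-compartment voxel configurations, then corrupts a few
dictionary signals with Rician noise and matches them back.  The printed
cosine similarities show how close the best match is to the (noisy)
measurement, and the recovered fiber counts show the effect of the
complexity penalty.
"""

import numpy as np

from fibermatch import FitConfig, add_rician_noise, build_dictionary, default_grid, make_gradient_table
from fibermatch.matching import fit_signals

gtab = make_gradient_table(n_directions=150, b_value=2000.0)
grid = default_grid()
print(f"acquisition: {len(gtab)} volumes ({gtab.n_b0} b0), grid: {len(grid)} orientations")

dictionary = build_dictionary(5000, gtab, grid, mode="invivo", seed=42)
print(f"dictionary: {len(dictionary)} entries x {dictionary.n_volumes} volumes")

rng = np.random.default_rng(0)
rows = rng.choice(len(dictionary), size=8, replace=False)
noisy = add_rician_noise(dictionary.signals[rows], snr=30.0, rng=rng)

best, cosine, _, _ = fit_signals(noisy, dictionary, FitConfig(alpha=1e-5))
true_counts = dictionary.configs.n_fibers[rows]
est_counts = dictionary.configs.n_fibers[best]

print("\nvoxel  true_entry  matched  cosine   true_fibers  est_fibers")
for i, (r, b, c) in enumerate(zip(rows, best, cosine)):
    print(f"{i:5d}  {r:10d}  {b:7d}  {c:.5f}  {true_counts[i]:11d}  {est_counts[i]:10d}")
print(
    "\nCosine ~0.99 at SNR 30 means the noisy voxel still points at a nearly"
    "\nidentical simulated signal; recovering the exact entry is not required"
    "\n(distinct configurations can be near-degenerate in signal space)."
    "\nFiber-bearing voxels usually keep their count; fiber-free voxels are"
    "\nthe most degenerate — an isotropic signal is well fit by heavily"
    "\ndispersed fiber configurations too, which is exactly what the"
    "\nuncertainty/ambiguity maps are there to flag."
)
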