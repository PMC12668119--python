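"""Scaled-down crossing-angle and fiber-count benchmark.

Simulates two-fiber crossings across eight angle bins with dispersion and
Rician noise, matches them against a 30,000-entry dictionary, and prints the
per-bin success rate (both peaks recovered within 20 degrees and the correct
peak count) plus fiber-count accuracy for three penalty strengths.  Small
sizes keep this to a few minutes; the production benchmark uses 1,000 voxels
per bin and a 500,000-entry dictionary.
"""

from fibermatch import FitConfig, PhantomSpec, build_dictionary, default_grid, make_gradient_table, run_experiment

gtab = make_gradient_table()
grid = default_grid()
print("building 30,000-entry dictionary ...")
dictionary = build_dictionary(30_000, gtab, grid, mode="invivo", seed=1)

spec = PhantomSpec(n_voxels_per_bin=50, snr_levels=(50.0, 10.0), seed=2)
print("running crossing + fiber-count experiments ...")
report = run_experiment(spec, dictionary, FitConfig(alpha=1e-5), n_count_configs=300)

print("\nper-bin success rate (fraction of crossings resolved within 20 deg):")
print(report.success_rates.round(3).to_string())
print("\nmean angular error (deg):")
print(report.mean_angular_error.round(2).to_string())
print("\nfiber-count accuracy by penalty strength (rows: alpha):")
print(report.count_accuracy.round(3).to_string())
print(
    "\nShallow crossings (10-30 deg) are hard at low SNR; success rises with"
    "\nthe crossing angle and with SNR.  The small alpha=1e-5 penalty trims"
    "\nspurious extra fibers without suppressing true crossings; alpha=1e-3"
    "\nover-penalizes and collapses genuine two- and three-fiber voxels."
)
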