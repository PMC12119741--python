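"""Run a small end-to-end two-arm study and print its report tables.

Three digital patients are scanned (Ga-68 range blur + Poisson noise),
reconstructed with and without PRC at noise-matched regularization, and
analyzed: per-lesion percentage changes stratified by tissue and size,
per-patient liver noise (COV), reader agreement, and binomial preference
tests.  With the default-sized study (10 patients) the pattern mirrors the
clinical one: positive SUVmax/CNR changes everywhere, largest for small
lesions.  Takes a couple of minutes.
"""

from garange import CohortConfig, StudyConfig, report_tables, run_study
from garange.cohort import VoxelGrid

config = StudyConfig(cohort=CohortConfig(n_patients=3), seed=11)
report = run_study(config)

m = report.manifest
print(f"kernel mean range: {m['kernel_mean_range_mm']:.2f} mm")
print(f"beta non-PRC {m['beta_nonprc']} -> matched beta PRC {m['beta_prc']:.4f} "
      f"(liver COV {m['matched_cov_pct']:.1f}% vs reference "
      f"{m['reference_cov_pct']:.1f}%)")

tables = report_tables(report)
print("\nstratified percentage changes (PRC vs non-PRC):")
sub = tables["pct_change_strata"]
print(sub[sub.metric.isin(["suv_max", "cnr"])].to_string(index=False))
print("\nliver noise per patient (COV, %):")
print(tables["cov_pairs"].to_string(index=False))
print("\nreader agreement per criterion:")
print(tables["agreement_overall"].to_string(index=False))

report.write("scratch/example_study")
print("\nfull report written to scratch/example_study/ "
      "(lesions.csv holds every per-lesion metric)")
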