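"""Run the complete decision pipeline on one synthetic study.

One call chains everything: context test first (deciding whether community
tests must stratify by context), then community tests with pairwise
follow-ups, an individual-identity test with community as restriction
factor, variable importance on significant omnibus tests, and post-hoc
mixed models.  The report mirrors the layout of a results table: one row
per analysis with observed vs expected cross-validated accuracy and the
permutation p-value.
"""

from pathlib import Path

from panthoot import (
    AnalysisPlan,
    FeatureSetSpec,
    PDFAConfig,
    study_shaped_config,
    render_report,
    run_full_analysis,
    simulate_dataset,
)

table, _ = simulate_dataset(study_shaped_config(seed=23))
plan = AnalysisPlan(
    feature_sets=[FeatureSetSpec(name="all", features=list(table.feature_names))],
    n_repdfa_runs=200,
)
report = run_full_analysis(table, plan, PDFAConfig(n_perm=200, seed=17))

for row in report.rows:
    if row["skipped"]:
        print(f"{row['analysis']}: skipped ({row['reason']})")
    else:
        star = " *" if row["significant"] else ""
        print(f"{row['analysis']}: cv {row['observed_accuracy_cv']:.1f}% "
              f"(expected {row['expected_accuracy_cv']:.1f}%), "
              f"p = {row['p_cv']:.3f}{star}")

out = Path("scratch/example_report")
for fmt in ("json", "csv", "markdown"):
    print("wrote", render_report(report, fmt, out))
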