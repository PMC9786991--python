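"""Do communities differ once individual identity is controlled?  (nested pDFA)

Simulates calls with a genuine community-level effect, runs the nested
permutation test (individuals are reassigned whole to communities), then
follows a significant omnibus with pairwise two-community tests.  Without
the nested permutation, repeated calls per male would inflate apparent
community differences.
"""

from panthoot import (
    PDFAConfig,
    PDFADesign,
    study_shaped_config,
    run_pairwise_pdfa,
    run_pdfa,
    simulate_dataset,
)

table, _ = simulate_dataset(study_shaped_config(seed=3, sigma_community=1.0))
design = PDFADesign(test_factor="community", control_factor="individual",
                    design="nested")
cfg = PDFAConfig(n_perm=1000, seed=5)

res = run_pdfa(table, design, cfg)
print(f"omnibus: observed cv {res.observed_accuracy_cv:.1f}% "
      f"vs expected {res.expected_accuracy_cv:.1f}%, p = {res.p_cv:.3f}")

if res.p_cv < 0.05:
    comms = sorted(table.df["community"].unique())
    pairs = [(a, b) for i, a in enumerate(comms) for b in comms[i + 1:]]
    for (a, b), r in run_pairwise_pdfa(table, "community", pairs, design, cfg).items():
        print(f"  {a} vs {b}: cv {r.observed_accuracy_cv:.1f}% "
              f"(expected {r.expected_accuracy_cv:.1f}%), p = {r.p_cv:.3f}")
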