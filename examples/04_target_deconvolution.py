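"""End-to-end target deconvolution on a synthetic phenotypic screen.

Generates a corpus where each phenotype is driven by 3 planted targets,
runs the full pipeline (family interaction models -> hybrid target
profiles -> phenotype classifiers -> iterative weight-threshold
selection with the 95% AUC-retention stopping rule), and scores the
selected proteins against the planted truth.
"""

import warnings

warnings.filterwarnings("ignore")

import targetdecon as td

params = td.BenchmarkParams(n_compounds=800, n_proteins=15, n_phenotypes=3)
bench = td.generate_benchmark(params, seed=7)
result = td.run_pipeline(bench, reg_type="l1", profile_mode="hybrid", seed=7)

print("selection summary (one row per phenotype):")
print(result.summary.to_string(index=False))
print(
    "\nn_full is the panel size, n_selected the significant targets kept by\n"
    "the retention rule; auc_final stays within 95% of auc_full by design.\n"
)

print("recovery against the planted relevant-target sets:")
print(result.recovery.to_string(index=False))
print("\nper-phenotype detail:")
for aid, trace in result.traces.items():
    planted = bench.truth.phenotype_targets[aid]
    print(
        f"  {aid}: planted={planted} selected={trace.final_selected} "
        f"(stopped at cycle {trace.stop_cycle}, threshold "
        f"{trace.cycles[-1].threshold:.2f})"
    )
print(
    "\nPrecision is the fraction of selected proteins that are truly causal;\n"
    "recall is the fraction of planted targets recovered."
)
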