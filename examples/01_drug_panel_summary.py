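"""Summarize a cell-line IC50 panel into drug-efficacy categories.

Builds a synthetic 30-line panel, censors IC50s at the 8 µM assay ceiling,
and prints per-drug type-7 quantiles, the efficacy category, and outliers.
A drug is *effective* when the panel median is ≤ 1 µM, *ineffective* when
the median sits at the ceiling, and *selective* when the interquartile
fold q75/q25 is ≥ 20 — the long-boxplot pattern of drugs active in only a
subset of lines.
"""

from pharmsig import summarize_panel, threshold_ic50
from pharmsig.simulate import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=7))
panel = threshold_ic50(cohort.drug_response, ceiling=8.0)

print(f"{'drug':<10} {'q25':>6} {'q50':>6} {'q75':>6}  category      outliers")
for s in summarize_panel(panel):
    out = ", ".join(f"{c}({v:.2g})" for c, v in s.outliers[:3])
    print(f"{s.drug_id:<10} {s.q25:>6.2f} {s.q50:>6.2f} {s.q75:>6.2f}  "
          f"{s.category.value:<12}  {out}")

# The planted broadly-potent drug lands in 'effective', the inert drug in
# 'ineffective', and the phenotype-bimodal drug in 'selective'.
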