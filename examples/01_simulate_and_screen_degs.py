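"""Simulate a small drug-perturbation experiment and screen for DEGs.

Three treated vs three control replicates, log2 intensities, 5% of genes
carrying a planted log2 fold-change around 2. The screen is the classical
Student t-test with the joint filter p <= 0.05 and linear fold-change
>= 1.5 (or <= 1/1.5).
"""

from pertnet import call_degs, simulate_perturbation, ttest_fold_change

expr, truth = simulate_perturbation(
    n_genes=2000, n_per_group=3, de_fraction=0.05,
    lfc_location=2.0, sigma=0.5, seed=1,
)
table = call_degs(ttest_fold_change(expr, "control", "treated"))

n_deg = int(table["is_deg"].sum())
n_up = int((table["is_deg"] & (table["direction"] == "up")).sum())
sens = table.loc[truth.de_genes, "is_deg"].mean()
fdr = 1 - table.loc[table["is_deg"]].index.isin(truth.de_genes).mean()

print(f"called {n_deg} DEGs of {len(table)} genes ({n_up} up, {n_deg - n_up} down)")
print(f"sensitivity against planted truth: {sens:.2f}")
print(f"false discovery proportion: {fdr:.2f}")
# Most of the 100 planted genes are recovered; the excess calls are the
# t-test's false positives at 3-vs-3, most of which fail the fold-change gate.
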