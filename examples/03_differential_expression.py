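"""Call differentially expressed genes on a case/control matrix.

A gene is a DEG when |log2 fold change| > 0.5 and the BH-adjusted Welch
P is below 0.05 — both jointly.  The generator plants 5% of genes with a
log2 shift of 2, which the caller should recover essentially completely.
"""

from netmark.dge import call_degs
from netmark.synth import SynthConfig, make_expression

cfg = SynthConfig(n_genes=1000, n_case=20, n_ctrl=20, deg_fraction=0.05,
                  planted_logfc=2.0, noise_sd=0.5, seed=1)
matrix, truth = make_expression(cfg)
table = call_degs(matrix, logfc_cut=0.5, alpha=0.05)

flagged = set(table.loc[table.significant, "gene"])
planted = set(truth.deg_genes)
print(f"genes tested: {len(table)}, flagged significant: {len(flagged)}")
print(f"planted DEGs: {len(planted)}, recovered: {len(flagged & planted)}")
print(f"sensitivity = {len(flagged & planted) / len(planted):.3f}, "
      f"false positives = {len(flagged - planted)}")
print(table[table.significant].head(5).to_string(index=False))
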