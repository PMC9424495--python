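"""Decompose the Th1/2 hybrid transcriptome into Th1 and Th2 contributions.

Per gene, the hybrid condition's (mean-centred) time profile is regressed
without intercept on the Th1 and Th2 profiles; the significance pattern of
(beta_Th1, beta_Th2) classifies the gene as Th1-like, Th2-like,
Superposition (both contribute) or Independent (neither explains it).
"""

import thkinetics as tk

cfg = tk.SimulationConfig(
    n_flat=0, n_shared_per_archetype={},
    n_hybrid_per_category={"Th1_like": 60, "Th2_like": 60,
                           "Superposition": 40, "Independent": 40},
    seed=4)
matrix, design, truth = tk.simulate_dataset(cfg)

hybrid_truth = truth.hybrid_genes()
fits, fractions = tk.decompose_all(matrix, design,
                                   list(hybrid_truth["gene_id"]),
                                   target="Th12", alpha=0.05)

print("category fractions over the analysed genes:")
print(fractions.as_frame().to_string(index=False))

merged = fits.merge(hybrid_truth[["gene_id", "hybrid_category"]], on="gene_id")
acc = (merged["category"] == merged["hybrid_category"]).mean()
print(f"\nagreement with generating truth: {acc:.1%}")
# Fractions should recover the generated 30/30/20/20% split; a gene whose
# profile follows neither lineage (Independent) indicates a transcriptional
# program that is not a mixture of the two canonical ones.
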