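"""miRNA-target and pathway over-representation on synthetic resources.

Builds a random evidence-graded MTI table and gene-set collection, then runs
the hypergeometric target enrichment (strong evidence, >= 2 interactions,
FDR < 0.05), gene-set enrichment of the hit genes, and a disease-association
join.
"""

import pandas as pd

import mirnet as mn

mti = mn.generate_mti_table(n_mirnas=100, n_genes=400, density=0.05, seed=6)
mirna = mti["mirna"].iloc[0]
counts = mn.classify_mti(mti, mirna)
print(f"{mirna}: {counts['strong']} strong / {counts['weak']} weak / "
      f"{counts['non-functional']} non-functional target genes")

# a biologically coherent list: the miRNAs that strongly target one gene
strong = mti[mti["evidence"] == "strong"]
focus_gene = strong["gene"].value_counts().idxmax()
mirna_list = sorted(strong.loc[strong["gene"] == focus_gene, "mirna"].unique())
hits = mn.target_enrichment(mirna_list, mti, min_interactions=2, fdr=0.05)
enriched = hits[hits["enriched"]]
print(f"target enrichment of the {len(mirna_list)} miRNAs co-targeting "
      f"{focus_gene}: {len(enriched)} genes at >= 2 strong interactions, "
      "FDR < 0.05 (the co-targeted gene itself should lead)")
print(hits.head(3)[["gene", "hits", "targeting_mirnas", "p", "fdr"]].round(4))

universe = sorted(mti["gene"].unique())
genesets = mn.generate_gene_sets(universe, n_sets=15, seed=7)
genes = list(hits.head(30)["gene"])
gsea = mn.geneset_enrichment(genes, genesets, universe)
print(f"\ntop gene set: {gsea.iloc[0]['geneset']} "
      f"(hits {gsea.iloc[0]['hits']}/{gsea.iloc[0]['set_size']}, "
      f"fdr {gsea.iloc[0]['fdr']:.3f})")

diseases = pd.DataFrame(
    {"mirna": [mirna] * 4, "disease": ["PD", "AD", "stroke", "glioma"],
     "causal": [True, False, False, True]}
)
ann = mn.annotate_disease(mirna, diseases)
print(f"{mirna}: {ann['total']} disease associations, {ann['causal']} causal")
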