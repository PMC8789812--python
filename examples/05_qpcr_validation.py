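"""Comparative-Ct qPCR validation with the vendor significance rule.

Simulates a validation-phase Ct table (duplicates, one endogenous control)
with one down-regulated target, then runs replicate aggregation, dCt
normalization, ddCt relative quantification, t-tests with BH correction and
the RQ > 2 / RQ < 0.5 magnitude gate.
"""

import mirnet as mn

ct, truth = mn.generate_ct_table(
    targets=["miR-down", "miR-null", "miR-186-5p"],
    group_sizes={"dnPD": 30, "adPD": 12, "CTR": 30},
    planted_log2fc={"dnPD": {"miR-down": -1.2}, "adPD": {"miR-down": -0.6}},
    controls=["miR-186-5p"],
    reference_group="CTR",
    noise_sd=0.25,
    seed=4,
)
print(f"Ct table: {len(ct)} wells ({ct['sample'].nunique()} samples x "
      f"{ct['target'].nunique()} targets, duplicates)")

means = mn.aggregate_replicates(ct)
dct = mn.delta_ct(means, controls=["miR-186-5p"])
for group in ("dnPD", "adPD"):
    res = mn.rq_test(dct, group, "CTR", exclude=["miR-186-5p"]).set_index("target")
    for target in ("miR-down", "miR-null"):
        r = res.loc[target]
        print(f"{group} vs CTR, {target}: RQ = {r['rq']:.2f} "
              f"(log2FC {r['log2fc']:+.2f}), padj = {r['padj']:.2g}, "
              f"significant = {bool(r['significant'])}")
print("\nNote the planted adPD effect (-0.6): statistically clear but blocked "
      "by the RQ magnitude gate, the vendor rule's behaviour.")

ranking = mn.rank_normalizers(ct, ["miR-186-5p", "miR-down"])
print(f"normalizer stability ranking: {list(ranking['target'])} "
      "(planted-effect targets are bad normalizers)")
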