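"""Rank item vulnerability with the Composite Sensitivity Index.

CSI = |dM| + |dr| + |dlambda| per item between the unscreened and
screened samples: the absolute changes in item mean, corrected
item-total correlation, and standardized factor loading.  CSI-z
standardizes each component across items before summation.
"""

from carescreen import (
    assemble_study,
    compute_item_stats,
    csi_compute,
    csi_z,
    default_sdas_config,
    flag_instructed,
    rank_agreement,
    recode_reverse,
    top_k_report,
)

study = assemble_study(default_sdas_config(seed=2025))
design = study.design
recoded = recode_reverse(study.matrix, design)
flags = flag_instructed(study.matrix, design)
scored = list(design.scored_items)

uns = recoded.data[scored]
scr = recoded.data.loc[~flags, scored]
table = csi_z(csi_compute(
    compute_item_stats(uns, design),
    compute_item_stats(scr, design),
    design,
))

top = table.sort_values("rank").head(10)
print(f"{'item':10s} {'factor':12s} {'type':9s} "
      f"{'dM':>6s} {'dr':>6s} {'dlam':>6s} {'CSI':>7s}")
for item, row in top.iterrows():
    print(f"{item:10s} {row['factor']:12s} {row['item_type']:9s} "
          f"{row['dM']:6.3f} {row['dr']:6.3f} {row['dlam']:6.3f} "
          f"{row['CSI']:7.3f}")

summary = top_k_report(table, 10)
agree = rank_agreement(table["rank"], table["rank_z"])
print(f"\nreverse-coded items in top 10: {summary['n_reverse_in_top_k']} "
      f"of {summary['n_reverse_total']} "
      f"(item share in pool: 6/36 = 16.7%)")
print(f"CSI vs CSI-z rank agreement: rho = {agree['spearman_rho']:.3f}, "
      f"tau-b = {agree['kendall_tau_b']:.3f}")
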