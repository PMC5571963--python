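"""Simulate a fractionation experiment and measure membrane enrichment.

Generates triplicate extract and membrane libraries in which every
membrane-protein-encoding mRNA (MPR) is planted with a two-fold true
membrane enrichment, then recovers the enrichment landscape and compares
MPRs against cytoplasmic-protein mRNAs (CPRs).
"""

import numpy as np

import fracrna as fr

design = fr.SimDesign(n_mpr=100, n_cpr=500, n_other=10,
                      fractions=("extract", "membrane"),
                      n_replicates=3, library_size=5e6, seed=42)
catalog = fr.build_gene_catalog(design)
truth = fr.make_truth(catalog, design,
                      class_effects={"membrane": {"MPR": 2.0}})
counts = fr.simulate_fraction_counts(catalog, design, truth)

mrna = fr.filter_feature_classes(counts, catalog)
pooled = fr.pool_replicates(mrna)
rpkm = fr.compute_rpkm(pooled, catalog)
table = fr.enrichment_ratio(rpkm, "membrane", "extract", min_rpkm=1.0)

cls = catalog.loc[table.gene_ids, "loc_class"]
mpr, cpr = table.ratios[cls == "MPR"], table.ratios[cls == "CPR"]
mw = fr.mann_whitney_test(mpr, cpr)
ks = fr.ks_test(mpr, cpr)

est_over_true = table.ratios / truth.multipliers.loc[table.gene_ids, "membrane"]
print(f"detected genes:          {len(table.ratios)} "
      f"({len(table.dropped)} dropped by the RPKM >= 1 filter)")
print(f"median MPR enrichment:   {mpr.median():.3f}")
print(f"median CPR enrichment:   {cpr.median():.3f}")
print(f"median |log2(est/true)|: {np.abs(np.log2(est_over_true)).median():.4f}")
print(f"Mann-Whitney p:          {mw.p_value:.3g}  (U={mw.statistic:.0f})")
print(f"Kolmogorov-Smirnov p:    {ks.p_value:.3g}  (D={ks.statistic:.3f})")
print()
print("MPRs sit about two-fold above CPRs on the membrane landscape, the")
print("planted effect; the log2 recovery error shows how precisely a 5e6-read")
print("triplicate design estimates per-gene enrichment.")
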