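"""Pausing index, metagene profile and MNase-seq change on synthetic tracks.

Simulates nascent-transcription coverage for four gene classes with
decreasing promoter-proximal enrichment (chrd_induced 8x > high 3x >
moderate 2x > low 1.5x), computes per-gene pausing indices and the
Kruskal-Wallis comparison, then simulates an MNase-seq control/treated pair
with 50% nucleosome depletion at chrd_induced promoters and measures the
relative density change around the TSS.
"""

from dataclasses import replace

import chromstress as cs

genes = cs.make_gene_models(400, length=1000)
cfg = cs.CoverageSimConfig(seed=0)
track, truth = cs.simulate_paused_coverage(cfg, genes)

pi = cs.pausing_indices(track, genes).merge(truth.genes, on="gene_id")
medians = pi.groupby("class")["pausing_index"].median()
print("median pausing index per class:")
print(medians.round(2).to_string())
h, p = cs.compare_groups_ranked({c: g["pausing_index"].to_numpy() for c, g in pi.groupby("class")})
print(f"Kruskal-Wallis H = {h:.1f}, p = {p:.3g}")
# chrd_induced genes show the highest pausing index, and the class
# difference is overwhelmingly significant.

mg = cs.metagene(track, genes, flank=500, bin_size=50, normalization="per_gene_mean")
peak_bin = mg.mean_profile.argmax()
print(f"metagene mean profile peaks at offset {mg.bin_offsets[peak_bin]}..."
      f"{mg.bin_offsets[peak_bin] + 50} bp (the paused-polymerase window)")

control, treated, mtruth = cs.simulate_mnase_pair(replace(cfg, seed=1), genes)
classes = mtruth.genes.set_index("gene_id")["class"]
res = cs.mnase_tss_change(control, treated, genes, classes=classes)
print("\nmean TSS-proximal MNase change (treated vs control):")
print(res.per_class.pivot(index="class", columns="window", values="mean").round(3).to_string())
print("\nt-tests, chrd_induced vs other classes (window 0..150):")
print(res.tests[res.tests["window"] == "0..150"].to_string(index=False))
# chrd_induced promoters lose ~50% of their nucleosome signal inside the
# depleted window; other classes stay near zero.
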