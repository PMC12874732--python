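"""PERMANOVA, pairwise comparisons, PCoA and NMDS on a functional profile.

Distances between samples use Bray-Curtis (the standard choice for
abundance profiles); group separation is tested with 999 permutations, and
every 3-vs-3 pairwise contrast has only 10 free permutations, which
triggers the Monte-Carlo fallback.
"""

import taxaflow as tf

panel = tf.load_pathway_panel("map00910")
table, metadata, _ = tf.generate_stratified_rpkm(
    tf.default_nitrogen_design(panel), panel, seed=1
)

profiles = table.data.T  # samples x (function, taxon) features
d = tf.bray_curtis(profiles)
groups = [metadata.treatment[s] for s in d.ids]

res = tf.permanova(d, groups, n_perm=999, seed=0)
print(f"PERMANOVA: pseudo-F = {res.pseudo_F:.2f}, p = {res.p_perm:.3f} "
      f"({res.method}, {res.n_permutations_used} permutations)")

pw = tf.pairwise_permanova(d, groups, seed=0)
row = pw.iloc[0]
print(f"pairwise {row.group1} vs {row.group2}: pseudo-t = {row.pseudo_t:.2f}, "
      f"exact p = {row.p_perm:.3f}, Monte-Carlo p = {row.p_montecarlo:.4f} "
      f"({row.n_free_permutations} free permutations)")

ordn = tf.pcoa(d)
pv = ordn.percent_variance
print(f"PCoA: axis1 {pv[0]:.1f}%, axis2 {pv[1]:.1f}% "
      f"(first two axes {pv[0] + pv[1]:.1f}% of variation)")

nm = tf.nmds(d, k=2, seed=0)
print(f"NMDS: stress = {nm.stress:.4f} (stress < 0.1 is a good 2-D fit)")
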