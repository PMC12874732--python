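"""Verify classifier assignments by mapping reads back to references.

Reads assigned to a species are re-mapped to that species' genome; a genus
is kept ("confirmed") if, within any one treatment, some species reaches 1%
genome breadth or has >= 100 assigned reads with >= 50% confirmed mappings.
Phantom genera — references that received reads but contributed none — fail
both clauses and are flagged potentially spurious.
"""

import taxaflow as tf

metadata = tf.SampleMetadata.from_design(tf.TREATMENTS, 3)
community = tf.make_community(metadata, n_genera=20, n_phantom_genera=5,
                              genome_length_bp=10_000, seed=1)
reads, truth = tf.simulate_reads(community, 500, 100, 0.01, seed=2)
assignments = tf.simulate_classifier_output(truth, community, 0.05, seed=3)

genomes = {g.lineage.to_string(): g.sequence for g in community.genomes}
report = tf.verify(assignments, genomes, reads, metadata)

phantoms = {tf.TaxonLineage.from_string(s).genus for s in community.phantom_taxa}
flagged = report.flagged_genera()
print(f"genera assessed: {len(report.verdicts)}")
print(f"flagged potentially spurious: {sorted(flagged)}")
print(f"phantoms caught: {len(flagged & phantoms)}/{len(phantoms)}; "
      f"true genera wrongly flagged: {len(flagged - phantoms)}")
row = report.species_frame().iloc[0]
print(f"example species row: breadth={row.breadth:.3f}, "
      f"confirmed {row.n_confirmed_reads}/{row.n_assigned_reads} reads")
print("-> breadth is the fraction of the genome covered by >= 1 confirmed read")
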