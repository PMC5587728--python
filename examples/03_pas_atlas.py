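"""Build a poly(A)-site atlas: cluster, annotate, filter, classify.

Cleavage events within 24 nt are clustered iteratively (the most supported
site represents the cluster), assigned to genes and regions, filtered to
sites with >= 2 reads and > 5% of the gene's reads in some sample, and
classified by poly(A) signal (AAUAAA, variant, A-rich, none) from their
-40..-1 upstream sequence.  Run examples 01-02 first conceptually; this
script recomputes everything it needs.
"""

import pyfaidx

from apakit import atlas
from apakit.pass_reads import call_pass_reads, merge_tallies
from apakit.workflow import read_annotation

genome = pyfaidx.Fasta("example_fixture/genome.fa")
annotation = read_annotation("example_fixture/annotation.tsv")

tallies = []
for sample in ("ctrl_rep1", "kd_rep1"):
    result = call_pass_reads(
        f"example_fixture/reads_{sample}.sam", genome, sample_id=sample
    )
    tallies.append(result.tally)

clusters = atlas.cluster_cleavage_sites(merge_tallies(tallies), window=24)
clusters = atlas.annotate_pas_location(clusters, annotation, extension=400)
retained = atlas.filter_pas_clusters(clusters, min_reads=2, min_frac=0.05)
atlas.attach_signal_classes(retained, genome)

print(f"clusters: {len(clusters)}, retained after abundance filter: {len(retained)}")
frame = atlas.clusters_to_frame(retained)
print(frame["signal_class"].value_counts().to_string())
print(frame.head(4).to_string(index=False))
frame.to_csv("example_atlas.tsv", sep="\t", index=False)
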