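"""Expression and regulation calls for PAS isoforms and genes.

Isoform expression is RPM (reads per million PASS reads in the sample);
gene expression sums its isoforms.  A transcript is called regulated at
fold change > 2 with > 50 supporting reads; the down/up ratio summarises
the direction bias of the knockdown.  Run examples/03_pas_atlas.py first.
"""

import pandas as pd

from apakit import quantify
from apakit.atlas import frame_to_counts

counts, meta = frame_to_counts(pd.read_csv("example_atlas.tsv", sep="\t"))
table = quantify.CountTable(counts, meta)

print("RPM columns sum to 1e6:", table.rpm.sum(axis=0).round(3).to_dict())
log2fc = quantify.transcript_fold_change(table, "kd_rep1", "ctrl_rep1")
totals = table.counts["kd_rep1"] + table.counts["ctrl_rep1"]
result = quantify.call_regulated_transcripts(log2fc, totals)
print(f"regulated transcripts: {result.n_down} down, {result.n_up} up "
      f"(down/up ratio {result.down_up_ratio:.2f})"
      if not result.ratio_infinite
      else f"regulated transcripts: {result.n_down} down, 0 up (ratio infinite)")

gene_rpm = quantify.gene_level_expression(table)
strata = quantify.expression_strata(gene_rpm["ctrl_rep1"])
gene_fc = quantify.gene_fold_change(table, "kd_rep1", "ctrl_rep1")
ks = quantify.stratified_ks(gene_fc, strata, ("low", "high"))
print(f"K-S low- vs high-expression genes: D={ks.statistic:.3f} p={ks.pvalue:.3g}")
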