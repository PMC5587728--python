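"""APA significance testing and global trends.

Per gene, the two most abundant 3'UTR isoforms form a 2x2 table against the
two samples; Fisher's exact test with BH-FDR control calls significant
switches, RED = log2(distal/proximal) gives the direction (dRED < 0 means
3'UTR shortening), and the global trend is log2 of the shortened-to-
lengthened gene count ratio.  Run examples/03_pas_atlas.py first.
"""

import pandas as pd

from apakit import apa
from apakit.atlas import frame_to_counts
from apakit.quantify import CountTable

counts, meta = frame_to_counts(pd.read_csv("example_atlas.tsv", sep="\t"))
table = CountTable(counts, meta)

utr = apa.run_saap_utr(table, ctrl="ctrl_rep1", kd="kd_rep1", seed=0)
trend = apa.gaap_utr_trend(utr)
print(f"genes tested: {int(utr['testable'].sum())}")
print(f"shortened: {trend.n_negative}, lengthened: {trend.n_positive}, "
      f"global trend log2 = {trend.trend:.2f}" if trend.defined
      else "no significant APA genes")
cols = ["gene_id", "p_value", "fdr", "red_ctrl", "red_kd", "delta_red", "direction"]
print(utr.sort_values("fdr").head(5)[cols].to_string(index=False))

ur, ur_trend = apa.run_ur_group_test(table, ctrl="ctrl_rep1", kd="kd_rep1", seed=0)
print(f"upstream-region PAS usage: {ur_trend.n_positive} activated, "
      f"{ur_trend.n_negative} suppressed")
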