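"""Identify PAS-supporting (PASS) reads in aligned 3' end sequencing data.

A PASS read is uniquely mapped (MAPQ > 10) and carries at least two
soft-clipped 5' Ts the genome cannot explain - the residue of the poly(A)
tail, and the evidence that the read marks a real cleavage site.  Run
examples/01_simulate_fixture.py first.
"""

import pyfaidx

from apakit.pass_reads import call_pass_reads, tally_to_frame

genome = pyfaidx.Fasta("example_fixture/genome.fa")
result = call_pass_reads(
    "example_fixture/reads_ctrl_rep1.sam", genome, sample_id="ctrl_rep1"
)

print(f"alignments processed : {result.n_records}")
print(f"PASS events          : {result.n_events}")
for reason, count in sorted(result.rejections.items()):
    print(f"rejected ({reason}): {count}")
# Each retained event is a single-nucleotide cleavage position; counts at
# the same position accumulate per sample.
frame = tally_to_frame(result.tally)
print(frame.head(5).to_string(index=False))
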