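# Methods

This note records the models, conventions and numerical choices behind
`apakit`, and what the synthetic benchmarks do and do not demonstrate.

## PASS-read model

3′ end sequencing reads terminate at the cleavage site and retain poly(A)
residue. After local alignment the tail is soft-clipped, and the package
calls a read *PAS-supporting* (PASS) when it is uniquely mapped with
MAPQ > 10 and its read-5′ soft clip begins with at least two Ts that the
genome cannot explain. Two conventions required decisions the underlying
protocol description leaves open:

- **Read orientation.** The default convention treats reads as reverse
  complements of transcript 3′ ends: a plus-strand gene yields a
  minus-strand alignment whose tail appears (in SAM orientation) as a
  trailing soft-clipped A-stretch, and vice versa. The PAS strand is the
  opposite of the alignment strand. Sense-orientation data are supported
  via `tail_mode="three_prime_a"` (tail = trailing As in read orientation),
  and the simulator can emit either convention (`orientation=`).
- **Genomic-tail subtraction.** Clipped tail bases are counted from the
  read 5′ end; when the entire clip is a tail-base run, residues that match
  the reference extended outward from the alignment boundary are
  subtracted, since an aligner could have aligned them — this guards
  against internal priming at genomic A/T stretches. Only contiguous Ts
  from the read 5′ end are counted; the clip is not required to be T-only.
- **Uniqueness** is operationalised as "primary alignment with MAPQ > 10";
  no separate multi-hit tag is consulted.

The cleavage position is the aligned base abutting the clip — the last
transcribed nucleotide — in 0-based coordinates.

## Atlas construction

Cleavage positions are clustered by the iterative greedy rule: repeatedly
the unclustered site with the highest pooled count becomes a representative
and absorbs all unclustered sites within ±24 nt *of it* (membership is
measured from the representative, not chained). Ties are broken 5′-most in
transcript orientation, making the procedure deterministic; the test suite
checks equality with an independent brute-force oracle over a thousand
random instances.

Gene assignment uses the annotated span plus a downstream extension
(default 4,000 nt genome-scale; the toy genome uses 400 nt to keep
neighbouring genes' territories disjoint). A cluster in the 3′-most exon or
the extension is a `three_prime_region` site; anywhere else within the gene
it is `upstream` (intron/internal exon). The abundance filter retains a
cluster only if *one and the same sample* gives it ≥ 2 PASS reads and
> 5 % of the gene's PASS reads; both thresholds are configurable, and
relaxation is provably monotone.

Poly(A)-signal classes are assigned hierarchically from the −40..−1
transcript-orientation sequence: AAUAAA, else one of ten single-nucleotide
variant hexamers (AUUAAA, UAUAAA, AGUAAA, AAGAAA, AAUAUA, AAUACA, CAUAAA,
GAUAAA, AAUGAA, ACUAAA — configurable, as published variant lists differ),
else an A-rich hexamer (≥ 5 adenosines, configurable), else none.

## Expression and regulation

Isoform expression is RPM — reads per million PASS reads in the sample —
and gene expression the sum over its retained isoforms, so RPM columns sum
to 10⁶ exactly and gene sums conserve it. Fold changes are log₂ RPM ratios
stabilised by a pseudocount of one read converted to each sample's RPM
scale (configurable, including 0). Regulation calls require
|log₂FC| > log₂(2) and > 50 raw reads summed over the two samples; raw
reads rather than RPM gate the evidence. Expression strata are quartiles
(< 25th, 25–75th, > 75th percentile) of control-sample gene RPM, compared
with two-sided two-sample K-S tests; sample clustering is average linkage
on 1 − Pearson correlation over the regulated set.

## APA statistics

For each gene with ≥ 2 retained 3′-region isoforms, the two most abundant
(pooled counts, ties 5′-most) form the proximal/distal pair — standard
practice when more than two PASs exist, configurable in principle through
the cluster inputs. The pairwise significance test is a two-sided Fisher's
exact test on the isoform × sample 2×2 table, with Benjamini–Hochberg FDR
across genes at 0.05; tables with a zero margin are flagged untestable and
excluded from FDR accounting. This exact-test formulation is this package's
implementation of pairwise APA significance analysis; an optional minimum
|ΔRED| effect-size gate exists and defaults to off.

RED = log₂((distal + 1)/(proximal + 1)) per sample; ΔRED = RED_kd −
RED_ctrl, so ΔRED < 0 is 3′UTR shortening. The global trend is
log₂((#shortened + 0.5)/(#lengthened + 0.5)); the +0.5 avoids division by
zero and is reported alongside raw counts. Sequencing-depth differences are
equalised before testing by seeded binomial thinning of the deeper sample
to the shallower sample's PASS total (a no-op at equal depth; switchable
off). Upstream-region analysis aggregates counts within the UR and
3′-region groups per sample and applies the same machinery; "activated"
means the relative UR share rose in the knockdown. Swapping sample labels
provably negates every ΔRED and swaps the direction tallies.

## Motif scoring

Position p of a width-7 PFM has information content
Iₚ = 2 − Hₚ bits (Hₚ the Shannon entropy of its four frequencies,
0·log₂0 ≡ 0), and a window scores Σₚ f₍ₚ,ₙ₍ₚ₎₎·Iₚ: 0 for a uniform PFM,
14 for the consensus under a fully conserved one. Ambiguous bases
contribute 0 — conservative and always defined. Scanning covers every
fully contained window of the −100..+100 flank (195 windows); the
−100..−41 region mean uses only windows lying entirely inside it (starts
−100..−47, 54 windows), so no sequence outside the stated region is
scored; averaging over partially overlapping edge windows is available
behind the region parameter. Meta-profiles are positionwise means smoothed
by LOWESS with span 0.05 and one robustness iteration. Percentile groups
use linear interpolation with ties at the cutoff falling to the lower
group; 4-mer enrichment counts presence/absence per sequence and tests the
2×2 with Fisher's exact test (256 rows per region; downstream regions
+1..+40 and +41..+100 mirror the two defined upstream regions); signal
composition between PAS groups uses a chi-square test of homogeneity,
falling back to a collapsed 2×2 exact test when an expected cell drops
below 1.

The bundled PFM (`example_pfm()`, consensus GCAUAGC at 0.97 per-position
conservation) is synthetic: an AUA core in a GC context built for
simulation and examples, not a measured binding model.

## The synthetic experiment

The generator emulates the statistical structure the analysis keys on, at
desk scale:

- **Architecture.** Non-overlapping genes on one contig (spacing larger
  than the downstream extension, so assignment is unambiguous), 2–4 PASs
  per gene ({2: 0.55, 3: 0.30, 4: 0.15}); 25 % of ≥3-PAS genes get an
  upstream (gene-body) PAS and 15 % of genes a PAS in the 3′ extension;
  15 % of genes are lncRNA. Every PAS keeps a full −100..+100 flank inside
  the contig.
- **Expression and usage.** Gene expression weights are log-uniform over
  ~2.5 orders of magnitude (spanning the percentile strata); PAS usage is
  Dirichlet(5). A configured fraction of genes (default 30 %) carries a
  knockdown effect: the distal member of the gene's two most-used
  3′-region isoforms — the pair a 3′UTR-APA analysis compares — has its
  usage multiplied by 2^(−1.5) in the knockdown and renormalised. Planted
  genes model a clear switch between two dominant isoforms, so other
  3′-region isoforms are capped at 0.6× the pair minimum; without this a
  near-equal third isoform can displace the shifted one from the analysed
  pair and the truth table would mislabel the gene's observable effect.
- **Reads.** Cleavage positions jitter uniformly ±2 nt (so 24-nt
  clustering matters); tail lengths follow a distribution with
  P(tail < 2) ≈ 0.1 (so the PASS filter matters); 5 % of alignments get
  MAPQ ≤ 10. Reads carry the tail as a soft clip adjacent to the cleavage
  end, per the orientation convention above, and the simulator records
  each read's ground-truth non-genomic tail using the same outward-walk
  definition, so PASS counting can be checked exactly.
- **Motifs.** A configured fraction of PASs (default 10 %) is flagged
  "polymerase-dependent" and receives six PFM-consensus occurrences at
  random starts in the −100..−47 window — a motif-dense upstream region.
  One occurrence is statistically unrecoverable through a 54-window region
  mean at these group sizes (power analysis during design); a dense
  region, consistent with broadly elevated motif profiles upstream of
  factor-dependent PASs, is recoverable with large margins.

All randomness flows from one mandatory seed; identical configurations
give byte-identical fixture bundles (checksummed manifests).

**What the simulation does not model:** adapter/RT/PCR artifacts, base-call
errors and meaningful quality strings, overlapping or multi-contig genes,
expression-level changes between conditions (usage shifts only, unless the
truth table is edited), internal-priming decoys beyond genomic-A adjacency,
and replicate-level biological variability. Passing the recovery benchmarks
therefore shows the statistics are implemented correctly and are powered
under the stated conditions — not that real 3′ end libraries meet those
conditions.

## Problem sizes used in validation

The default test fixture is 30 genes × 2 samples × 8,000 reads (SAM
round-trip, PASS fidelity, pipeline determinism). APA parameter recovery
uses 500 genes with 150 planted −1.5 shifts at 250 reads/gene/sample
(counts-level draws); observed sensitivity is ≈ 0.95–0.97 with ≤ 1.5 %
wrong-direction calls among significant genes. Motif recovery uses ~1,000
PASs with 100 planted. The Fisher oracle enumerates every 2×2 table with
all margins ≤ 30. These sizes were chosen so each property is tested with
clear statistical margin while the whole suite stays quick on a laptop.

## Known limitations

- The pairwise APA test assumes two samples; replicates of a condition are
  pooled rather than modelled (no dispersion estimation).
- Gene assignment assumes non-overlapping genes per strand; overlapping
  annotations would need a precedence rule the package does not define.
- The A-rich signal rule and the variant-hexamer list are simple,
  configurable stand-ins for the several definitions in circulation.
- LOWESS smoothing near flank edges has the usual endpoint bias; peak
  locations within ±3 nt are what the tests guarantee.
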