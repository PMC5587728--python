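"""Building a poly(A)-site atlas from cleavage events.

Cleavage positions observed by 3' end sequencing are heterogeneous over a
few nucleotides; sites within 24 nt are therefore iteratively clustered and
each cluster is represented by its most supported position.  Clusters are
assigned to genes (gene span plus a configurable downstream extension),
labelled by region (3'-most exon / extension versus upstream), filtered by
abundance (>= 2 PASS reads and > 5% of the gene's reads in at least one
sample) and annotated with their poly(A)-signal class from the -40..-1
upstream sequence.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import fetch, revcomp, to_rna
from .pass_reads import SiteKey

#: Ten single-nucleotide variants of AAUAAA commonly used as the "variant"
#: poly(A)-signal class.  Configurable because published variant lists
#: differ slightly.
DEFAULT_VARIANT_HEXAMERS = (
    "AUUAAA",
    "UAUAAA",
    "AGUAAA",
    "AAGAAA",
    "AAUAUA",
    "AAUACA",
    "CAUAAA",
    "GAUAAA",
    "AAUGAA",
    "ACUAAA",
)

THREE_PRIME = "three_prime_region"
UPSTREAM = "upstream"


@dataclass
class PASCluster:
    """A clustered poly(A) site.

    ``representative`` is the member position with the greatest pooled PASS
    count (ties broken 5'-most in transcript orientation); every member lies
    within the clustering window of it.
    """

    contig: str
    strand: str
    representative: int
    members: dict[int, int]  # position -> pooled count
    per_sample: Counter = field(default_factory=Counter)
    cluster_id: str = ""
    gene_id: str | None = None
    region: str | None = None
    signal_class: str | None = None

    def __post_init__(self):
        if not self.cluster_id:
            self.cluster_id = f"{self.contig}:{self.strand}:{self.representative}"

    @property
    def pooled_count(self) -> int:
        return sum(self.members.values())


def cluster_cleavage_sites(
    tally: Mapping[SiteKey, Mapping[str, int]], window: int = 24
) -> list[PASCluster]:
    """Iterative greedy clustering of cleavage sites within ``window`` nt.

    Repeatedly the unclustered site with the highest pooled count becomes a
    representative and absorbs every unclustered site within +/- ``window``
    nt of it.  Ties on the pooled count are broken 5'-most in transcript
    orientation (lowest coordinate on '+', highest on '-').  Membership is
    measured from the representative, not chained.
    """
    by_group: dict[tuple[str, str], list[tuple[int, int, Counter]]] = defaultdict(list)
    for (contig, strand, pos), samples in tally.items():
        counter = Counter(samples)
        by_group[(contig, strand)].append((pos, sum(counter.values()), counter))

    clusters: list[PASCluster] = []
    for (contig, strand), sites in sorted(by_group.items()):
        remaining = dict((pos, (pooled, counter)) for pos, pooled, counter in sites)
        five_prime_sign = 1 if strand == "+" else -1
        while remaining:
            rep = min(
                remaining,
                key=lambda p: (-remaining[p][0], five_prime_sign * p),
            )
            member_pos = [p for p in remaining if abs(p - rep) <= window]
            members = {p: remaining[p][0] for p in member_pos}
            per_sample: Counter = Counter()
            for p in member_pos:
                per_sample.update(remaining[p][1])
                del remaining[p]
            clusters.append(
                PASCluster(
                    contig=contig,
                    strand=strand,
                    representative=rep,
                    members=members,
                    per_sample=per_sample,
                )
            )
    clusters.sort(key=lambda c: (c.contig, c.strand, c.representative))
    return clusters


def annotate_pas_location(
    clusters: Iterable[PASCluster],
    annotation: pd.DataFrame,
    extension: int = 4000,
) -> list[PASCluster]:
    """Assign clusters to genes and label their region.

    A cluster is assigned to a same-strand gene if its representative lies
    within the gene span or within ``extension`` nt downstream of the
    gene's 3' end (genes are assumed non-overlapping per strand).  The
    region is ``three_prime_region`` when the representative falls in the
    3'-most exon or the downstream extension, otherwise ``upstream``.
    Unassigned clusters keep ``gene_id`` None.
    """
    genes_by_group: dict[tuple[str, str], list] = defaultdict(list)
    for row in annotation.itertuples(index=False):
        genes_by_group[(row.contig, row.strand)].append(row)

    out = list(clusters)
    for cluster in out:
        cluster.gene_id = None
        cluster.region = None
        for gene in genes_by_group.get((cluster.contig, cluster.strand), ()):
            if gene.strand == "+":
                lo, hi = gene.gene_start, gene.gene_end + extension
                tp_lo, tp_hi = gene.last_exon_start, gene.gene_end + extension
            else:
                lo, hi = gene.gene_start - extension, gene.gene_end
                tp_lo, tp_hi = gene.gene_start - extension, gene.last_exon_end
            if lo <= cluster.representative < hi:
                cluster.gene_id = gene.gene_id
                cluster.region = (
                    THREE_PRIME
                    if tp_lo <= cluster.representative < tp_hi
                    else UPSTREAM
                )
                break
    return out


def gene_totals_per_sample(
    clusters: Iterable[PASCluster],
) -> dict[str, Counter]:
    """Per-gene, per-sample PASS totals over the given clusters."""
    totals: dict[str, Counter] = defaultdict(Counter)
    for cluster in clusters:
        if cluster.gene_id is not None:
            totals[cluster.gene_id].update(cluster.per_sample)
    return totals


def filter_pas_clusters(
    clusters: Sequence[PASCluster],
    min_reads: int = 2,
    min_frac: float = 0.05,
) -> list[PASCluster]:
    """Abundance filter: keep clusters with real support in some sample.

    A cluster is retained iff there exists a sample in which it has at
    least ``min_reads`` PASS reads *and* more than ``min_frac`` of its
    gene's PASS reads (both conditions in the same sample).  Gene totals
    are computed over all annotated clusters before filtering; unassigned
    clusters are dropped because no gene fraction is defined for them.
    """
    totals = gene_totals_per_sample(clusters)
    retained = []
    for cluster in clusters:
        if cluster.gene_id is None:
            continue
        gene_total = totals[cluster.gene_id]
        for sample, count in cluster.per_sample.items():
            total = gene_total[sample]
            if count >= min_reads and total > 0 and count / total > min_frac:
                retained.append(cluster)
                break
    return retained


def classify_pas_signal(
    flank: str,
    variant_hexamers: Sequence[str] = DEFAULT_VARIANT_HEXAMERS,
    a_rich_min_a: int = 5,
) -> str:
    """Classify the -40..-1 upstream sequence of a PAS.

    Hierarchical: AAUAAA anywhere -> ``AAUAAA``; else any variant hexamer
    -> ``variant``; else any hexamer with >= ``a_rich_min_a`` adenosines ->
    ``A_rich``; else ``none``.  The flank is given 5'->3' in transcript
    orientation; shorter flanks (contig edges) are classified as-is.
    """
    seq = to_rna(flank)
    if any(b not in "ACGU" for b in seq):
        raise ValueError("flank contains non-ACGT(U) characters")
    if "AAUAAA" in seq:
        return "AAUAAA"
    variants = {to_rna(v) for v in variant_hexamers}
    for i in range(len(seq) - 5):
        if seq[i : i + 6] in variants:
            return "variant"
    for i in range(len(seq) - 5):
        if seq[i : i + 6].count("A") >= a_rich_min_a:
            return "A_rich"
    return "none"


def upstream_signal_flank(reference, cluster: PASCluster, length: int = 40) -> str:
    """The -length..-1 transcript-orientation sequence upstream of a PAS."""
    pos = cluster.representative
    if cluster.strand == "+":
        return fetch(reference, cluster.contig, pos - length, pos)
    return revcomp(fetch(reference, cluster.contig, pos + 1, pos + 1 + length))


def attach_signal_classes(
    clusters: Iterable[PASCluster],
    reference,
    variant_hexamers: Sequence[str] = DEFAULT_VARIANT_HEXAMERS,
) -> None:
    for cluster in clusters:
        flank = upstream_signal_flank(reference, cluster)
        cluster.signal_class = classify_pas_signal(flank, variant_hexamers)


def clusters_to_frame(
    clusters: Sequence[PASCluster], samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tabular atlas: one row per cluster with per-sample counts."""
    if samples is None:
        seen: list[str] = []
        for c in clusters:
            for s in c.per_sample:
                if s not in seen:
                    seen.append(s)
        samples = sorted(seen)
    rows = []
    for c in clusters:
        row = {
            "cluster_id": c.cluster_id,
            "contig": c.contig,
            "position": c.representative,
            "strand": c.strand,
            "gene_id": c.gene_id,
            "region": c.region,
            "signal_class": c.signal_class,
            "n_members": len(c.members),
            "pooled_count": c.pooled_count,
        }
        for s in samples:
            row[f"count_{s}"] = c.per_sample.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_counts(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an atlas frame into (counts, metadata), indexed by cluster_id."""
    frame = frame.set_index("cluster_id")
    count_cols = [c for c in frame.columns if c.startswith("count_")]
    counts = frame[count_cols].rename(columns=lambda c: c[len("count_") :])
    meta = frame.drop(columns=count_cols)
    return counts, meta


def clusters_to_bed(clusters: Sequence[PASCluster]) -> str:
    """BED6 representation (chrom, representative, representative+1)."""
    lines = []
    for c in clusters:
        name = f"{c.gene_id or 'NA'}|{c.cluster_id}"
        lines.append(
            f"{c.contig}\t{c.representative}\t{c.representative + 1}\t"
            f"{name}\t{c.pooled_count}\t{c.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
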