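"""Synthetic 3' end sequencing data with known ground truth.

Generates a toy genome with non-overlapping multi-PAS genes, per-condition
PAS usage proportions with planted knockdown effects, and aligned reads in
SAM format that carry the hallmarks the downstream analysis keys on:
poly(A)-derived non-genomic 5' T stretches of variable length, cleavage
heterogeneity of a few nucleotides, a configurable fraction of low-MAPQ
alignments, and PFM-consensus motif occurrences planted upstream of
"polymerase-dependent" PASs.  All randomness flows from a single seed, so
an identical configuration reproduces a byte-identical fixture bundle.

Read/strand convention
----------------------
Reads are reverse complements of transcript 3' ends, so a read from a
plus-strand gene aligns to the minus genome strand and its tail appears in
SAM orientation as a trailing soft-clipped A stretch; a minus-strand gene
yields a forward alignment with a leading soft-clipped T stretch.  The
alternative sense-orientation convention is available via
``orientation="sense"``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .motif import Pfm, example_pfm

BASES = np.array(list("ACGT"))

REGION_THREE_PRIME_EXON = "three_prime_exon"
REGION_EXTENDED = "extended"
REGION_UPSTREAM = "upstream"

_LAST_EXON_LEN = 420
_BODY_LEN = 260
_UTR_PAS_OFFSETS = (130, 200, 270, 340)  # within the last exon, 5'->3'
_UPSTREAM_PAS_OFFSET = 130  # within the gene body, 5'->3'
_EXTENDED_PAS_OFFSET = 120  # downstream of the gene 3' end
_EDGE_MARGIN = 250


class SizingError(ValueError):
    """The requested contig cannot hold the requested genes."""


@dataclass(frozen=True)
class PasSite:
    """One annotated poly(A) site of a gene model."""

    position: int  # 0-based genomic coordinate of the last transcribed nt
    region: str  # three_prime_exon | extended | upstream
    motif_planted: bool = False


@dataclass
class GeneModel:
    """A toy gene: span, strand, 3'-most exon and its PAS repertoire.

    ``pas_list`` is ordered 5'->3' in transcript orientation (ascending
    genomic coordinates on '+', descending on '-').
    """

    gene_id: str
    contig: str
    strand: str
    gene_span: tuple[int, int]  # half-open
    last_exon_span: tuple[int, int]  # half-open
    biotype: str  # mRNA | lncRNA
    pas_list: list[PasSite]

    def validate(self, contig_length: int, extension: int) -> None:
        lo, hi = self.gene_span
        if not (0 <= lo < hi <= contig_length):
            raise ValueError(f"{self.gene_id}: gene span outside contig")
        sign = 1 if self.strand == "+" else -1
        positions = [sign * p.position for p in self.pas_list]
        if not self.pas_list:
            raise ValueError(f"{self.gene_id}: empty pas_list")
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError(f"{self.gene_id}: PASs not strictly 5'->3'")
        for pas in self.pas_list:
            if self.strand == "+":
                lo_ok, hi_ok = lo, hi + extension
            else:
                lo_ok, hi_ok = lo - extension, hi
            if not (lo_ok <= pas.position < hi_ok):
                raise ValueError(f"{self.gene_id}: PAS outside extended span")


@dataclass
class GenomeAssets:
    """A toy genome plus its gene annotation."""

    contigs: dict[str, str]
    annotation: list[GeneModel]
    extension: int = 400
    pfm: Pfm | None = None

    def validate(self) -> None:
        for name, seq in self.contigs.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} has non-ACGT characters")
        for gene in self.annotation:
            gene.validate(len(self.contigs[gene.contig]), self.extension)

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "contig": g.contig,
                    "strand": g.strand,
                    "gene_start": g.gene_span[0],
                    "gene_end": g.gene_span[1],
                    "last_exon_start": g.last_exon_span[0],
                    "last_exon_end": g.last_exon_span[1],
                    "biotype": g.biotype,
                }
                for g in self.annotation
            ]
        )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic 3' end experiment.

    The defaults describe a desk-scale two-condition knockdown experiment:
    a modest number of multi-PAS genes, gene expression spanning ~2.5
    orders of magnitude, cleavage jitter of +/-2 nt (so 24-nt clustering
    matters), a tail-length distribution with P(tail < 2) ~ 0.1 (so the
    PASS filter matters), 5% low-MAPQ alignments, 30% of genes with a
    -1.5 log2 shift of distal-PAS usage in the knockdown, and 10% of PASs
    with a motif-dense upstream region (six planted PFM-consensus
    occurrences in -100..-41).
    """

    seed: int
    n_genes: int = 60
    n_pas_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.55, 3: 0.30, 4: 0.15}
    )
    samples: tuple[tuple[str, str, int], ...] = (
        ("ctrl_rep1", "ctrl", 50_000),
        ("kd_rep1", "kd", 50_000),
    )
    conditions: tuple[str, ...] = ("ctrl", "kd")
    tail_probs: tuple[float, ...] = (0.04, 0.06, 0.20, 0.25, 0.20, 0.15, 0.10)
    cleavage_jitter: int = 2
    frac_low_mapq: float = 0.05
    planted_shift_fraction: float = 0.30
    planted_shift_log2: float = -1.5
    planted_motif_fraction: float = 0.10
    planted_motifs_per_pas: int = 6
    upstream_pas_prob: float = 0.25
    extended_pas_prob: float = 0.15
    lncrna_fraction: float = 0.15
    extension: int = 400
    read_length: int = 50
    contig_name: str = "chr1"
    contig_length: int | None = None
    orientation: str = "antisense"  # or "sense"
    pfm_conservation: float = 0.97

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "frac_low_mapq",
            "planted_shift_fraction",
            "planted_motif_fraction",
            "upstream_pas_prob",
            "extended_pas_prob",
            "lncrna_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not np.isclose(sum(self.tail_probs), 1.0):
            raise ValueError("tail_probs must sum to 1")
        if not np.isclose(sum(self.n_pas_per_gene.values()), 1.0):
            raise ValueError("n_pas_per_gene probabilities must sum to 1")
        if self.orientation not in ("antisense", "sense"):
            raise ValueError("orientation must be 'antisense' or 'sense'")
        if self.extension < _EXTENDED_PAS_OFFSET + 100:
            raise ValueError(
                f"extension must be >= {_EXTENDED_PAS_OFFSET + 100} to keep "
                "extended-PAS flanks inside assigned territory"
            )

    @property
    def pfm(self) -> Pfm:
        return example_pfm(conservation=self.pfm_conservation)

    def to_dict(self) -> dict:
        data = asdict(self)
        data["n_pas_per_gene"] = {int(k): float(v) for k, v in self.n_pas_per_gene.items()}
        data["samples"] = [list(s) for s in self.samples]
        return data

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "n_pas_per_gene" in data:
            data["n_pas_per_gene"] = {
                int(k): float(v) for k, v in dict(data["n_pas_per_gene"]).items()
            }
        if "samples" in data:
            data["samples"] = tuple(tuple(s) for s in data["samples"])
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        if "tail_probs" in data:
            data["tail_probs"] = tuple(data["tail_probs"])
        return cls(**data)


@dataclass
class TruthTable:
    """Ground truth of the simulation.

    ``genes``: one row per gene with biotype and expected RPM per
    condition.  ``pas``: one row per PAS with usage proportion per
    condition (summing to 1 within gene and condition), the planted-motif
    flag and the intended regulation direction of the gene's distal PAS.
    """

    genes: pd.DataFrame
    pas: pd.DataFrame
    conditions: tuple[str, ...]

    def validate(self) -> None:
        for cond in self.conditions:
            expr = self.genes[f"expr_{cond}"]
            if (expr <= 0).any():
                raise ValueError("expression levels must be positive")
            sums = self.pas.groupby("gene_id")[f"usage_{cond}"].sum()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"usage proportions do not sum to 1 in {cond}")
            usage = self.pas[f"usage_{cond}"]
            if ((usage < 0) | (usage > 1)).any():
                raise ValueError("usage proportions outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return self.pas.merge(self.genes, on="gene_id", how="left")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, conditions: Sequence[str]
    ) -> "TruthTable":
        gene_cols = ["gene_id", "biotype", "strand", "planted_direction"] + [
            f"expr_{c}" for c in conditions
        ]
        genes = frame[gene_cols].drop_duplicates("gene_id").reset_index(drop=True)
        pas_cols = [
            c
            for c in frame.columns
            if c not in set(gene_cols) - {"gene_id"}
        ]
        return cls(
            genes=genes, pas=frame[pas_cols].copy(), conditions=tuple(conditions)
        )


def _gene_footprint(config: SimulationConfig) -> int:
    return _BODY_LEN + _LAST_EXON_LEN


def _spacing(config: SimulationConfig) -> int:
    # Keeps neighbouring genes' extensions and motif/flank windows disjoint.
    return config.extension + 300


def build_toy_genome(config: SimulationConfig) -> GenomeAssets:
    """Generate the toy genome and annotation for a configuration.

    Genes are laid out left to right on one contig with spacing larger
    than the downstream extension, so gene assignment is unambiguous.  A
    deterministic function of the seed; flagged PASs receive
    ``planted_motifs_per_pas`` PFM-consensus occurrences at random starts
    in their -100..-47 upstream window (transcript orientation).
    """
    rng = np.random.default_rng(config.seed)
    footprint = _gene_footprint(config)
    spacing = _spacing(config)
    needed = 2 * _EDGE_MARGIN + config.n_genes * footprint + (
        config.n_genes - 1
    ) * spacing + config.extension
    length = config.contig_length if config.contig_length else needed
    if length < needed:
        raise SizingError(
            f"contig length {length} too small for {config.n_genes} genes "
            f"(need >= {needed})"
        )
    seq = rng.choice(4, size=length)

    pas_choices = sorted(config.n_pas_per_gene)
    pas_probs = [config.n_pas_per_gene[k] for k in pas_choices]
    genes: list[GeneModel] = []
    cursor = _EDGE_MARGIN
    for i in range(config.n_genes):
        g0 = cursor
        g1 = g0 + footprint
        cursor = g1 + spacing
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lncRNA" if rng.random() < config.lncrna_fraction else "mRNA"
        n_pas = int(rng.choice(pas_choices, p=pas_probs))
        has_upstream = n_pas >= 3 and rng.random() < config.upstream_pas_prob
        has_extended = rng.random() < config.extended_pas_prob
        n_utr = n_pas - int(has_upstream) - int(has_extended)
        if n_utr < 1:
            has_extended = False
            n_utr = n_pas - int(has_upstream)

        if strand == "+":
            last_exon = (g1 - _LAST_EXON_LEN, g1)
            utr_pos = [last_exon[0] + off for off in _UTR_PAS_OFFSETS[:n_utr]]
            upstream_pos = g0 + _UPSTREAM_PAS_OFFSET
            extended_pos = g1 - 1 + _EXTENDED_PAS_OFFSET
        else:
            last_exon = (g0, g0 + _LAST_EXON_LEN)
            utr_pos = [last_exon[1] - 1 - off for off in _UTR_PAS_OFFSETS[:n_utr]]
            upstream_pos = g1 - 1 - _UPSTREAM_PAS_OFFSET
            extended_pos = g0 - _EXTENDED_PAS_OFFSET

        sites: list[PasSite] = []
        if has_upstream:
            sites.append(PasSite(upstream_pos, REGION_UPSTREAM))
        sites.extend(PasSite(p, REGION_THREE_PRIME_EXON) for p in utr_pos)
        if has_extended:
            sites.append(PasSite(extended_pos, REGION_EXTENDED))
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:04d}",
                contig=config.contig_name,
                strand=strand,
                gene_span=(g0, g1),
                last_exon_span=last_exon,
                biotype=biotype,
                pas_list=sites,
            )
        )

    # Motif planting: flag an exact fraction of all PASs, then write the
    # PFM consensus (as DNA) into the upstream window in transcript
    # orientation.
    all_sites = [(gi, si) for gi, g in enumerate(genes) for si in range(len(g.pas_list))]
    n_flagged = int(round(config.planted_motif_fraction * len(all_sites)))
    flagged_idx = rng.choice(len(all_sites), size=n_flagged, replace=False)
    consensus_dna = config.pfm.consensus.replace("U", "T")
    cons_codes = np.array(["ACGT".index(b) for b in consensus_dna])
    width = len(consensus_dna)
    for k in sorted(flagged_idx):
        gi, si = all_sites[k]
        gene = genes[gi]
        pas = gene.pas_list[si]
        gene.pas_list[si] = PasSite(pas.position, pas.region, motif_planted=True)
        for _ in range(config.planted_motifs_per_pas):
            start = int(rng.integers(-100, -47 + 1))  # window start offset
            if gene.strand == "+":
                a = pas.position + start
                seq[a : a + width] = cons_codes
            else:
                a = pas.position - start - (width - 1)
                seq[a : a + width] = cons_codes[::-1] ^ 3  # revcomp in 2-bit space

    # 2-bit codes use A=0,C=1,G=2,T=3 so complement is code ^ 3.
    contig_seq = "".join(BASES[seq])
    assets = GenomeAssets(
        contigs={config.contig_name: contig_seq},
        annotation=genes,
        extension=config.extension,
        pfm=config.pfm,
    )
    assets.validate()
    return assets


def plan_truth(assets: GenomeAssets, config: SimulationConfig) -> TruthTable:
    """Draw ground-truth expression and usage, planting knockdown effects.

    Per-gene expression weights span roughly 2.5 orders of magnitude
    (log-uniform), identical across conditions; PAS usage proportions are
    Dirichlet-distributed.  An exact count of genes
    (``round(planted_shift_fraction * n_genes)``, among genes with at
    least two 3' region PASs) get their distal (3'-most) PAS usage
    multiplied by ``2**planted_shift_log2`` in the knockdown condition and
    renormalised.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = assets.annotation
    n = len(genes)
    weights = 10 ** rng.uniform(0.0, 2.5, size=n)
    expr_rpm = weights / weights.sum() * 1e6

    eligible = [
        i
        for i, g in enumerate(genes)
        if sum(p.region != REGION_UPSTREAM for p in g.pas_list) >= 2
    ]
    n_planted = int(round(config.planted_shift_fraction * n))
    if n_planted > len(eligible):
        warnings.warn(
            f"only {len(eligible)} genes eligible for a planted usage shift; "
            f"requested {n_planted}"
        )
        n_planted = len(eligible)
    planted = set(
        rng.choice(eligible, size=n_planted, replace=False).tolist()
    )
    direction = "down" if config.planted_shift_log2 < 0 else "up"

    gene_rows = []
    pas_rows = []
    for i, gene in enumerate(genes):
        k = len(gene.pas_list)
        usage = rng.dirichlet(np.full(k, 5.0))
        usages = {cond: usage.copy() for cond in config.conditions}
        gene_direction = "none"
        target = k - 1
        if i in planted and config.planted_shift_log2 != 0:
            gene_direction = direction
            # The perturbed site is the distal isoform of the pair a 3'UTR
            # APA analysis compares: of the two most-used 3'-region PASs,
            # the 3'-most one (pas_list is ordered 5'->3').  A planted gene
            # models a clear switch between its two dominant isoforms, so
            # any further 3'-region isoform is capped well below the pair
            # (keeping the pair dominant in both conditions even after the
            # knockdown shift reduces the target's abundance).
            eligible_idx = [
                si
                for si, p in enumerate(gene.pas_list)
                if p.region != REGION_UPSTREAM
            ]
            by_usage = sorted(eligible_idx, key=lambda si: -usage[si])
            pair = set(by_usage[:2])
            target = max(pair)
            cap = 0.6 * min(usage[si] for si in pair)
            excess = 0.0
            for si in eligible_idx:
                if si not in pair and usage[si] > cap:
                    excess += usage[si] - cap
                    usage[si] = cap
            if excess:
                pair_total = sum(usage[si] for si in pair)
                for si in pair:
                    usage[si] *= (pair_total + excess) / pair_total
            usages = {cond: usage.copy() for cond in config.conditions}
            for cond in config.conditions:
                if cond == "ctrl":
                    continue
                shifted = usages[cond].copy()
                shifted[target] *= 2.0 ** config.planted_shift_log2
                if (shifted <= 0).any():
                    warnings.warn(
                        f"{gene.gene_id}: clamping non-positive usage after shift"
                    )
                    shifted = np.clip(shifted, 1e-9, None)
                usages[cond] = shifted / shifted.sum()
        gene_rows.append(
            {
                "gene_id": gene.gene_id,
                "biotype": gene.biotype,
                "strand": gene.strand,
                "planted_direction": gene_direction,
                **{f"expr_{c}": expr_rpm[i] for c in config.conditions},
            }
        )
        for si, pas in enumerate(gene.pas_list):
            pas_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "pas_index": si,
                    "position": pas.position,
                    "region": pas.region,
                    "motif_planted": pas.motif_planted,
                    "intended_direction": gene_direction
                    if si == target
                    else "none",
                    **{f"usage_{c}": usages[c][si] for c in config.conditions},
                }
            )
    truth = TruthTable(
        genes=pd.DataFrame(gene_rows),
        pas=pd.DataFrame(pas_rows),
        conditions=tuple(config.conditions),
    )
    truth.validate()
    return truth


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated alignment with its ground-truth provenance."""

    read_id: str
    gene_id: str
    pas_index: int
    contig: str
    cleavage_pos: int  # last transcribed nt after jitter
    pas_strand: str
    tail_len: int
    n_nongenomic_ts: int
    mapq: int
    flag: int
    pos: int  # 0-based leftmost aligned position
    cigar: str
    seq: str

    @property
    def qualifies_pass(self) -> bool:
        """Ground-truth PASS status: unique enough and a real >= 2 nt tail."""
        return self.mapq > 10 and self.n_nongenomic_ts >= 2

    def to_sam(self) -> str:
        return "\t".join(
            [
                self.read_id,
                str(self.flag),
                self.contig,
                str(self.pos + 1),
                str(self.mapq),
                self.cigar,
                "*",
                "0",
                "0",
                self.seq,
                "I" * len(self.seq),
            ]
        )


def _nongenomic_tail(contig_seq: str, pos: int, strand: str, k: int) -> int:
    """Tail length minus residues the genome could also explain.

    Walking outward from the cleavage site along the transcript strand,
    genomic adenosines extend the apparent transcript, so matching tail
    residues are not evidence of polyadenylation.
    """
    g = 0
    for i in range(k):
        if strand == "+":
            j = pos + 1 + i
            base = contig_seq[j] if j < len(contig_seq) else ""
            if base != "A":
                break
        else:
            j = pos - 1 - i
            base = contig_seq[j] if j >= 0 else ""
            if base != "T":
                break
        g += 1
    return k - g


def simulate_sample_reads(
    assets: GenomeAssets,
    truth: TruthTable,
    condition: str,
    n_reads: int,
    seed: int,
    config: SimulationConfig,
) -> list[SimulatedRead]:
    """Draw one sample's reads from the ground truth.

    Genes are drawn proportional to expression, PAS within gene by usage,
    cleavage positions jittered uniformly within +/- ``cleavage_jitter``
    nt, tail lengths from ``tail_probs`` and MAPQ from a two-component
    distribution with ``frac_low_mapq`` of alignments at MAPQ <= 10.
    Deterministic per seed.
    """
    if condition not in truth.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    genes = {g.gene_id: g for g in assets.annotation}
    gene_ids = truth.genes["gene_id"].tolist()
    expr = truth.genes[f"expr_{condition}"].to_numpy()
    p_gene = expr / expr.sum()
    usage_by_gene = {
        gid: grp.sort_values("pas_index")[f"usage_{condition}"].to_numpy()
        for gid, grp in truth.pas.groupby("gene_id")
    }

    gene_draw = rng.choice(len(gene_ids), size=n_reads, p=p_gene)
    jitters = rng.integers(-config.cleavage_jitter, config.cleavage_jitter + 1, n_reads)
    tails = rng.choice(len(config.tail_probs), size=n_reads, p=config.tail_probs)
    low = rng.random(n_reads) < config.frac_low_mapq
    mapqs = np.where(low, rng.integers(0, 11, n_reads), rng.integers(25, 43, n_reads))

    reads: list[SimulatedRead] = []
    length = config.read_length
    for r in range(n_reads):
        gid = gene_ids[gene_draw[r]]
        gene = genes[gid]
        usage = usage_by_gene[gid]
        si = int(rng.choice(len(usage), p=usage))
        pas = gene.pas_list[si]
        pos = pas.position + int(jitters[r])
        k = int(tails[r])
        contig_seq = assets.contigs[gene.contig]
        if gene.strand == "+":
            aligned = contig_seq[pos - length + 1 : pos + 1]
            seq = aligned + "A" * k
            cigar = f"{length}M{k}S" if k else f"{length}M"
            left = pos - length + 1
        else:
            aligned = contig_seq[pos : pos + length]
            seq = "T" * k + aligned
            cigar = f"{k}S{length}M" if k else f"{length}M"
            left = pos
        sam_reverse = (gene.strand == "+") == (config.orientation == "antisense")
        reads.append(
            SimulatedRead(
                read_id=f"{condition}.{r + 1}",
                gene_id=gid,
                pas_index=si,
                contig=gene.contig,
                cleavage_pos=pos,
                pas_strand=gene.strand,
                tail_len=k,
                n_nongenomic_ts=_nongenomic_tail(contig_seq, pos, gene.strand, k),
                mapq=int(mapqs[r]),
                flag=16 if sam_reverse else 0,
                pos=left,
                cigar=cigar,
                seq=seq,
            )
        )
    return reads


def expected_pass_counts(reads: Iterable[SimulatedRead]) -> pd.Series:
    """Truth-side PASS count per (contig, strand, cleavage position)."""
    rows = [
        (r.contig, r.pas_strand, r.cleavage_pos)
        for r in reads
        if r.qualifies_pass
    ]
    index = pd.MultiIndex.from_tuples(rows, names=["contig", "strand", "position"])
    return pd.Series(1, index=index).groupby(level=[0, 1, 2]).sum()


def write_sam(
    reads: Sequence[SimulatedRead], contigs: Mapping[str, str], path
) -> None:
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in contigs.items():
            handle.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for read in reads:
            handle.write(read.to_sam() + "\n")


def write_fasta(contigs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in contigs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_fixture_bundle(
    assets: GenomeAssets,
    truth: TruthTable,
    reads_by_sample: Mapping[str, Sequence[SimulatedRead]],
    out_dir,
    config: SimulationConfig | None = None,
) -> dict[str, str]:
    """Write a complete on-disk fixture: FASTA, TSVs, SAMs, config, manifest.

    Returns the manifest (file name -> sha256), which is also written as
    ``manifest.json``.  Re-running with the same inputs produces identical
    checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    genome = out / "genome.fa"
    write_fasta(assets.contigs, genome)
    files.append(genome)

    annot = out / "annotation.tsv"
    assets.annotation_frame().to_csv(annot, sep="\t", index=False)
    files.append(annot)

    truth_path = out / "truth.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    files.append(truth_path)

    for sample_id, reads in reads_by_sample.items():
        sam = out / f"reads_{sample_id}.sam"
        write_sam(reads, assets.contigs, sam)
        files.append(sam)

    if config is not None:
        cfg = out / "config.yaml"
        with open(cfg, "w") as handle:
            yaml.safe_dump(config.to_dict(), handle, sort_keys=True)
        files.append(cfg)

    manifest = {f.name: _sha256(f) for f in files}
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


def simulate_bundle(
    config: SimulationConfig, out_dir
) -> tuple[GenomeAssets, TruthTable, dict[str, str]]:
    """End-to-end convenience: genome, truth, reads per sample, bundle."""
    assets = build_toy_genome(config)
    truth = plan_truth(assets, config)
    reads_by_sample = {}
    for i, (sample_id, condition, n_reads) in enumerate(config.samples):
        reads_by_sample[sample_id] = simulate_sample_reads(
            assets, truth, condition, n_reads, seed=config.seed + 100 + i, config=config
        )
    manifest = write_fixture_bundle(assets, truth, reads_by_sample, out_dir, config)
    return assets, truth, manifest


def draw_pas_counts(
    truth: TruthTable, reads_per_gene: int, seed: int
) -> pd.DataFrame:
    """Counts-level simulation: multinomial PAS draws at fixed gene depth.

    Bypasses read/alignment simulation to exercise the APA statistics at a
    controlled per-gene depth; returns a frame indexed like the truth PAS
    table with one count column per condition.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for gid, grp in truth.pas.groupby("gene_id", sort=True):
        grp = grp.sort_values("pas_index")
        row = {"gene_id": gid, "pas_index": grp["pas_index"].to_numpy()}
        for cond in truth.conditions:
            draws = rng.multinomial(reads_per_gene, grp[f"usage_{cond}"].to_numpy())
            row[f"count_{cond}"] = draws
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)
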