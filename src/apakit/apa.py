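"""Pairwise APA significance testing and global trend statistics.

For each gene with two 3'UTR PAS isoforms the proximal/distal read counts
in two samples form a 2x2 table; a two-sided Fisher's exact test asks
whether the relative isoform expression differs between the samples
(significance analysis of APA), with Benjamini-Hochberg control of the FDR
across genes.  Effect direction is summarised by the relative expression
difference RED = log2(distal / proximal) per sample and its change
dRED = RED_kd - RED_ctrl: negative dRED means 3'UTR shortening.  The
global trend (global analysis of APA) is the log2 ratio of shortened to
lengthened gene counts; sequencing-depth differences are equalised by
seeded binomial downsampling of the deeper sample before testing.  The
same machinery compares upstream-region (intronic/internal) PAS usage
against 3'-most-exon usage, where a positive shift means activation of
upstream PASs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .atlas import PASCluster, THREE_PRIME, UPSTREAM
from .quantify import CountTable


def saap_pair_test(table) -> tuple[float, bool]:
    """Two-sided Fisher's exact test on an isoform x sample 2x2 table.

    Returns ``(p_value, testable)``; a zero row or column margin makes the
    table untestable (p is NaN and the gene should be excluded from FDR
    accounting).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), False
    _, p = fisher_exact(t, alternative="two-sided")
    return float(p), True


def compute_red(proximal: float, distal: float, pseudocount: float = 1.0) -> float:
    """Relative expression difference: log2((distal+pc)/(proximal+pc))."""
    return float(np.log2(distal + pseudocount) - np.log2(proximal + pseudocount))


def delta_red(red_kd: float, red_ctrl: float) -> float:
    """Change of RED between conditions; negative = 3'UTR shortening."""
    return red_kd - red_ctrl


def gaap_trend(n_first: int, n_second: int) -> float:
    """log2 ratio of two gene counts with a +0.5 stabilising pseudocount."""
    return float(np.log2(n_first + 0.5) - np.log2(n_second + 0.5))


def select_utr_isoform_pair(
    clusters: list[PASCluster],
) -> tuple[PASCluster, PASCluster] | None:
    """Choose the proximal/distal 3'UTR isoform pair for one gene.

    The two 3'-most-exon/extension clusters with the highest pooled counts
    are selected; the 5'-most of the two (transcript orientation) is the
    proximal isoform.  Genes with fewer than two eligible clusters yield
    None.
    """
    eligible = [c for c in clusters if c.region == THREE_PRIME]
    if len(eligible) < 2:
        return None
    strand = eligible[0].strand
    sign = 1 if strand == "+" else -1
    # Deterministic: most reads first, ties broken 5'-most.
    eligible.sort(key=lambda c: (-c.pooled_count, sign * c.representative))
    a, b = eligible[0], eligible[1]
    if sign * a.representative > sign * b.representative:
        a, b = b, a
    return a, b


def equalize_depth(
    counts: pd.DataFrame, ctrl: str, kd: str, seed: int = 0
) -> pd.DataFrame:
    """Binomially downsample the deeper of two samples to the other's depth.

    Each cluster count of the deeper sample is thinned with a binomial draw
    at the depth ratio, which equalises expected totals while preserving
    relative abundances.  Deterministic for a fixed seed.
    """
    totals = counts[[ctrl, kd]].sum(axis=0)
    if totals[ctrl] == totals[kd]:
        return counts
    deep, shallow = (ctrl, kd) if totals[ctrl] > totals[kd] else (kd, ctrl)
    rng = np.random.default_rng(seed)
    out = counts.copy()
    ratio = totals[shallow] / totals[deep]
    out[deep] = rng.binomial(counts[deep].to_numpy(), ratio)
    return out


@dataclass
class GaapResult:
    """Global APA trend over significant genes."""

    trend: float | None
    n_negative: int  # shortened (3'UTR) or suppressed (UR)
    n_positive: int  # lengthened (3'UTR) or activated (UR)
    defined: bool
    label_negative: str = "shortened"
    label_positive: str = "lengthened"


def _bh_adjust(frame: pd.DataFrame, fdr_threshold: float) -> pd.Series:
    fdr = pd.Series(np.nan, index=frame.index)
    testable = frame["testable"] & frame["p_value"].notna()
    if testable.any():
        _, adj, _, _ = multipletests(
            frame.loc[testable, "p_value"], alpha=fdr_threshold, method="fdr_bh"
        )
        fdr[testable] = adj
    return fdr


def _counts_for(counts: pd.DataFrame, cluster_id: str, sample: str) -> int:
    return int(counts.at[cluster_id, sample])


def run_saap_utr(
    table: CountTable,
    ctrl: str,
    kd: str,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
    depth_equalize: bool = True,
    seed: int = 0,
    min_abs_delta_red: float = 0.0,
    clusters: list[PASCluster] | None = None,
) -> pd.DataFrame:
    """Per-gene 3'UTR-APA test between a control and a knockdown sample.

    Returns one row per gene with >= 2 retained 3'UTR clusters: the 2x2
    counts (after optional depth equalisation), Fisher p, BH FDR, RED per
    sample, dRED and the direction call in {shortened, lengthened, none}.
    An optional minimum |dRED| effect-size gate can be applied on top of
    the FDR threshold (off by default).
    """
    counts = table.counts
    if depth_equalize:
        counts = equalize_depth(counts, ctrl, kd, seed=seed)
    groups = _gene_cluster_groups(table, clusters)
    rows = []
    for gene_id, gene_clusters in groups:
        pair = select_utr_isoform_pair(gene_clusters)
        if pair is None:
            continue
        prox, dist = pair
        p_ctrl = _counts_for(counts, prox.cluster_id, ctrl)
        d_ctrl = _counts_for(counts, dist.cluster_id, ctrl)
        p_kd = _counts_for(counts, prox.cluster_id, kd)
        d_kd = _counts_for(counts, dist.cluster_id, kd)
        p, testable = saap_pair_test([[p_ctrl, d_ctrl], [p_kd, d_kd]])
        red_ctrl = compute_red(p_ctrl, d_ctrl, pseudocount)
        red_kd = compute_red(p_kd, d_kd, pseudocount)
        rows.append(
            {
                "gene_id": gene_id,
                "proximal_id": prox.cluster_id,
                "distal_id": dist.cluster_id,
                "proximal_ctrl": p_ctrl,
                "distal_ctrl": d_ctrl,
                "proximal_kd": p_kd,
                "distal_kd": d_kd,
                "p_value": p,
                "testable": testable,
                "red_ctrl": red_ctrl,
                "red_kd": red_kd,
                "delta_red": delta_red(red_kd, red_ctrl),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "proximal_id",
            "distal_id",
            "proximal_ctrl",
            "distal_ctrl",
            "proximal_kd",
            "distal_kd",
            "p_value",
            "testable",
            "red_ctrl",
            "red_kd",
            "delta_red",
        ],
    )
    if result.empty:
        result["fdr"] = pd.Series(dtype=float)
        result["direction"] = pd.Series(dtype=object)
        return result
    result["fdr"] = _bh_adjust(result, fdr_threshold)
    significant = (
        (result["fdr"] < fdr_threshold)
        & (result["delta_red"].abs() >= min_abs_delta_red)
        & (result["delta_red"] != 0)
    )
    result["direction"] = "none"
    result.loc[significant & (result["delta_red"] < 0), "direction"] = "shortened"
    result.loc[significant & (result["delta_red"] > 0), "direction"] = "lengthened"
    return result


def gaap_utr_trend(
    results: pd.DataFrame, fdr_threshold: float = 0.05
) -> GaapResult:
    """Shortened-to-lengthened trend over FDR-significant genes.

    trend = log2((#shortened + 0.5) / (#lengthened + 0.5)); positive means
    net 3'UTR shortening.  With no significant gene the trend is undefined.
    """
    sig = results[(results["fdr"] < fdr_threshold) & results["testable"]]
    n_short = int((sig["delta_red"] < 0).sum())
    n_long = int((sig["delta_red"] > 0).sum())
    if n_short + n_long == 0:
        return GaapResult(None, 0, 0, False)
    return GaapResult(gaap_trend(n_short, n_long), n_short, n_long, True)


def run_ur_group_test(
    table: CountTable,
    ctrl: str,
    kd: str,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
    depth_equalize: bool = True,
    seed: int = 0,
    clusters: list[PASCluster] | None = None,
) -> tuple[pd.DataFrame, GaapResult]:
    """Upstream-region vs 3'-most-exon PAS group test per gene.

    PASS counts are aggregated within each region group per sample and the
    same 2x2 Fisher/BH machinery applies.  ``activated`` means the relative
    upstream-PAS usage increased in the knockdown; the trend is
    log2((#activated + 0.5) / (#suppressed + 0.5)).
    """
    counts = table.counts
    if depth_equalize:
        counts = equalize_depth(counts, ctrl, kd, seed=seed)
    groups = _gene_cluster_groups(table, clusters)
    rows = []
    for gene_id, gene_clusters in groups:
        ur = [c for c in gene_clusters if c.region == UPSTREAM]
        tp = [c for c in gene_clusters if c.region == THREE_PRIME]
        if not ur or not tp:
            continue
        ur_ctrl = sum(_counts_for(counts, c.cluster_id, ctrl) for c in ur)
        ur_kd = sum(_counts_for(counts, c.cluster_id, kd) for c in ur)
        tp_ctrl = sum(_counts_for(counts, c.cluster_id, ctrl) for c in tp)
        tp_kd = sum(_counts_for(counts, c.cluster_id, kd) for c in tp)
        p, testable = saap_pair_test([[tp_ctrl, ur_ctrl], [tp_kd, ur_kd]])
        # RED analogue: relative upstream usage, log2(UR / 3'-most).
        rel_ctrl = compute_red(tp_ctrl, ur_ctrl, pseudocount)
        rel_kd = compute_red(tp_kd, ur_kd, pseudocount)
        rows.append(
            {
                "gene_id": gene_id,
                "ur_ctrl": ur_ctrl,
                "tp_ctrl": tp_ctrl,
                "ur_kd": ur_kd,
                "tp_kd": tp_kd,
                "p_value": p,
                "testable": testable,
                "rel_ur_ctrl": rel_ctrl,
                "rel_ur_kd": rel_kd,
                "delta_rel_ur": delta_red(rel_kd, rel_ctrl),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "ur_ctrl",
            "tp_ctrl",
            "ur_kd",
            "tp_kd",
            "p_value",
            "testable",
            "rel_ur_ctrl",
            "rel_ur_kd",
            "delta_rel_ur",
        ],
    )
    if result.empty:
        result["fdr"] = pd.Series(dtype=float)
        result["direction"] = pd.Series(dtype=object)
        return result, GaapResult(None, 0, 0, False, "suppressed", "activated")
    result["fdr"] = _bh_adjust(result, fdr_threshold)
    significant = (result["fdr"] < fdr_threshold) & (result["delta_rel_ur"] != 0)
    result["direction"] = "none"
    result.loc[significant & (result["delta_rel_ur"] > 0), "direction"] = "activated"
    result.loc[significant & (result["delta_rel_ur"] < 0), "direction"] = "suppressed"
    n_act = int((result["direction"] == "activated").sum())
    n_sup = int((result["direction"] == "suppressed").sum())
    if n_act + n_sup == 0:
        trend = GaapResult(None, 0, 0, False, "suppressed", "activated")
    else:
        trend = GaapResult(
            gaap_trend(n_act, n_sup), n_sup, n_act, True, "suppressed", "activated"
        )
    return result, trend


def _gene_cluster_groups(
    table: CountTable, clusters: list[PASCluster] | None
) -> list[tuple[str, list[PASCluster]]]:
    """Group clusters by gene, reconstructing them from metadata if needed."""
    if clusters is None:
        clusters = []
        for cluster_id, row in table.meta.iterrows():
            if pd.isna(row["gene_id"]):
                continue
            clusters.append(
                PASCluster(
                    contig=row.get("contig", ""),
                    strand=row["strand"],
                    representative=int(row["position"]),
                    members={int(row["position"]): int(table.counts.loc[cluster_id].sum())},
                    per_sample=Counter(table.counts.loc[cluster_id].to_dict()),
                    cluster_id=cluster_id,
                    gene_id=row["gene_id"],
                    region=row["region"],
                )
            )
    by_gene: dict[str, list[PASCluster]] = {}
    for c in clusters:
        if c.gene_id is not None:
            by_gene.setdefault(c.gene_id, []).append(c)
    return sorted(by_gene.items())
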