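"""Expression quantification and regulation calls for PAS isoforms.

Expression of a PAS isoform is the number of PASS reads assigned to it,
normalised to reads per million uniquely mapped PASS reads in the sample
(RPM); a gene's expression is the sum over its retained PAS isoforms.
Changes between a knockdown and a control sample are log2 RPM ratios, and a
transcript is called regulated when the fold change exceeds 2 with more
than 50 supporting reads in the two samples combined.  Group comparisons
(biotype strata, expression-percentile strata) use two-sample K-S tests,
and samples are clustered hierarchically with 1 - Pearson correlation as
the distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import ks_2samp


class CountTable:
    """PAS x sample PASS counts with per-row metadata and derived RPM.

    ``counts`` is indexed by cluster id with one integer column per sample;
    ``meta`` shares the index and carries gene_id, region, biotype and
    coordinates.  RPM columns are derived lazily and always sum to 1e6 per
    sample.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame):
        if not counts.index.equals(meta.index):
            meta = meta.reindex(counts.index)
        self.counts = counts.astype(int)
        self.meta = meta
        self._rpm: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def rpm(self) -> pd.DataFrame:
        if self._rpm is None:
            self._rpm = compute_rpm(self.counts)
        return self._rpm

    def sample_total(self, sample: str) -> int:
        return int(self.counts[sample].sum())

    def pseudocount_rpm(self, sample: str, pseudocount: float = 1.0) -> float:
        """``pseudocount`` raw reads expressed on the sample's RPM scale."""
        total = self.sample_total(sample)
        return pseudocount * 1e6 / total if total else 0.0


def compute_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalisation; errors on an empty sample."""
    totals = counts.sum(axis=0)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(
            f"zero PASS-read total in sample(s): {', '.join(map(str, empty.index))}"
        )
    return counts / totals * 1e6


def gene_level_expression(table: CountTable) -> pd.DataFrame:
    """Gene x sample RPM: the sum of a gene's PAS isoform RPM values."""
    rpm = table.rpm.copy()
    rpm["gene_id"] = table.meta["gene_id"]
    return rpm.dropna(subset=["gene_id"]).groupby("gene_id").sum()


def gene_level_counts(table: CountTable) -> pd.DataFrame:
    counts = table.counts.copy()
    counts["gene_id"] = table.meta["gene_id"]
    return counts.dropna(subset=["gene_id"]).groupby("gene_id").sum()


def log2_ratio(
    numerator: pd.Series | np.ndarray,
    denominator: pd.Series | np.ndarray,
    pc_num: float = 0.0,
    pc_den: float = 0.0,
) -> pd.Series | np.ndarray:
    return np.log2(np.asarray(numerator, float) + pc_num) - np.log2(
        np.asarray(denominator, float) + pc_den
    )


def transcript_fold_change(
    table: CountTable,
    kd: str,
    ctrl: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-PAS log2(RPM_kd / RPM_ctrl), pseudocount-stabilised.

    The pseudocount is given in raw-read units and converted to each
    sample's RPM scale, so the default of 1 read behaves symmetrically at
    matched depth; ``pseudocount=0`` gives the raw ratio (with -inf/inf at
    zeros).
    """
    rpm = table.rpm
    pc_kd = table.pseudocount_rpm(kd, pseudocount)
    pc_ctrl = table.pseudocount_rpm(ctrl, pseudocount)
    values = log2_ratio(rpm[kd], rpm[ctrl], pc_kd, pc_ctrl)
    return pd.Series(values, index=rpm.index, name=f"log2fc_{kd}_vs_{ctrl}")


def gene_fold_change(
    table: CountTable,
    kd: str,
    ctrl: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    gene_rpm = gene_level_expression(table)
    pc_kd = table.pseudocount_rpm(kd, pseudocount)
    pc_ctrl = table.pseudocount_rpm(ctrl, pseudocount)
    values = log2_ratio(gene_rpm[kd], gene_rpm[ctrl], pc_kd, pc_ctrl)
    return pd.Series(values, index=gene_rpm.index, name=f"log2fc_{kd}_vs_{ctrl}")


@dataclass
class RegulationResult:
    """Regulated-transcript calls and the down/up summary ratio."""

    calls: pd.DataFrame  # columns: log2fc, total_reads, call
    n_down: int
    n_up: int
    down_up_ratio: float
    ratio_infinite: bool


def call_regulated_transcripts(
    log2fc: pd.Series,
    total_reads: pd.Series,
    fc_cutoff: float = 2.0,
    min_total: int = 50,
) -> RegulationResult:
    """Call transcripts regulated at fold change > cutoff and reads > 50.

    ``total_reads`` is the sum of raw PASS counts in the two compared
    samples (reads, not RPM, measure the evidence).  Returns calls in
    {down, up, unchanged} and the ratio of downregulated to upregulated
    counts, flagged infinite when nothing is upregulated.
    """
    threshold = np.log2(fc_cutoff)
    total = total_reads.reindex(log2fc.index).fillna(0)
    call = pd.Series("unchanged", index=log2fc.index)
    eligible = total > min_total
    call[eligible & (log2fc > threshold)] = "up"
    call[eligible & (log2fc < -threshold)] = "down"
    n_down = int((call == "down").sum())
    n_up = int((call == "up").sum())
    if n_up == 0:
        ratio = np.inf if n_down else np.nan
        infinite = n_down > 0
    else:
        ratio = n_down / n_up
        infinite = False
    calls = pd.DataFrame(
        {"log2fc": log2fc, "total_reads": total, "call": call}
    )
    return RegulationResult(calls, n_down, n_up, ratio, infinite)


def expression_strata(
    expression: pd.Series, percentiles: tuple[float, float] = (25.0, 75.0)
) -> pd.Series:
    """Label genes low/median/high by expression percentile of one sample."""
    lo = np.percentile(expression, percentiles[0])
    hi = np.percentile(expression, percentiles[1])
    labels = pd.Series("median", index=expression.index)
    labels[expression < lo] = "low"
    labels[expression > hi] = "high"
    return labels


@dataclass
class KsComparison:
    group_sizes: dict[str, int]
    group_medians: dict[str, float]
    pair: tuple[str, str]
    statistic: float | None
    pvalue: float | None


def stratified_ks(
    values: pd.Series,
    groups: pd.Series,
    pair: tuple[str, str],
    min_group: int = 5,
) -> KsComparison:
    """Two-sided two-sample K-S test between two designated strata.

    Distribution summaries are reported for every stratum; the test applies
    to ``pair`` (e.g. low vs high expression, or mRNA vs lncRNA).  Groups
    smaller than ``min_group`` yield an undefined p-value with a warning.
    """
    groups = groups.reindex(values.index)
    sizes = values.groupby(groups).size().to_dict()
    medians = values.groupby(groups).median().to_dict()
    a = values[groups == pair[0]].dropna()
    b = values[groups == pair[1]].dropna()
    if len(a) < min_group or len(b) < min_group:
        warnings.warn(
            f"group size below {min_group} for pair {pair}; K-S p undefined"
        )
        return KsComparison(sizes, medians, pair, None, None)
    stat, p = ks_2samp(a, b, alternative="two-sided")
    return KsComparison(sizes, medians, pair, float(stat), float(p))


def cluster_samples(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of samples.

    ``matrix`` holds one column per sample (e.g. log2 fold changes over the
    regulated transcript set).  The distance between samples is
    1 - Pearson correlation (identical profiles are at distance 0, perfect
    anticorrelation at 2).  Constant columns have undefined correlation and
    are dropped with a warning.  Returns the SciPy linkage matrix and the
    retained sample labels in input order.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    constant = [c for c in matrix.columns if matrix[c].std(ddof=0) == 0]
    if constant:
        warnings.warn(f"dropping constant sample column(s): {constant}")
        matrix = matrix.drop(columns=constant)
    if matrix.shape[1] < 2:
        raise ValueError("fewer than two non-constant samples remain")
    corr = matrix.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    return linkage(condensed, method="average"), list(matrix.columns)
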