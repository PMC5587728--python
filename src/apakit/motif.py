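"""PFM-based motif scoring around poly(A) sites.

A polyadenylation site (PAS) is recognised in part through sequence elements
in its vicinity; RNA-binding proteins such as the non-canonical poly(A)
polymerase Star-PAP bind short degenerate elements upstream of the cleavage
position.  This module scores such elements with a position frequency matrix
(PFM) weighted by per-position information content, builds positional
meta-profiles over sets of PASs, and provides the group-comparison statistics
used to relate motif strength to regulation: percentile-group K-S tests,
k-mer enrichment between PAS groups, and poly(A)-signal composition tests.

Scoring model
-------------
For PFM position ``p`` with nucleotide frequencies ``f_{p,n}``, the
information content in bits is ``I_p = 2 - H_p`` where ``H_p`` is the Shannon
entropy of the four frequencies (``0 * log2(0) := 0``).  A 7-mer ``w`` is
scored ``sum_p f_{p, w_p} * I_p``; a fully conserved PFM therefore scores its
consensus at ``7 * 2 = 14`` and a uniform PFM scores everything 0.

All flanking sequences handed to this module are in transcript (sense)
orientation, 5'->3', with the PAS (the last transcribed nucleotide) at a
fixed offset; by default flanks cover -100..+100 around the PAS.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, ks_2samp
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._util import fetch, revcomp, to_rna

RNA_ALPHABET = "ACGU"

#: k-mer scan regions around the PAS (transcript orientation, inclusive
#: offsets; 0 is the PAS base itself).  The two upstream windows follow the
#: convention used for 3' end motif analyses; the downstream windows mirror
#: them.
DEFAULT_KMER_REGIONS: Mapping[str, tuple[int, int]] = {
    "-100..-41": (-100, -41),
    "-40..-1": (-40, -1),
    "+1..+40": (1, 40),
    "+41..+100": (41, 100),
}


class Pfm:
    """A position frequency matrix over the RNA alphabet A, C, G, U.

    Parameters
    ----------
    freqs
        Array of shape (width, 4); every row must be a probability vector.
    """

    def __init__(self, freqs: np.ndarray):
        freqs = np.asarray(freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[1] != 4:
            raise ValueError("PFM must have shape (width, 4)")
        if (freqs < 0).any():
            raise ValueError("PFM frequencies must be non-negative")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PFM row must sum to 1")
        self.freqs = freqs

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def information_content(self) -> np.ndarray:
        """Per-position information content I_p in bits (0 <= I_p <= 2)."""
        return np.array([position_information_content(row) for row in self.freqs])

    @property
    def consensus(self) -> str:
        """Most frequent base per position (ties broken A<C<G<U)."""
        return "".join(RNA_ALPHABET[i] for i in self.freqs.argmax(axis=1))

    @classmethod
    def from_tsv(cls, path) -> "Pfm":
        frame = pd.read_csv(path, sep="\t")
        cols = [c for c in ("A", "C", "G", "U") if c in frame.columns]
        if len(cols) != 4:
            raise ValueError("PFM TSV must have columns A, C, G, U")
        return cls(frame[["A", "C", "G", "U"]].to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.freqs, columns=list(RNA_ALPHABET)).to_csv(
            path, sep="\t", index=False
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Pfm(width={self.width}, consensus={self.consensus!r})"


def example_pfm(consensus: str = "GCAUAGC", conservation: float = 0.97) -> Pfm:
    """A bundled synthetic PFM: an AUA core in a GC context.

    This is a stand-in constructed for simulations and examples (synthetic;
    it is not a measured binding model).  ``conservation`` is the frequency
    of the consensus base at each position; the remainder is spread evenly.
    """
    if not 0.25 <= conservation <= 1.0:
        raise ValueError("conservation must be in [0.25, 1]")
    freqs = np.full((len(consensus), 4), (1.0 - conservation) / 3.0)
    for p, base in enumerate(to_rna(consensus)):
        freqs[p, RNA_ALPHABET.index(base)] = conservation
    return Pfm(freqs)


def position_information_content(freqs: Sequence[float]) -> float:
    """Information content of one PFM position, ``2 - entropy`` in bits.

    Uses the convention ``0 * log2(0) = 0``; a uniform position scores 0 and
    a fully conserved one scores 2.
    """
    f = np.asarray(freqs, dtype=float)
    if (f < 0).any():
        raise ValueError("frequencies must be non-negative")
    if not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError("frequencies must sum to 1")
    nz = f[f > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return 2.0 - entropy


def _window_indices(window: str, width: int) -> np.ndarray:
    """Map a window to alphabet indices; ambiguous bases map to -1."""
    win = to_rna(window)
    if len(win) != width:
        raise ValueError(f"window must have length {width}, got {len(win)}")
    return np.array([RNA_ALPHABET.find(b) for b in win])


def score_7mer(window: str, pfm: Pfm) -> float:
    """Score one window: sum over positions of f_{p, n(p)} * I_p.

    Ambiguous (non-ACGU) bases contribute 0 at their position.
    """
    idx = _window_indices(window, pfm.width)
    info = pfm.information_content
    score = 0.0
    for p, n in enumerate(idx):
        if n >= 0:
            score += pfm.freqs[p, n] * info[p]
    return score


def scan_flank(flank: str, pfm: Pfm, upstream: int = 100):
    """Score every fully contained window of a PAS flank.

    Parameters
    ----------
    flank
        Sequence in transcript orientation with the PAS base at index
        ``upstream`` (a -100..+100 flank has length 201 and upstream=100).

    Returns
    -------
    offsets, scores
        ``offsets[i]`` is the window start relative to the PAS; a 201-nt
        flank yields 195 scores at offsets -100..+94.  Shorter-than-width
        flanks yield empty arrays.
    """
    w = pfm.width
    n = len(flank) - w + 1
    if n <= 0:
        return np.empty(0, dtype=int), np.empty(0)
    seq = to_rna(flank)
    idx = np.array([RNA_ALPHABET.find(b) for b in seq])
    info = pfm.information_content
    scores = np.zeros(n)
    for p in range(w):
        col = idx[p : p + n]
        valid = col >= 0
        contrib = np.where(valid, pfm.freqs[p, np.clip(col, 0, 3)] * info[p], 0.0)
        scores += contrib
    offsets = np.arange(n) - upstream
    return offsets, scores


@dataclass
class MotifProfile:
    """Positionwise mean motif score over a PAS set, raw and smoothed."""

    offsets: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    n_flanks: int = 0


def build_meta_profile(
    flanks: Iterable[str], pfm: Pfm, upstream: int = 100, span: float = 0.05
) -> MotifProfile:
    """Average per-start-position scores over flanks, LOWESS-smoothed.

    All flanks must have equal length.  Smoothing uses a locally weighted
    regression with smoother span ``span`` (default 0.05) and one robustness
    iteration; with a single position or constant scores the smoothed curve
    equals the raw one.
    """
    flanks = list(flanks)
    if not flanks:
        raise ValueError("need at least one flank")
    lengths = {len(f) for f in flanks}
    if len(lengths) != 1:
        raise ValueError("all flanks must have the same length")
    offsets = None
    acc = None
    for f in flanks:
        offsets, scores = scan_flank(f, pfm, upstream=upstream)
        acc = scores if acc is None else acc + scores
    raw = acc / len(flanks)
    if len(raw) < 3 or np.allclose(raw, raw[0]):
        smoothed = raw.copy()
    else:
        smoothed = lowess(
            raw, offsets.astype(float), frac=span, it=1, return_sorted=False
        )
    return MotifProfile(offsets=offsets, raw=raw, smoothed=smoothed, n_flanks=len(flanks))


def mean_upstream_score(
    flank: str,
    pfm: Pfm,
    region: tuple[int, int] = (-100, -41),
    upstream: int = 100,
) -> float:
    """Mean score of windows lying entirely within an upstream region.

    ``region`` gives inclusive offsets relative to the PAS; only windows
    fully contained in it contribute, so the default -100..-41 region of a
    7-wide PFM averages the 54 windows starting at -100..-47.
    """
    a, b = region
    if b - a + 1 < pfm.width:
        raise ValueError("region shorter than the PFM width")
    offsets, scores = scan_flank(flank, pfm, upstream=upstream)
    mask = (offsets >= a) & (offsets <= b - pfm.width + 1)
    if not mask.any():
        raise ValueError("flank does not cover the requested region")
    return float(scores[mask].mean())


@dataclass
class PercentileKsResult:
    """Grouping of units by motif-score percentile plus a two-sample K-S test."""

    high: np.ndarray  # boolean mask of the high-score group
    low: np.ndarray  # boolean mask of the comparison group
    cut_high: float
    cut_low: float | None
    statistic: float | None
    pvalue: float | None
    degenerate: bool = False


def percentile_group_ks(
    scores: Sequence[float],
    values: Sequence[float],
    cut: str = "90th",
) -> PercentileKsResult:
    """Split units at score percentiles and K-S test their paired values.

    ``cut='90th'`` compares units scoring above the 90th percentile against
    all others; ``cut='10th/90th'`` compares the >90th against the <10th
    percentile group.  Percentiles use linear interpolation and ties at the
    cutoff fall in the lower group.  The K-S test is two-sided two-sample.
    """
    scores = np.asarray(scores, dtype=float)
    values = np.asarray(values, dtype=float)
    if scores.shape != values.shape:
        raise ValueError("scores and values must align")
    if scores.size < 20:
        raise ValueError("need at least 20 units for percentile grouping")
    if cut not in ("90th", "10th/90th"):
        raise ValueError(f"unknown cut {cut!r}")
    p90 = float(np.percentile(scores, 90))
    high = scores > p90
    if cut == "10th/90th":
        p10 = float(np.percentile(scores, 10))
        low = scores < p10
        cut_low = p10
    else:
        low = ~high
        cut_low = None
    if not high.any() or not low.any():
        warnings.warn("degenerate score grouping: an empty percentile group")
        return PercentileKsResult(high, low, p90, cut_low, None, None, True)
    stat, p = ks_2samp(values[high], values[low], alternative="two-sided")
    return PercentileKsResult(high, low, p90, cut_low, float(stat), float(p))


def _region_slice(flank: str, region: tuple[int, int], upstream: int) -> str:
    a, b = region
    return flank[a + upstream : b + upstream + 1]


def kmer_enrichment(
    group_seqs: Sequence[str],
    background_seqs: Sequence[str],
    k: int = 4,
    region_id: str = "",
) -> pd.DataFrame:
    """Per-k-mer presence/absence enrichment of a group over a background.

    For each of the 4**k RNA k-mers, sequences containing the k-mer at least
    once are counted in each set and compared with a two-sided Fisher's
    exact test on the 2x2 presence table.  Returns one row per k-mer with
    the raw counts, p-value and -log10(p).
    """
    if not group_seqs or not background_seqs:
        raise ValueError("group and background must be non-empty")
    group = [to_rna(s) for s in group_seqs]
    background = [to_rna(s) for s in background_seqs]

    def presence(seqs):
        counts: dict[str, int] = {}
        for s in seqs:
            seen = {s[i : i + k] for i in range(len(s) - k + 1)}
            for kmer in seen:
                counts[kmer] = counts.get(kmer, 0) + 1
        return counts

    gcount = presence(group)
    bcount = presence(background)
    ng, nb = len(group), len(background)
    rows = []
    for kmer in ("".join(t) for t in itertools.product(RNA_ALPHABET, repeat=k)):
        g = gcount.get(kmer, 0)
        b = bcount.get(kmer, 0)
        _, p = fisher_exact([[g, ng - g], [b, nb - b]], alternative="two-sided")
        rows.append(
            {
                "kmer": kmer,
                "region": region_id,
                "group_with": g,
                "group_n": ng,
                "background_with": b,
                "background_n": nb,
                "p_value": p,
                "neg_log10_p": -np.log10(p),
            }
        )
    return pd.DataFrame(rows)


SIGNAL_CLASSES = ("AAUAAA", "variant", "A_rich", "none")


@dataclass
class SignalCompositionResult:
    proportions: pd.DataFrame  # group x class proportions
    counts: pd.DataFrame
    statistic: float
    pvalue: float
    method: str
    pair: tuple[str, str] = field(default=("", ""))


def signal_composition_test(
    groups: Mapping[str, Sequence[str]],
    pair: tuple[str, str] | None = None,
) -> SignalCompositionResult:
    """Compare poly(A)-signal class composition between two PAS groups.

    ``groups`` maps a group name to the signal classes of its PASs.  A
    chi-square test of homogeneity is applied to the class contingency table
    of the designated pair (default: the first two groups).  If any expected
    cell is below 1, a 2x2 collapse is tested exactly instead (Fisher on the
    most common class versus the rest), with a warning.
    """
    if pair is None:
        names = list(groups)
        if len(names) < 2:
            raise ValueError("need at least two groups")
        pair = (names[0], names[1])
    counts = pd.DataFrame(
        {
            name: [list(classes).count(c) for c in SIGNAL_CLASSES]
            for name, classes in groups.items()
        },
        index=list(SIGNAL_CLASSES),
    ).T
    proportions = counts.div(counts.sum(axis=1), axis=0)
    table = counts.loc[list(pair)]
    table = table.loc[:, table.sum(axis=0) > 0]
    stat, p, _, expected = chi2_contingency(table.to_numpy())
    method = "chi-square"
    if (expected < 1).any():
        warnings.warn(
            "expected cell count < 1; collapsing to a 2x2 exact test"
        )
        top = table.sum(axis=0).idxmax()
        collapsed = np.column_stack(
            [table[top].to_numpy(), table.drop(columns=top).sum(axis=1).to_numpy()]
        )
        stat, p = fisher_exact(collapsed, alternative="two-sided")
        method = "fisher-2x2-collapsed"
    return SignalCompositionResult(
        proportions=proportions,
        counts=counts,
        statistic=float(stat),
        pvalue=float(p),
        method=method,
        pair=pair,
    )


def extract_flank(
    reference,
    contig: str,
    position: int,
    strand: str,
    upstream: int = 100,
    downstream: int = 100,
) -> str:
    """Transcript-orientation flank around a PAS (last transcribed base).

    For a plus-strand PAS this is the forward genomic sequence
    ``[position-upstream, position+downstream]``; for a minus-strand PAS the
    reverse complement of ``[position-downstream, position+upstream]``.  The
    PAS base sits at index ``upstream`` when the contig permits the full
    window.
    """
    if strand == "+":
        return fetch(reference, contig, position - upstream, position + downstream + 1)
    if strand == "-":
        return revcomp(
            fetch(reference, contig, position - downstream, position + upstream + 1)
        )
    raise ValueError(f"bad strand {strand!r}")
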