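"""Small shared helpers: sequence manipulation and reference access."""

from __future__ import annotations

from typing import Mapping

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (N-safe, case preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def to_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def contig_length(reference, contig: str) -> int:
    seq = _contig(reference, contig)
    return len(seq)


def _contig(reference, contig: str):
    # Accepts a plain mapping contig -> str, a GenomeAssets-like object with
    # a ``contigs`` mapping, or a pyfaidx.Fasta.
    if hasattr(reference, "contigs") and isinstance(reference.contigs, Mapping):
        source = reference.contigs
    else:
        source = reference
    try:
        return source[contig]
    except KeyError as exc:
        raise KeyError(f"reference contig {contig!r} not found") from exc


def fetch(reference, contig: str, start: int, end: int) -> str:
    """Fetch reference bases [start, end), clamped to contig bounds.

    Positions outside the contig are simply not returned, so callers must
    not assume len(result) == end - start near contig edges.
    """
    seq = _contig(reference, contig)
    start = max(0, start)
    end = min(len(seq), end)
    if end <= start:
        return ""
    return str(seq[start:end]).upper()
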