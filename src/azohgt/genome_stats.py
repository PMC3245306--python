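"""Genome-record statistics and in-silico PCR.

Statistics mirror a "general features" genome table: total length, GC
content, CDS/tRNA/rRNA counts and the protein-coding fraction.  GC is
computed over unambiguous bases only (ambiguity codes are excluded from
both numerator and denominator, making the value stable under N-padding).
The coding fraction is reported both as the per-base union of CDS
intervals (overlaps counted once) and as the raw interval-length sum.

In-silico PCR locates every exact occurrence of a primer pair on either
strand and reports the implied amplicon with 1-based inclusive
coordinates, primers included.  Zero mismatches only; degenerate-base
primers are not supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import GenomeRecord

__all__ = ["GenomeStats", "PcrProduct", "compute_stats", "insilico_pcr", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeStats:
    n_replicons: int
    total_length_bp: int
    gc_percent: float  # 2 decimals, half-even
    n_cds: int
    coding_percent: float  # per-base union of CDS intervals
    coding_percent_raw: float  # sum of CDS interval lengths (overlaps double-counted)
    n_trna: int
    n_rrna_genes: int


def _merged_interval_length(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals.sort()
    covered = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end + 1:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    covered += cur_end - cur_start + 1
    return covered


def compute_stats(records: Sequence[GenomeRecord]) -> GenomeStats:
    """Aggregate statistics over one or more replicon records."""
    if not records:
        raise ValueError("no genome records supplied")
    total_len = 0
    gc = 0
    acgt = 0
    n_cds = n_trna = n_rrna = 0
    union_bp = 0
    raw_bp = 0
    for rec in records:
        seq = rec.sequence.upper()
        total_len += len(seq)
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
        cds_intervals = []
        for feat in rec.features:
            if not (1 <= feat.start <= feat.end <= len(seq)):
                raise ValueError(
                    f"{rec.replicon_id}: feature {feat.start}..{feat.end} outside sequence"
                )
            if feat.type == "CDS":
                n_cds += 1
                cds_intervals.append((feat.start, feat.end))
                raw_bp += feat.end - feat.start + 1
            elif feat.type == "tRNA":
                n_trna += 1
            elif feat.type == "rRNA":
                n_rrna += 1
        union_bp += _merged_interval_length(cds_intervals)
    gc_percent = round(100.0 * gc / acgt, 2) if acgt else 0.0
    return GenomeStats(
        n_replicons=len(records),
        total_length_bp=total_len,
        gc_percent=gc_percent,
        n_cds=n_cds,
        coding_percent=round(100.0 * union_bp / total_len, 2),
        coding_percent_raw=round(100.0 * raw_bp / total_len, 2),
        n_trna=n_trna,
        n_rrna_genes=n_rrna,
    )


@dataclass(frozen=True)
class PcrProduct:
    replicon_id: str
    start: int  # 1-based inclusive, forward primer's first base
    end: int  # last base of the reverse primer's binding site
    length_bp: int
    strand_of_forward_primer: str  # '+' | '-'


def _find_all(haystack: str, needle: str) -> list[int]:
    """0-based start positions of every (possibly overlapping) occurrence."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def insilico_pcr(
    records: Sequence[GenomeRecord],
    fwd: str,
    rev: str,
    max_product: int = 10000,
) -> list[PcrProduct]:
    """Predict amplicons for a primer pair over a set of replicons.

    A product exists wherever the forward primer occurs on a strand with
    the reverse complement of the reverse primer downstream on the same
    strand, within ``max_product``; both primer-role orientations are
    searched.  Product coordinates are on the plus strand, primers
    included, and every valid pairing is reported.
    """
    fwd, rev = fwd.upper(), rev.upper()
    for name, primer in (("fwd", fwd), ("rev", rev)):
        if not primer or any(b not in "ACGT" for b in primer):
            raise ValueError(f"{name} primer must be a non-empty A/C/G/T string")
    products: list[PcrProduct] = []
    seen: set[tuple[str, int, int]] = set()
    for rec in records:
        seq = rec.sequence.upper()
        # (forward-role primer, reverse-role primer, plus-strand label of fwd)
        for fprimer, rprimer, strand in ((fwd, rev, "+"), (rev, fwd, "-")):
            f_sites = _find_all(seq, fprimer)
            r_sites = _find_all(seq, revcomp(rprimer))
            for i in f_sites:
                for j in r_sites:
                    end = j + len(rprimer)  # 0-based exclusive
                    length = end - i
                    if j < i + len(fprimer) or length > max_product:
                        continue
                    key = (rec.replicon_id, i + 1, end)
                    if key in seen:  # palindromic primer pair: one amplicon
                        continue
                    seen.add(key)
                    products.append(
                        PcrProduct(
                            replicon_id=rec.replicon_id,
                            start=i + 1,
                            end=end,
                            length_bp=length,
                            strand_of_forward_primer=strand,
                        )
                    )
    products.sort(key=lambda p: (p.replicon_id, p.start, p.end))
    return products
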