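"""Spectral-count proteomics post-processing.

Charge-aware PSM filtering in the DTASelect style (XCorr minima of
1.8/2.5/3.5 for charge +1/+2/+3, ΔCN >= 0.08, at least semi-tryptic
peptides, two distinct peptides per protein), reverse-decoy false-positive
rate ``%FP = 2 * reverse / (reverse + real)``, and NSAF relative protein
abundance ``NSAF_k = (SpC/L)_k / sum_n (SpC/L)_n``.

All thresholds are inclusive minima (a PSM exactly at a threshold passes).
Charges above +3 are filtered with the +3 threshold.  "Two peptides per
protein" counts distinct peptide sequences (modification marks stripped),
not PSMs; peptides shared between proteins count toward every protein they
map to — no parsimony grouping is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import PsmRecord

__all__ = [
    "PsmFilterConfig",
    "FilterResult",
    "NsafRecord",
    "filter_psms",
    "fp_rate",
    "nsaf",
]


@dataclass(frozen=True)
class PsmFilterConfig:
    xcorr_min_by_charge: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.8, 2: 2.5, 3: 3.5}
    )
    delta_cn_min: float = 0.08
    min_peptides_per_protein: int = 2
    #: accepted tryptic statuses ("semi-or-better")
    allowed_tryptic: tuple[str, ...] = ("fully", "semi")

    def __post_init__(self) -> None:
        if self.min_peptides_per_protein < 1:
            raise ValueError("min_peptides_per_protein must be >= 1")
        if any(t <= 0 for t in self.xcorr_min_by_charge.values()):
            raise ValueError("XCorr thresholds must be positive")

    def xcorr_threshold(self, charge: int) -> float:
        if charge <= 0:
            raise ValueError(f"invalid charge state {charge}")
        if charge in self.xcorr_min_by_charge:
            return self.xcorr_min_by_charge[charge]
        # charges above the table use the highest configured threshold
        return self.xcorr_min_by_charge[max(self.xcorr_min_by_charge)]


@dataclass(frozen=True)
class FilterResult:
    accepted: tuple[PsmRecord, ...]
    #: protein_id -> set of distinct passing peptide sequences,
    #: restricted to proteins meeting the min-peptide requirement
    proteins: dict[str, frozenset[str]]

    @property
    def n_reverse_proteins(self) -> int:
        return sum(1 for p in self.proteins if p.startswith("REV_"))


def _base_peptide(peptide: str) -> str:
    """Strip modification marks so modified/unmodified forms collapse."""
    return re.sub(r"[^A-Za-z]", "", peptide).upper()


def psm_passes(psm: PsmRecord, cfg: PsmFilterConfig) -> bool:
    """Spectrum-level filter (thresholds inclusive)."""
    return (
        psm.xcorr >= cfg.xcorr_threshold(psm.charge)
        and psm.delta_cn >= cfg.delta_cn_min
        and psm.tryptic_status in cfg.allowed_tryptic
    )


def filter_psms(
    psms: Sequence[PsmRecord], cfg: PsmFilterConfig = PsmFilterConfig()
) -> FilterResult:
    """Apply the spectrum-level filter, then the peptides-per-protein rule.

    Returns the accepted PSMs (file order preserved) and the proteins with
    at least ``min_peptides_per_protein`` distinct passing peptides.  Decoy
    PSMs are filtered identically so the decoy protein count feeds
    :func:`fp_rate` directly.
    """
    accepted = tuple(p for p in psms if psm_passes(p, cfg))
    peptides_by_protein: dict[str, set[str]] = {}
    for p in accepted:
        peptides_by_protein.setdefault(p.protein_id, set()).add(_base_peptide(p.peptide))
    proteins = {
        prot: frozenset(peps)
        for prot, peps in peptides_by_protein.items()
        if len(peps) >= cfg.min_peptides_per_protein
    }
    return FilterResult(accepted=accepted, proteins=proteins)


def fp_rate(n_reverse: int, n_real: int) -> float:
    """Reverse-decoy false-positive percentage: ``200 * rev / (rev + real)``.

    Bounded in [0, 200]; equals 100 when decoy and real counts match.
    """
    if n_reverse < 0 or n_real < 0:
        raise ValueError("counts must be non-negative")
    total = n_reverse + n_real
    if total == 0:
        raise ValueError("undefined FP rate: no identifications at all")
    return 200.0 * n_reverse / total


@dataclass(frozen=True)
class NsafRecord:
    protein_id: str
    spc: int
    length_l: int
    saf: float
    nsaf: float


def nsaf(identifications: Iterable[tuple[str, int, int]]) -> list[NsafRecord]:
    """Normalized spectral abundance factors from (protein_id, SpC, length).

    ``nsaf_k = (SpC_k / L_k) / sum_n (SpC_n / L_n)``; the result sums to 1
    and is returned sorted by descending NSAF (ties broken by protein id).
    """
    items = list(identifications)
    if not items:
        raise ValueError("no identifications")
    for protein_id, spc, length in items:
        if length <= 0:
            raise ValueError(f"protein {protein_id!r} has non-positive length {length}")
        if spc < 0:
            raise ValueError(f"protein {protein_id!r} has negative spectral count")
    total_saf = sum(spc / length for _pid, spc, length in items)
    if total_saf == 0:
        raise ValueError("undefined NSAF: every spectral count is zero")
    records = [
        NsafRecord(
            protein_id=pid,
            spc=spc,
            length_l=length,
            saf=spc / length,
            nsaf=(spc / length) / total_saf,
        )
        for pid, spc, length in items
    ]
    records.sort(key=lambda r: (-r.nsaf, r.protein_id))
    return records
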