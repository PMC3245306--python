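"""Downstream summaries of ancestry calls.

* COG functional-category enrichment between the ancestral and HGT gene
  sets (two-sided Fisher's exact test per category, Benjamini–Hochberg
  FDR across categories).
* Taxonomic distribution of the best eligible BLAST hit of each HGT gene
  (the donor-lineage view: the first hit that is neither the query's own
  species nor another focal-genus genome).
* A 16S rRNA molecular-clock bracket: with 1–2% 16S divergence per
  50 Myr, an observed divergence maps to a [min, max] age interval
  (the 2%/50 Myr rate is the fast bound and gives the minimum age).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .ancestry import AncestryCall, ClassifierConfig
from .io_formats import BlastHit, TaxonRecord

__all__ = [
    "EnrichmentResult",
    "ClockCalibration",
    "cog_enrichment",
    "best_hit_taxonomy",
    "estimate_divergence_time",
]

_CONF_RANK = {"high": 0, "medium": 1, "low": 2}


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-category enrichment table plus the genes left out for lacking a COG."""

    table: pd.DataFrame  # category, count_ancestral, count_hgt, odds_ratio,
    #                      p_value, q_value, direction
    n_no_cog_ancestral: int
    n_no_cog_hgt: int


@dataclass(frozen=True)
class ClockCalibration:
    """16S rRNA clock: percent divergence accumulated per ``myr_per_unit``.

    ``percent_high`` is the fast rate (more divergence per unit time, so it
    yields the minimum age); ``percent_low`` the slow rate (maximum age).
    """

    percent_low: float = 1.0
    percent_high: float = 2.0
    myr_per_unit: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.percent_low <= self.percent_high):
            raise ValueError("need 0 < percent_low <= percent_high")


def _filter_by_confidence(
    calls: Sequence[AncestryCall], category: str, floor: str
) -> list[AncestryCall]:
    if floor not in _CONF_RANK:
        raise ValueError(f"confidence_floor must be one of {tuple(_CONF_RANK)}")
    level = _CONF_RANK[floor]
    return [
        c for c in calls
        if c.category == category and _CONF_RANK.get(c.confidence, 99) <= level
    ]


def cog_enrichment(
    calls: Sequence[AncestryCall],
    cog_map: Mapping[str, str],
    confidence_floor: str = "high",
) -> EnrichmentResult:
    """Compare COG category composition of the ancestral vs HGT gene sets.

    Genes are filtered to confidence >= ``confidence_floor``; genes without
    a COG assignment are excluded from the tests and reported in the
    ``n_no_cog_*`` counts.  For each category present in either set a 2x2
    table (in-category / not x ancestral / hgt) is tested with a two-sided
    Fisher exact test; q-values are Benjamini–Hochberg across categories.
    Direction is by odds ratio (ancestral counts in the numerator):
    OR > 1 ancestral-enriched, OR < 1 hgt-enriched, OR = 1 none.
    """
    anc = _filter_by_confidence(calls, "ancestral", confidence_floor)
    hgt = _filter_by_confidence(calls, "hgt", confidence_floor)
    anc_cats = [cog_map[c.query_id] for c in anc if c.query_id in cog_map]
    hgt_cats = [cog_map[c.query_id] for c in hgt if c.query_id in cog_map]
    n_no_cog_anc = len(anc) - len(anc_cats)
    n_no_cog_hgt = len(hgt) - len(hgt_cats)
    if not anc_cats or not hgt_cats:
        raise ValueError(
            "one of the ancestral/hgt sets is empty after filtering; "
            "try a lower confidence_floor"
        )

    n_anc, n_hgt = len(anc_cats), len(hgt_cats)
    categories = sorted(set(anc_cats) | set(hgt_cats))
    rows = []
    for cat in categories:
        a = anc_cats.count(cat)  # ancestral, in category
        b = hgt_cats.count(cat)  # hgt, in category
        c = n_anc - a
        d = n_hgt - b
        _stat, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if b * c == 0:
            # undefined OR guarded with an inf/nan sentinel
            odds = math.inf if a * d > 0 else math.nan
        else:
            odds = (a * d) / (b * c)
        if odds > 1:
            direction = "ancestral-enriched"
        elif odds < 1:
            direction = "hgt-enriched"
        else:
            direction = "none"
        rows.append(
            {
                "category": cat,
                "count_ancestral": a,
                "count_hgt": b,
                "odds_ratio": odds,
                "p_value": p,
                "direction": direction,
            }
        )
    table = pd.DataFrame(rows)
    _rej, qvals, _a, _b = multipletests(table["p_value"], method="fdr_bh")
    table["q_value"] = qvals
    table = table[
        ["category", "count_ancestral", "count_hgt", "odds_ratio",
         "p_value", "q_value", "direction"]
    ]
    return EnrichmentResult(
        table=table, n_no_cog_ancestral=n_no_cog_anc, n_no_cog_hgt=n_no_cog_hgt
    )


def best_hit_taxonomy(
    hit_tables: Mapping[str, Sequence[BlastHit]],
    calls: Sequence[AncestryCall],
    taxonomy: Mapping[str, TaxonRecord],
    cfg: ClassifierConfig,
    group_level: str = "order",
    confidence_floor: str = "low",
) -> pd.DataFrame:
    """Distribution of the best eligible hit's taxon for predicted HGT genes.

    For each HGT call the first hit that is neither the query's own species
    nor another focal-genus genome is taken; its lineage label at
    ``group_level`` ∈ {order, class, phylum} is tallied.  HGT genes with no
    eligible hit fall in an explicit ``unresolved`` bin.  Fractions
    (including unresolved) sum to 1.  An empty HGT set yields an empty table.
    """
    attr = {"order": "order", "class": "class_name", "phylum": "phylum"}.get(group_level)
    if attr is None:
        raise ValueError("group_level must be 'order', 'class' or 'phylum'")
    hgt_calls = _filter_by_confidence(calls, "hgt", confidence_floor)
    counts: dict[str, int] = {}
    for call in hgt_calls:
        group = "unresolved"
        for hit in hit_tables.get(call.query_id, ()):
            rec = taxonomy.get(hit.subject_id)
            if rec is None:
                continue
            if rec.species == cfg.self_species or rec.genus == cfg.focal_genus:
                continue
            label = getattr(rec, attr)
            if not label:
                raise ValueError(
                    f"taxonomy record {rec.subject_key!r} lacks a {group_level} label"
                )
            group = label
            break
        counts[group] = counts.get(group, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["group", "count", "fraction"])
    total = sum(counts.values())
    rows = [
        {"group": g, "count": n, "fraction": n / total}
        for g, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)


def estimate_divergence_time(
    divergence_percent: float, cal: ClockCalibration = ClockCalibration()
) -> tuple[float, float]:
    """Bracket a divergence time from percent 16S divergence.

    Returns ``(t_min_myr, t_max_myr)``; e.g. 8% divergence under the
    1–2%/50 Myr calibration gives (200, 400) Myr.
    """
    if divergence_percent < 0:
        raise ValueError("divergence_percent must be >= 0")
    t_min = divergence_percent / cal.percent_high * cal.myr_per_unit
    t_max = divergence_percent / cal.percent_low * cal.myr_per_unit
    return (t_min, t_max)
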