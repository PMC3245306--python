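"""Ancestral-vs-HGT classification of genes from their taxonomic BLAST neighborhood.

The classifier labels each query protein ``ancestral`` or ``hgt``
(horizontally transferred) with tiered confidence by asking which taxa
appear among its best database hits.  A gene inherited vertically should
find its closest relatives — here the family *Rhodospirillaceae* and order
*Rhodospirillales* that contain *Azospirillum* — dominating its top hits; a
recently acquired gene should find none of them there.

Each query's hit list is reduced to a *neighborhood*: hits below the
E-value cutoff are discarded upstream, hits to the query's own species are
removed, and only the first occurrence of each species is kept (the
reference database is species-non-redundant, so repeats are strain-level
noise).  The rules then count family/order members in rank windows over
that ordered species sequence:

========== ============ ==============================================
category   confidence   condition (defaults)
========== ============ ==============================================
ancestral  high         >=6 of top 8 in the focal order; for lists
                        shorter than 8 species, all but one
ancestral  medium       >=4 focal-family species in the top 8
ancestral  low          >=1 focal-family species in the top 8, after
                        removing other focal-genus species
hgt        high         0 focal-order species in the top 10, after
                        removing other focal-genus species
hgt        medium       as above over the top 5
hgt        low          0 focal-family species in the top 8, after
                        removing other focal-genus species
unassigned —            no hits outside the focal genus, or the
                        hgt-medium and ancestral-low conditions hold
                        simultaneously (conflicting evidence)
========== ============ ==============================================

Rules are evaluated in a fixed precedence order so that stronger evidence
wins: no-outside-genus-hits → ancestral-high → hgt-high → ancestral-medium
→ conflict → hgt-medium → ancestral-low → hgt-low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import BlastHit, TaxonRecord

__all__ = [
    "ClassifierConfig",
    "Neighborhood",
    "AncestryCall",
    "ProportionSummary",
    "UnresolvableSubjectError",
    "membership_letter",
    "build_neighborhood",
    "classify_membership_sequence",
    "classify_ancestry",
    "classify_genome",
    "summarize_proportions",
    "CATEGORIES",
    "CONFIDENCES",
]

CATEGORIES = ("ancestral", "hgt", "unassigned")
CONFIDENCES = ("high", "medium", "low", "none")


class UnresolvableSubjectError(KeyError):
    """Subject ids with no taxonomy record (lists the offending ids)."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Focal lineage and rule constants for the neighborhood classifier.

    The window/threshold defaults encode the rule table in the module
    docstring; they are exposed so the same machinery can be pointed at a
    different focal lineage or stress-tested under different windows.

    ``count_focal_genus_in_ancestral``
        Whether other focal-genus species count toward the ancestral
        high/medium tallies (they are bona fide family members; default
        True).  The low-confidence and all HGT rules always exclude them.
    ``genus_exclusion``
        ``"prefilter"`` removes focal-genus species from the sequence
        before taking a top-k window (genus hits cannot consume window
        slots and mask distal evidence); ``"inwindow"`` keeps them in the
        window but ignores them in the count.
    """

    self_species: str
    focal_genus: str = "Azospirillum"
    focal_family: str = "Rhodospirillaceae"
    focal_order: str = "Rhodospirillales"
    window_high_anc: int = 8
    threshold_high_anc: int = 6
    window_med_anc: int = 8
    threshold_med_anc: int = 4
    window_low_anc: int = 8
    window_high_hgt: int = 10
    window_med_hgt: int = 5
    window_low_hgt: int = 8
    count_focal_genus_in_ancestral: bool = True
    genus_exclusion: str = "prefilter"
    evalue_cutoff: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("window_high_anc", "window_med_anc", "window_low_anc",
                     "window_high_hgt", "window_med_hgt", "window_low_hgt"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.threshold_high_anc > self.window_high_anc:
            raise ValueError("threshold_high_anc exceeds its window")
        if self.threshold_med_anc > self.window_med_anc:
            raise ValueError("threshold_med_anc exceeds its window")
        if self.genus_exclusion not in ("prefilter", "inwindow"):
            raise ValueError("genus_exclusion must be 'prefilter' or 'inwindow'")


@dataclass(frozen=True)
class Neighborhood:
    """A query's ordered, species-deduplicated taxonomic hit sequence."""

    query_id: str
    species_seq: tuple[tuple[str, str, str, str], ...]  # (species, genus, family, order)


@dataclass(frozen=True)
class AncestryCall:
    query_id: str
    category: str  # ancestral | hgt | unassigned
    confidence: str  # high | medium | low | none
    rule_fired: str
    evidence: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if (self.category == "unassigned") != (self.confidence == "none"):
            raise ValueError("category 'unassigned' iff confidence 'none'")


def membership_letter(genus: str, family: str, order: str, cfg: ClassifierConfig) -> str:
    """Collapse a lineage to its relation to the focal lineage.

    ``G`` other focal-genus species, ``F`` focal-family species outside the
    genus, ``O`` focal-order species outside the family, ``X`` outside the
    order.
    """
    if genus == cfg.focal_genus:
        return "G"
    if family == cfg.focal_family:
        return "F"
    if order == cfg.focal_order:
        return "O"
    return "X"


def build_neighborhood(
    hits: Sequence[BlastHit],
    taxonomy: Mapping[str, TaxonRecord],
    cfg: ClassifierConfig,
    lenient: bool = False,
) -> Neighborhood:
    """Map hits to species, drop the query's own species, and keep each
    species' first occurrence, preserving hit order.

    Subject ids resolve against ``taxonomy`` directly by ``subject_id``.
    Unresolvable ids raise :class:`UnresolvableSubjectError` listing every
    offender, or are skipped when ``lenient`` is set.
    """
    unresolved = [h.subject_id for h in hits if h.subject_id not in taxonomy]
    if unresolved and not lenient:
        raise UnresolvableSubjectError(
            f"no taxonomy record for subject id(s): {', '.join(sorted(set(unresolved)))}"
        )
    seen: set[str] = set()
    seq: list[tuple[str, str, str, str]] = []
    for h in hits:
        rec = taxonomy.get(h.subject_id)
        if rec is None:
            continue
        if rec.species == cfg.self_species or rec.species in seen:
            continue
        seen.add(rec.species)
        seq.append((rec.species, rec.genus, rec.family, rec.order))
    query_id = hits[0].query_id if hits else ""
    return Neighborhood(query_id=query_id, species_seq=tuple(seq))


def classify_membership_sequence(
    letters: Sequence[str], cfg: ClassifierConfig
) -> tuple[str, str, str, dict]:
    """Classify an ordered membership sequence over the alphabet ``GFOX``.

    This is the rule engine behind :func:`classify_ancestry`, exposed for
    what-if exploration on bare membership strings (e.g. ``"FFOXX"``).
    Returns ``(category, confidence, rule_fired, evidence)``.
    """
    n = len(letters)
    if cfg.genus_exclusion == "prefilter":
        xg = [m for m in letters if m != "G"]
    else:  # inwindow: genus keeps its slot but never counts
        xg = ["X" if m == "G" else m for m in letters]
    if not any(m != "G" for m in letters):
        return (
            "unassigned",
            "none",
            "no_hits_outside_genus",
            {"n_species": n},
        )

    if cfg.count_focal_genus_in_ancestral:
        order_members = ("G", "F", "O")
        family_members = ("G", "F")
    else:
        order_members = ("F", "O")
        family_members = ("F",)

    top_ha = letters[: cfg.window_high_anc]
    order_in_ha = sum(m in order_members for m in top_ha)
    # short lists: "all but 1" suffices, but never zero evidence — at least
    # one focal-order species must actually be present
    need_high = cfg.threshold_high_anc if n >= cfg.window_high_anc else max(n - 1, 1)
    evidence = {
        "n_species": n,
        "order_in_top_high_anc": order_in_ha,
        "threshold_high_anc": need_high,
    }
    if order_in_ha >= need_high:
        return ("ancestral", "high", "anc_high", evidence)

    order_in_hh = sum(m in ("F", "O") for m in xg[: cfg.window_high_hgt])
    evidence["order_in_top_high_hgt_xg"] = order_in_hh
    if order_in_hh == 0:
        return ("hgt", "high", "hgt_high", evidence)

    fam_in_ma = sum(m in family_members for m in letters[: cfg.window_med_anc])
    evidence["family_in_top_med_anc"] = fam_in_ma
    if fam_in_ma >= cfg.threshold_med_anc:
        return ("ancestral", "medium", "anc_med", evidence)

    hgt_med = sum(m in ("F", "O") for m in xg[: cfg.window_med_hgt]) == 0
    anc_low = any(m == "F" for m in xg[: cfg.window_low_anc])
    evidence["hgt_med_holds"] = int(hgt_med)
    evidence["anc_low_holds"] = int(anc_low)
    if hgt_med and anc_low:
        return ("unassigned", "none", "conflict_hgt_med_vs_anc_low", evidence)
    if hgt_med:
        return ("hgt", "medium", "hgt_med", evidence)
    if anc_low:
        return ("ancestral", "low", "anc_low", evidence)
    if not any(m == "F" for m in xg[: cfg.window_low_hgt]):
        return ("hgt", "low", "hgt_low", evidence)
    return ("unassigned", "none", "no_rule_fired", evidence)


def classify_ancestry(nb: Neighborhood, cfg: ClassifierConfig) -> AncestryCall:
    """Apply the rule table to one neighborhood."""
    letters = [membership_letter(g, f, o, cfg) for (_s, g, f, o) in nb.species_seq]
    category, confidence, rule, evidence = classify_membership_sequence(letters, cfg)
    return AncestryCall(
        query_id=nb.query_id,
        category=category,
        confidence=confidence,
        rule_fired=rule,
        evidence=evidence,
    )


def classify_genome(
    hit_tables: Mapping[str, Sequence[BlastHit]],
    taxonomy: Mapping[str, TaxonRecord],
    cfg: ClassifierConfig,
    all_queries: Iterable[str] | None = None,
    lenient: bool = False,
) -> list[AncestryCall]:
    """Classify every query; queries listed in ``all_queries`` but absent
    from ``hit_tables`` are unassigned (no detectable homologs).

    Output is sorted by query id so results do not depend on mapping
    iteration order.
    """
    calls: list[AncestryCall] = []
    for query_id in hit_tables:
        nb = build_neighborhood(hit_tables[query_id], taxonomy, cfg, lenient=lenient)
        if not nb.query_id:
            nb = Neighborhood(query_id=query_id, species_seq=())
        calls.append(classify_ancestry(nb, cfg))
    if all_queries is not None:
        for query_id in all_queries:
            if query_id not in hit_tables:
                calls.append(
                    AncestryCall(
                        query_id=query_id,
                        category="unassigned",
                        confidence="none",
                        rule_fired="no_hits",
                        evidence={"n_species": 0},
                    )
                )
    return sorted(calls, key=lambda c: c.query_id)


@dataclass(frozen=True)
class ProportionSummary:
    """Category x confidence counts and fractions over a set of calls."""

    counts: dict[tuple[str, str], int]
    fractions: dict[tuple[str, str], float]
    n_total: int

    def category_fractions(self) -> dict[str, float]:
        out = {c: 0.0 for c in CATEGORIES}
        for (cat, _conf), frac in self.fractions.items():
            out[cat] += frac
        return out

    def high_confidence_only(self) -> dict[str, int]:
        """Counts restricted to high-confidence ancestral/hgt calls."""
        return {
            cat: self.counts.get((cat, "high"), 0)
            for cat in ("ancestral", "hgt")
        }


def summarize_proportions(calls: Sequence[AncestryCall]) -> ProportionSummary:
    """Tally calls into category x confidence counts and fractions."""
    if not calls:
        raise ValueError("cannot summarize an empty call list")
    counts: dict[tuple[str, str], int] = {}
    for c in calls:
        key = (c.category, c.confidence)
        counts[key] = counts.get(key, 0) + 1
    n = len(calls)
    fractions = {k: v / n for k, v in counts.items()}
    return ProportionSummary(counts=counts, fractions=fractions, n_total=n)
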