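"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive, written straight from the prose statement of
each rule or formula, and share no code with the package.
"""

from __future__ import annotations

from math import comb

# Membership alphabet: G other focal-genus species, F focal-family species
# outside the genus, O focal-order species outside the family, X outside.


def literal_conditions(seq) -> dict[str, bool]:
    """Each classification sentence transcribed word for word as a boolean.

    "Rhodospirillales" members are G, F and O; "Rhodospirillaceae" members
    are G and F; "excluding hits to other Azospirillum genomes" drops G
    from the list before anything else.
    """
    seq = list(seq)
    no_genus = [c for c in seq if c != "G"]

    # High confidence ancestral proteins have at least 6 of the top 8
    # species belonging to Rhodospirillales, or all but 1 if the BLAST
    # result had less than 8 species.  "All but 1" of a one-species list
    # would be zero, so short lists still need at least one order member
    # actually present.
    if len(seq) >= 8:
        anc_high = len([c for c in seq[:8] if c in "GFO"]) >= 6
    elif len(seq) >= 1:
        anc_high = len([c for c in seq if c in "GFO"]) >= max(len(seq) - 1, 1)
    else:
        anc_high = False

    # Medium confidence ancestral proteins have at least 4 Rhodospirillaceae
    # in the top 8.
    anc_med = len([c for c in seq[:8] if c in "GF"]) >= 4

    # Low confidence ancestral proteins have at least 1 Rhodospirillaceae in
    # the top 8, excluding hits to other Azospirillum genomes.
    anc_low = len([c for c in no_genus[:8] if c == "F"]) >= 1

    # High confidence horizontally transferred proteins have 0 hits to
    # Rhodospirillales in the top 10, excluding hits to other Azospirillum
    # genomes.
    hgt_high = len([c for c in no_genus[:10] if c in "FO"]) == 0

    # Medium: 0 hits to Rhodospirillales in the top 5, excluding ...
    hgt_med = len([c for c in no_genus[:5] if c in "FO"]) == 0

    # Low: 0 hits to Rhodospirillaceae in the top 8, excluding ...
    hgt_low = len([c for c in no_genus[:8] if c == "F"]) == 0

    # Unassigned proteins either have no BLAST hits outside Azospirillum, or
    # simultaneously classify as medium confidence horizontally transferred
    # and medium or low confidence ancestral.
    no_outside = len(no_genus) == 0

    return {
        "anc_high": anc_high,
        "anc_med": anc_med,
        "anc_low": anc_low,
        "hgt_high": hgt_high,
        "hgt_med": hgt_med,
        "hgt_low": hgt_low,
        "no_outside": no_outside,
        "conflict": hgt_med and (anc_med or anc_low),
    }


def literal_ancestry(seq) -> tuple[str, str]:
    """Apply the sentences in strongest-evidence-first order.

    Genes with no hits outside the focal genus are unassigned outright;
    then ancestral-high, hgt-high, ancestral-medium, the stated
    medium-hgt-vs-ancestral conflict, hgt-medium, ancestral-low, hgt-low.
    """
    c = literal_conditions(seq)
    if c["no_outside"]:
        return ("unassigned", "none")
    if c["anc_high"]:
        return ("ancestral", "high")
    if c["hgt_high"]:
        return ("hgt", "high")
    if c["anc_med"]:
        return ("ancestral", "medium")
    if c["conflict"]:
        return ("unassigned", "none")
    if c["hgt_med"]:
        return ("hgt", "medium")
    if c["anc_low"]:
        return ("ancestral", "low")
    if c["hgt_low"]:
        return ("hgt", "low")
    return ("unassigned", "none")


def first_occurrence_scan(species_list, self_species):
    """Set-based one-pass species dedup with self removal."""
    seen, out = set(), []
    for sp in species_list:
        if sp == self_species or sp in seen:
            continue
        seen.add(sp)
        out.append(sp)
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive enumeration of tables with the
    same margins, summing probabilities <= that of the observed table."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x: int) -> float:
        # hypergeometric: x successes (row1) among c1 draws
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = table_prob(a)
    eps = 1e-12
    return sum(
        p for x in range(0, min(r1, c1) + 1)
        if (p := table_prob(x)) <= p_obs * (1 + eps)
    )


def per_base_coding_fraction(records) -> float:
    """Brute-force per-base CDS occupancy over GenomeRecord-like objects."""
    covered = total = 0
    for rec in records:
        occupied = [False] * len(rec.sequence)
        for f in rec.features:
            if f.type == "CDS":
                for i in range(f.start - 1, f.end):
                    occupied[i] = True
        covered += sum(occupied)
        total += len(rec.sequence)
    return 100.0 * covered / total


def naive_nsaf(items):
    """Two-pass NSAF: compute all SAFs, then normalize."""
    safs = {pid: spc / length for pid, spc, length in items}
    total = sum(safs.values())
    return {pid: saf / total for pid, saf in safs.items()}


def exhaustive_pcr_pairs(seq: str, fwd: str, rev: str, max_product: int):
    """All (start, end) amplicons by scanning every position pair, both
    primer-role orientations, on the plus strand representation."""

    def rc(s):
        return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    found = set()
    for f, r in ((fwd, rev), (rev, fwd)):
        for i in range(len(seq) - len(f) + 1):
            if seq[i : i + len(f)] != f:
                continue
            target = rc(r)
            for j in range(i + len(f), len(seq) - len(r) + 1):
                if seq[j : j + len(r)] != target:
                    continue
                length = j + len(r) - i
                if length <= max_product:
                    found.add((i + 1, j + len(r)))
    return found
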