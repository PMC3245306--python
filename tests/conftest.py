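from __future__ import annotations

import pytest

from azohgt.ancestry import ClassifierConfig, Neighborhood
from azohgt.io_formats import BlastHit, TaxonRecord

SELF = "Azospirillum lipoferum 4B"


@pytest.fixture(scope="session")
def cfg() -> ClassifierConfig:
    return ClassifierConfig(self_species=SELF)


#: one representative species per membership letter
LETTER_SPECIES = {
    "G": ("Azospirillum sp. B510", "Azospirillum", "Rhodospirillaceae", "Rhodospirillales"),
    "F": ("Rhodospirillum rubrum", "Rhodospirillum", "Rhodospirillaceae", "Rhodospirillales"),
    "O": ("Acetobacter pasteurianus", "Acetobacter", "Acetobacteraceae", "Rhodospirillales"),
    "X": ("Escherichia coli", "Escherichia", "Enterobacteriaceae", "Enterobacterales"),
}


def neighborhood_from_letters(letters: str, query_id: str = "q1") -> Neighborhood:
    """Build a Neighborhood whose memberships spell ``letters``.

    Species names are uniquified per position so nothing deduplicates away.
    """
    seq = []
    for i, letter in enumerate(letters):
        sp, genus, family, order = LETTER_SPECIES[letter]
        seq.append((f"{sp} #{i}", genus, family, order))
    return Neighborhood(query_id=query_id, species_seq=tuple(seq))


def make_hit(query, subject, rank, evalue=1e-50, bitscore=500.0) -> BlastHit:
    return BlastHit(
        query_id=query,
        subject_id=subject,
        percent_identity=90.0,
        aln_length=200,
        evalue=evalue,
        bitscore=bitscore,
        rank=rank,
    )


@pytest.fixture(scope="session")
def small_taxonomy() -> dict[str, TaxonRecord]:
    """The 8-genome focal-family universe plus one outside species."""
    rows = [
        (SELF, "Azospirillum"),
        ("Azospirillum brasilense Sp245", "Azospirillum"),
        ("Magnetospirillum magneticum", "Magnetospirillum"),
        ("Magnetospirillum gryphiswaldense", "Magnetospirillum"),
        ("Magnetospirillum magnetotacticum", "Magnetospirillum"),
        ("Rhodospirillum rubrum", "Rhodospirillum"),
        ("Rhodospirillum centenum", "Rhodospirillum"),
        ("Nisaea sp. BAL199", "Nisaea"),
    ]
    tax = {
        sp.replace(" ", "_"): TaxonRecord(
            subject_key=sp.replace(" ", "_"),
            species=sp,
            genus=genus,
            family="Rhodospirillaceae",
            order="Rhodospirillales",
        )
        for sp, genus in rows
    }
    tax["Escherichia_coli"] = TaxonRecord(
        subject_key="Escherichia_coli",
        species="Escherichia coli",
        genus="Escherichia",
        family="Enterobacteriaceae",
        order="Enterobacterales",
    )
    return tax
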