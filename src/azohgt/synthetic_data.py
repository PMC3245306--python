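"""Ground-truth generators for every input the pipeline consumes.

The generators emulate the statistical structure the classifier assumes,
sized like the study system: a species universe with the focal genus
*Azospirillum* inside *Rhodospirillaceae* (2 other focal-genus genomes and
5 other family genomes — the *Magnetospirillum*/*Rhodospirillum*
complement), further *Rhodospirillales* members, and outside-order donors
concentrated in *Rhizobiales* and *Burkholderiales* (the lineages
over-represented among observed HGT donors) plus a mixed bag of other
orders.

An ancestral gene's hit list leads with the non-self family species (each
retained with probability ``family_retention``, mirroring incomplete
homolog detection), followed by order-level species and a tail of outside
species.  An HGT gene leads with a species from a donor group drawn from
``donor_group_probs`` followed by other outside species, keeping the top
10 free of family/order hits; family homologs, when present, appear only
beyond rank 12 (acquired genes may spread within the order later).
E-values are a deterministic decreasing function of rank — the rules are
rank-based, so only the cutoff matters.

Everything is a pure function of (config, seed): the same seed reproduces
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_formats import BlastHit, GenomeFeature, GenomeRecord, PsmRecord, TaxonRecord
from .proteomics import PsmFilterConfig, psm_passes

__all__ = [
    "SimConfig",
    "SimLabel",
    "ConfigError",
    "CPAB_FWD_PRIMER",
    "CPAB_REV_PRIMER",
    "simulate_taxonomy",
    "simulate_hit_tables",
    "simulate_psm_table",
    "simulate_genome_with_primers",
]

#: Primer pair flanking the 211-bp internal cpaB fragment.
CPAB_FWD_PRIMER = "GCGTGGACCTGATCCTGAC"
CPAB_REV_PRIMER = "GTGACCGTCTCGCTCTGAC"


class ConfigError(ValueError):
    """An impossible generator configuration."""


_GENUS_OTHERS = ["Azospirillum sp. B510", "Azospirillum brasilense Sp245"]
_FAMILY_OTHERS = [
    "Magnetospirillum magneticum AMB-1",
    "Magnetospirillum gryphiswaldense MSR-1",
    "Magnetospirillum magnetotacticum MS-1",
    "Rhodospirillum rubrum",
    "Rhodospirillum centenum",
]
_ORDER_NONFAMILY = [
    ("Acetobacter pasteurianus", "Acetobacter"),
    ("Gluconobacter oxydans", "Gluconobacter"),
    ("Gluconacetobacter diazotrophicus", "Gluconacetobacter"),
    ("Granulibacter bethesdensis", "Granulibacter"),
]
# (species, genus, family, order, class, phylum) per outside donor group
_OUTSIDE_POOLS: dict[str, list[tuple[str, str, str, str, str, str]]] = {
    "Rhizobiales": [
        (s, s.split()[0], f, "Rhizobiales", "Alphaproteobacteria", "Proteobacteria")
        for s, f in [
            ("Rhizobium etli", "Rhizobiaceae"),
            ("Rhizobium leguminosarum", "Rhizobiaceae"),
            ("Sinorhizobium meliloti", "Rhizobiaceae"),
            ("Agrobacterium tumefaciens", "Rhizobiaceae"),
            ("Bradyrhizobium japonicum", "Bradyrhizobiaceae"),
            ("Nitrobacter winogradskyi", "Bradyrhizobiaceae"),
            ("Mesorhizobium loti", "Phyllobacteriaceae"),
            ("Ochrobactrum anthropi", "Brucellaceae"),
            ("Brucella melitensis", "Brucellaceae"),
            ("Methylobacterium extorquens", "Methylobacteriaceae"),
        ]
    ],
    "Burkholderiales": [
        (s, s.split()[0], f, "Burkholderiales", "Betaproteobacteria", "Proteobacteria")
        for s, f in [
            ("Burkholderia xenovorans", "Burkholderiaceae"),
            ("Burkholderia cenocepacia", "Burkholderiaceae"),
            ("Cupriavidus necator", "Burkholderiaceae"),
            ("Ralstonia solanacearum", "Burkholderiaceae"),
            ("Bordetella pertussis", "Alcaligenaceae"),
            ("Variovorax paradoxus", "Comamonadaceae"),
            ("Polaromonas naphthalenivorans", "Comamonadaceae"),
            ("Acidovorax citrulli", "Comamonadaceae"),
            ("Delftia acidovorans", "Comamonadaceae"),
            ("Janthinobacterium lividum", "Oxalobacteraceae"),
        ]
    ],
    "other": [
        ("Escherichia coli", "Escherichia", "Enterobacteriaceae", "Enterobacterales",
         "Gammaproteobacteria", "Proteobacteria"),
        ("Vibrio cholerae", "Vibrio", "Vibrionaceae", "Vibrionales",
         "Gammaproteobacteria", "Proteobacteria"),
        ("Pseudomonas fluorescens", "Pseudomonas", "Pseudomonadaceae",
         "Pseudomonadales", "Gammaproteobacteria", "Proteobacteria"),
        ("Xanthomonas campestris", "Xanthomonas", "Xanthomonadaceae",
         "Xanthomonadales", "Gammaproteobacteria", "Proteobacteria"),
        ("Bacillus subtilis", "Bacillus", "Bacillaceae", "Bacillales",
         "Bacilli", "Firmicutes"),
        ("Clostridium acetobutylicum", "Clostridium", "Clostridiaceae",
         "Clostridiales", "Clostridia", "Firmicutes"),
        ("Streptomyces coelicolor", "Streptomyces", "Streptomycetaceae",
         "Streptomycetales", "Actinomycetia", "Actinobacteria"),
        ("Myxococcus xanthus", "Myxococcus", "Myxococcaceae", "Myxococcales",
         "Deltaproteobacteria", "Proteobacteria"),
        ("Geobacter sulfurreducens", "Geobacter", "Geobacteraceae",
         "Desulfuromonadales", "Deltaproteobacteria", "Proteobacteria"),
        ("Flavobacterium johnsoniae", "Flavobacterium", "Flavobacteriaceae",
         "Flavobacteriales", "Flavobacteriia", "Bacteroidetes"),
    ],
}


@dataclass(frozen=True)
class SimConfig:
    """Conditions for hit-table simulation.

    ``family_retention`` is the probability that each non-self family
    species appears among an ancestral gene's leading hits;
    ``donor_group_probs`` is the multinomial over donor groups for HGT
    genes' best hits.  The taxonomy-shape counts default to the reference
    database composition (2 other focal-genus genomes, 5 other family
    genomes).
    """

    seed: int
    n_genes: int = 1000
    hgt_fraction: float = 0.5
    family_retention: float = 0.9
    donor_group_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Rhizobiales": 0.5, "Burkholderiales": 0.3, "other": 0.2}
    )
    n_focal_genus_other: int = 2
    n_family_other: int = 5
    n_order_nonfamily: int = 4
    n_outside: int = 30
    self_species: str = "Azospirillum lipoferum 4B"
    gene_prefix: str = "AZOLI_g"
    n_outside_per_hgt: int = 12
    family_tail_prob: float = 0.3
    genus_lead_prob: float = 0.3
    dup_hit_prob: float = 0.2

    def __post_init__(self) -> None:
        for name in ("hgt_fraction", "family_retention"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_focal_genus_other", "n_family_other",
                     "n_order_nonfamily", "n_outside"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        psum = sum(self.donor_group_probs.values())
        if abs(psum - 1.0) > 1e-9 or any(p < 0 for p in self.donor_group_probs.values()):
            raise ConfigError("donor_group_probs must be non-negative and sum to 1")
        unknown = set(self.donor_group_probs) - set(_OUTSIDE_POOLS)
        if unknown:
            raise ConfigError(f"unknown donor group(s): {sorted(unknown)}")
        if self.hgt_fraction < 1 and self.family_retention > 0 and self.n_family_other == 0:
            raise ConfigError(
                "impossible shape: ancestral genes require family species "
                "(family_retention > 0 with n_family_other = 0)"
            )
        if self.n_outside < max(self.n_outside_per_hgt, 10):
            raise ConfigError("n_outside must cover at least the HGT top-10 window")


def _synth_names(base: str, genus: str, n: int) -> list[str]:
    return [f"{genus} sp. {base}{i}" for i in range(1, n + 1)]


def _species_universe(cfg: SimConfig):
    """Named pools sized to the config (synthetic names pad short pools)."""
    genus = list(_GENUS_OTHERS[: cfg.n_focal_genus_other])
    if len(genus) < cfg.n_focal_genus_other:
        genus += _synth_names("SYN-G", "Azospirillum", cfg.n_focal_genus_other - len(genus))
    family = list(_FAMILY_OTHERS[: cfg.n_family_other])
    if len(family) < cfg.n_family_other:
        family += _synth_names("SYN-F", "Phaeospirillum", cfg.n_family_other - len(family))
    order = [s for s, _g in _ORDER_NONFAMILY[: cfg.n_order_nonfamily]]
    if len(order) < cfg.n_order_nonfamily:
        order += _synth_names("SYN-O", "Acidiphilium", cfg.n_order_nonfamily - len(order))
    # outside species round-robin across groups so every group stays populated
    outside: list[tuple[str, str, str, str, str, str]] = []
    group_names = list(_OUTSIDE_POOLS)
    idx = {g: 0 for g in group_names}
    while len(outside) < cfg.n_outside:
        progressed = False
        for g in group_names:
            if len(outside) >= cfg.n_outside:
                break
            pool = _OUTSIDE_POOLS[g]
            if idx[g] < len(pool):
                outside.append(pool[idx[g]])
                idx[g] += 1
                progressed = True
        if not progressed:  # pools exhausted: synthesize per-group extras
            for g in group_names:
                if len(outside) >= cfg.n_outside:
                    break
                i = idx[g] + 1
                tmpl = _OUTSIDE_POOLS[g][0]
                outside.append(
                    (f"{tmpl[1]} sp. SYN-X{i}", tmpl[1], tmpl[2], tmpl[3], tmpl[4], tmpl[5])
                )
                idx[g] += 1
    return genus, family, order, outside


def _subject_key(species: str) -> str:
    return species.replace(" ", "_").replace(".", "")


def simulate_taxonomy(cfg: SimConfig) -> dict[str, TaxonRecord]:
    """Subject→lineage table covering every species the generator can emit."""
    genus, family, order, outside = _species_universe(cfg)
    records: dict[str, TaxonRecord] = {}

    def add(species, genus_name, family_name, order_name, class_name, phylum):
        records[_subject_key(species)] = TaxonRecord(
            subject_key=_subject_key(species),
            species=species,
            genus=genus_name,
            family=family_name,
            order=order_name,
            class_name=class_name,
            phylum=phylum,
        )

    add(cfg.self_species, "Azospirillum", "Rhodospirillaceae", "Rhodospirillales",
        "Alphaproteobacteria", "Proteobacteria")
    for s in genus:
        add(s, "Azospirillum", "Rhodospirillaceae", "Rhodospirillales",
            "Alphaproteobacteria", "Proteobacteria")
    for s in family:
        add(s, s.split()[0], "Rhodospirillaceae", "Rhodospirillales",
            "Alphaproteobacteria", "Proteobacteria")
    for s in order:
        add(s, s.split()[0], "Acetobacteraceae", "Rhodospirillales",
            "Alphaproteobacteria", "Proteobacteria")
    for s, g, f, o, c, p in outside:
        add(s, g, f, o, c, p)
    return records


@dataclass(frozen=True)
class SimLabel:
    category: str  # ancestral | hgt
    donor_group: str | None = None  # for hgt genes


def _hits_for(query_id: str, species_list: list[str], rng, dup_prob: float) -> list[BlastHit]:
    hits: list[BlastHit] = []
    rank = 0
    for i, sp in enumerate(species_list):
        copies = 2 if (dup_prob > 0 and rng.random() < dup_prob) else 1
        for _ in range(copies):
            rank += 1
            hits.append(
                BlastHit(
                    query_id=query_id,
                    subject_id=_subject_key(sp),
                    percent_identity=max(30.0, round(98.0 - 1.5 * i, 1)),
                    aln_length=int(200 + 10 * (i % 7)),
                    evalue=10.0 ** (-150 + 3 * i),
                    bitscore=max(50.0, 800.0 - 20.0 * i),
                    rank=rank,
                )
            )
    return hits


def simulate_hit_tables(
    cfg: SimConfig,
) -> tuple[dict[str, list[BlastHit]], dict[str, SimLabel]]:
    """Per-gene BLAST hit lists with known ancestral/HGT labels."""
    rng = np.random.default_rng(cfg.seed)
    genus, family, order, outside = _species_universe(cfg)
    outside_by_group: dict[str, list[str]] = {g: [] for g in _OUTSIDE_POOLS}
    for entry in outside:
        for g, pool in _OUTSIDE_POOLS.items():
            if entry in pool or (entry[0].startswith(f"{pool[0][1]} sp. SYN-X")):
                outside_by_group[g].append(entry[0])
                break
    all_outside = [e[0] for e in outside]
    groups = sorted(g for g, p in cfg.donor_group_probs.items() if p > 0)
    for g in groups:
        if not outside_by_group[g]:
            raise ConfigError(f"donor group {g!r} has probability > 0 but no species")
    probs = np.array([cfg.donor_group_probs[g] for g in groups])

    hit_tables: dict[str, list[BlastHit]] = {}
    labels: dict[str, SimLabel] = {}
    fam_lead = genus + family  # non-self family members, canonical order
    for i in range(cfg.n_genes):
        gene = f"{cfg.gene_prefix}{i + 1:04d}"
        is_hgt = rng.random() < cfg.hgt_fraction
        species_list: list[str] = [cfg.self_species]  # a query's best hit is itself
        if not is_hgt:
            retained = [s for s in fam_lead if rng.random() < cfg.family_retention]
            tail_n = min(cfg.n_outside_per_hgt, len(all_outside))
            tail = list(rng.choice(all_outside, size=tail_n, replace=False))
            species_list += retained + list(order) + tail
            labels[gene] = SimLabel(category="ancestral")
        else:
            gi = int(rng.choice(len(groups), p=probs))
            group = groups[gi]
            donor_pool = outside_by_group[group]
            best = donor_pool[int(rng.integers(len(donor_pool)))]
            rest_pool = [s for s in all_outside if s != best]
            n_rest = min(cfg.n_outside_per_hgt - 1, len(rest_pool))
            rest = list(rng.choice(rest_pool, size=n_rest, replace=False))
            lead: list[str] = []
            if rng.random() < cfg.genus_lead_prob and genus:
                lead = [genus[int(rng.integers(len(genus)))]]
            tail_family: list[str] = []
            if rng.random() < cfg.family_tail_prob and family:
                tail_family = [family[int(rng.integers(len(family)))]]
            species_list += lead + [best] + rest + tail_family
            labels[gene] = SimLabel(category="hgt", donor_group=group)
        hit_tables[gene] = _hits_for(gene, species_list, rng, cfg.dup_hit_prob)
    return hit_tables, labels


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def simulate_psm_table(
    seed: int,
    n_psms: int = 500,
    n_proteins: int = 30,
    pass_fraction: float = 0.6,
    decoy_fraction: float = 0.1,
    decoy_pass_fraction: float = 0.2,
    cfg: PsmFilterConfig = PsmFilterConfig(),
) -> tuple[list[PsmRecord], list[bool]]:
    """PSMs with per-spectrum ground-truth pass labels.

    Passing PSMs are drawn at or above every threshold (occasionally
    exactly at it, to pin the inclusive boundary); failing PSMs violate
    one randomly chosen criterion.  Decoy PSMs target ``REV_``-prefixed
    proteins and pass with ``decoy_pass_fraction``.
    """
    rng = np.random.default_rng(seed)
    psms: list[PsmRecord] = []
    truth: list[bool] = []
    for _ in range(n_psms):
        is_decoy = bool(rng.random() < decoy_fraction)
        prot = f"P{int(rng.integers(n_proteins)) + 1:03d}"
        if is_decoy:
            prot = f"REV_{prot}"
        should_pass = bool(
            rng.random() < (decoy_pass_fraction if is_decoy else pass_fraction)
        )
        charge = int(rng.integers(1, 4))
        thr = cfg.xcorr_min_by_charge[charge]
        peptide = "".join(rng.choice(_AA, size=9))
        if should_pass:
            xcorr = thr if rng.random() < 0.1 else thr + float(rng.uniform(0.05, 2.0))
            dcn = cfg.delta_cn_min if rng.random() < 0.1 else float(rng.uniform(0.09, 0.5))
            status = "semi" if rng.random() < 0.3 else "fully"
        else:
            mode = int(rng.integers(3))
            xcorr = thr + float(rng.uniform(0.05, 2.0))
            dcn = float(rng.uniform(0.09, 0.5))
            status = "fully"
            if mode == 0:
                xcorr = thr - float(rng.uniform(0.01, 0.5))
            elif mode == 1:
                dcn = cfg.delta_cn_min - float(rng.uniform(0.001, 0.07))
            else:
                status = "non"
        psm = PsmRecord(
            peptide=peptide,
            protein_id=prot,
            charge=charge,
            xcorr=round(xcorr, 4),
            delta_cn=round(dcn, 4),
            tryptic_status=status,
            is_decoy=is_decoy,
        )
        # rounding could graze a threshold; recompute the label from the record
        psms.append(psm)
        truth.append(psm_passes(psm, cfg))
    return psms, truth


# ---------------------------------------------------------------------------
# Genomes with planted primer sites
# ---------------------------------------------------------------------------


def simulate_genome_with_primers(
    seed: int,
    length: int = 5000,
    n_cds: int = 3,
    n_trna: int = 2,
    cds_fraction: float = 0.4,
    fwd: str = CPAB_FWD_PRIMER,
    rev: str = CPAB_REV_PRIMER,
    amplicon_length: int = 211,
    replicon_id: str = "synthetic_replicon",
) -> tuple[GenomeRecord, dict]:
    """A random replicon with planted CDS/tRNA features and one primer pair.

    Returns the record plus a truth dict with the planted amplicon
    coordinates (1-based inclusive), the disjoint CDS intervals and the
    exact coding percentage they cover.
    """
    from .genome_stats import revcomp

    if amplicon_length < len(fwd) + len(rev):
        raise ConfigError("amplicon shorter than the two primers")
    if amplicon_length > length:
        raise ConfigError("amplicon longer than the sequence")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    rc_rev = revcomp(rev)
    for _attempt in range(50):
        seq = list(rng.choice(bases, size=length))
        fstart = int(rng.integers(0, length - amplicon_length + 1))
        seq[fstart : fstart + len(fwd)] = list(fwd)
        rstart = fstart + amplicon_length - len(rev)
        seq[rstart : rstart + len(rev)] = list(rc_rev)
        s = "".join(seq)
        # the planted pair must be the only primer binding sites
        if (
            s.count(fwd) == 1
            and s.count(rc_rev) == 1
            and s.count(rev) == 0
            and s.count(revcomp(fwd)) == 0
        ):
            break
    else:  # pragma: no cover - astronomically unlikely for 19-mers
        raise RuntimeError("could not plant a unique primer pair")

    cds_total = int(round(length * cds_fraction))
    if n_cds > 0 and cds_total > 0:
        sizes = [cds_total // n_cds] * n_cds
        sizes[0] += cds_total - sum(sizes)
        gap = max(1, (length - cds_total) // (n_cds + 1))
        features = []
        pos = 1
        intervals = []
        for size in sizes:
            start = pos + gap
            end = start + size - 1
            if end > length:
                raise ConfigError("cds_fraction too high for disjoint placement")
            intervals.append((start, end))
            features.append(GenomeFeature(type="CDS", start=start, end=end, strand="+"))
            pos = end
    else:
        features, intervals = [], []
    for t in range(n_trna):
        start = 1 + t * 80
        features.append(
            GenomeFeature(type="tRNA", start=start, end=min(start + 74, length), strand="-")
        )
    record = GenomeRecord(replicon_id=replicon_id, sequence=s, features=tuple(features))
    truth = {
        "amplicon_start": fstart + 1,
        "amplicon_end": fstart + amplicon_length,
        "amplicon_length": amplicon_length,
        "cds_intervals": intervals,
        "coding_percent": 100.0 * cds_total / length,
    }
    return record, truth
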