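"""Readers and writers for the tabular and flat-file formats the pipeline touches.

Every reader validates strictly and every writer emits plain TSV whose
metadata lines start with ``#`` followed by a tab-separated column header,
so that each writer's output round-trips through its reader.

Conventions
-----------
* BLAST hit files are 12+-column outfmt-6 tables
  (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore).  File order within a query is trusted — BLAST emits
  hits in descending bitscore and the downstream rank-based rules are
  defined on that order — and recorded as a 1-based ``rank``.
* Genome coordinates are 1-based inclusive throughout; ``join``/
  ``complement`` locations collapse to (min start, max end, strand).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "BlastHit",
    "TaxonRecord",
    "GenomeFeature",
    "GenomeRecord",
    "PsmRecord",
    "ParseError",
    "SchemaError",
    "DuplicateKeyError",
    "COG_CATEGORIES",
    "TRYPTIC_STATUSES",
    "read_blast_tab",
    "write_blast_tab",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "read_cog_map",
    "read_genome_flatfile",
    "read_psm_table",
    "write_psm_table",
    "read_calls_table",
    "write_calls_table",
]


class ParseError(ValueError):
    """A malformed row or block in an input file (reports the line number)."""


class SchemaError(ValueError):
    """A missing column or an out-of-vocabulary token."""


class DuplicateKeyError(ValueError):
    """A key that must be unique within a table appeared twice."""


#: The 25 one-letter COG functional categories.
COG_CATEGORIES = frozenset("JAKLBDYVTMNZWUOCGEFHIPQRS")

TRYPTIC_STATUSES = ("fully", "semi", "non")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    rank: int  # 1-based position within the query's retained hit list


@dataclass(frozen=True)
class TaxonRecord:
    """Lineage labels for one subject sequence (or species).

    ``class_name`` and ``phylum`` are optional higher ranks used only when
    best-hit distributions are grouped above the order level.
    """

    subject_key: str
    species: str
    genus: str
    family: str
    order: str
    class_name: str = ""
    phylum: str = ""


@dataclass(frozen=True)
class GenomeFeature:
    type: str  # CDS | tRNA | rRNA | other
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' | '-'


@dataclass(frozen=True)
class GenomeRecord:
    replicon_id: str
    sequence: str
    features: tuple[GenomeFeature, ...] = ()

    def features_of_type(self, ftype: str) -> tuple[GenomeFeature, ...]:
        return tuple(f for f in self.features if f.type == ftype)


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with the fields the DTASelect-style filter needs."""

    peptide: str
    protein_id: str
    charge: int
    xcorr: float
    delta_cn: float
    tryptic_status: str  # fully | semi | non
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.tryptic_status not in TRYPTIC_STATUSES:
            raise SchemaError(
                f"unknown tryptic_status {self.tryptic_status!r}; "
                f"expected one of {TRYPTIC_STATUSES}"
            )
        if self.delta_cn < 0:
            raise ValueError("delta_cn must be >= 0")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

_BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_blast_tab(path, evalue_cutoff: float = 1e-4) -> dict[str, list[BlastHit]]:
    """Parse an outfmt-6 style BLAST table into per-query ordered hit lists.

    Hits with ``evalue > evalue_cutoff`` are dropped; file order within each
    query is preserved and re-numbered as ``rank`` (1-based) over the
    retained hits.  Queries whose hits are all removed still appear, mapped
    to an empty list.  An empty file yields an empty mapping.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    hits: dict[str, list[BlastHit]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=12 tab-separated "
                    f"columns, got {len(parts)}"
                )
            try:
                pident = float(parts[2])
                length = int(parts[3])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric field ({exc})") from None
            if evalue < 0:
                raise ParseError(f"{path}: line {lineno}: negative e-value")
            query = parts[0]
            if not query:
                raise ParseError(f"{path}: line {lineno}: empty query id")
            bucket = hits.setdefault(query, [])
            if evalue > evalue_cutoff:
                continue
            bucket.append(
                BlastHit(
                    query_id=query,
                    subject_id=parts[1],
                    percent_identity=pident,
                    aln_length=length,
                    evalue=evalue,
                    bitscore=bitscore,
                    rank=len(bucket) + 1,
                )
            )
    return hits


def write_blast_tab(hit_tables: Mapping[str, Iterable[BlastHit]], path) -> None:
    """Write hit lists back out as 12-column outfmt-6 (placeholder coordinates)."""
    with open(path, "w", encoding="utf-8") as fh:
        for query in hit_tables:
            for h in hit_tables[query]:
                row = [
                    h.query_id,
                    h.subject_id,
                    f"{h.percent_identity:.2f}",
                    str(h.aln_length),
                    "0",
                    "0",
                    "1",
                    str(h.aln_length),
                    "1",
                    str(h.aln_length),
                    f"{h.evalue:.3g}",
                    f"{h.bitscore:.1f}",
                ]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Generic commented-TSV helpers
# ---------------------------------------------------------------------------


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _write_tsv(df: pd.DataFrame, path, header_note: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy and COG maps
# ---------------------------------------------------------------------------


def read_taxonomy_table(path) -> dict[str, TaxonRecord]:
    """Read a subject→lineage TSV (subject_key, species, genus, family, order
    [, class, phylum]) into a mapping keyed by subject_key."""
    df = _read_tsv(path, ("subject_key", "species", "genus", "family", "order"))
    records: dict[str, TaxonRecord] = {}
    for _, row in df.iterrows():
        key = row["subject_key"]
        if key in records:
            raise DuplicateKeyError(f"{path}: duplicate subject_key {key!r}")
        for col in ("species", "genus", "family", "order"):
            if not row[col]:
                raise SchemaError(f"{path}: empty {col} for subject_key {key!r}")
        records[key] = TaxonRecord(
            subject_key=key,
            species=row["species"],
            genus=row["genus"],
            family=row["family"],
            order=row["order"],
            class_name=row.get("class", ""),
            phylum=row.get("phylum", ""),
        )
    return records


def write_taxonomy_table(taxonomy: Mapping[str, TaxonRecord], path) -> None:
    rows = []
    has_upper = any(t.class_name or t.phylum for t in taxonomy.values())
    for t in taxonomy.values():
        row = {
            "subject_key": t.subject_key,
            "species": t.species,
            "genus": t.genus,
            "family": t.family,
            "order": t.order,
        }
        if has_upper:
            row["class"] = t.class_name
            row["phylum"] = t.phylum
        rows.append(row)
    _write_tsv(pd.DataFrame(rows), path, "subject -> lineage table")


def read_cog_map(path) -> dict[str, str]:
    """Read a gene→COG one-letter functional category TSV (gene_id, category)."""
    df = _read_tsv(path, ("gene_id", "category"))
    cog: dict[str, str] = {}
    for _, row in df.iterrows():
        gene, cat = row["gene_id"], row["category"]
        if cat not in COG_CATEGORIES:
            raise SchemaError(f"{path}: {cat!r} is not a one-letter COG category")
        if gene in cog:
            raise DuplicateKeyError(f"{path}: duplicate gene_id {gene!r}")
        cog[gene] = cat
    return cog


# ---------------------------------------------------------------------------
# Genome flat files
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _detect_flatfile_format(path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                return "genbank" if line.startswith("LOCUS") else "embl"
    raise ParseError(f"{path}: empty file")


def read_genome_flatfile(path, fmt: str | None = None) -> GenomeRecord:
    """Read a GenBank/EMBL flat file into a :class:`GenomeRecord`.

    The sequence is upper-cased.  CDS, tRNA and rRNA features keep their
    type; other feature keys (except ``source``) map to ``other``.
    Compound (``join``/``complement``) locations resolve to the minimal
    enclosing interval with the feature's strand.  Features whose location
    cannot be interpreted are skipped with a warning.
    """
    fmt = fmt or _detect_flatfile_format(path)
    try:
        seqrec = SeqIO.read(path, fmt)
    except Exception as exc:  # Bio raises plain ValueError on bad blocks
        raise ParseError(f"{path}: not a readable {fmt} record: {exc}") from None
    sequence = str(seqrec.seq).upper()
    if not sequence:
        raise ParseError(f"{path}: record has no sequence block")
    features = []
    for feat in seqrec.features:
        if feat.type == "source":
            continue
        ftype = _FEATURE_TYPES.get(feat.type, "other")
        try:
            start = int(feat.location.start) + 1  # 0-based -> 1-based
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
        except (TypeError, AttributeError):
            warnings.warn(f"{path}: skipping feature with unparseable location: {feat}")
            continue
        if not (1 <= start <= end <= len(sequence)):
            warnings.warn(
                f"{path}: skipping {ftype} feature with out-of-range "
                f"coordinates {start}..{end}"
            )
            continue
        features.append(GenomeFeature(type=ftype, start=start, end=end, strand=strand))
    return GenomeRecord(replicon_id=seqrec.id, sequence=sequence, features=tuple(features))


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

_PSM_COLUMNS = ("peptide", "protein_id", "charge", "xcorr", "delta_cn", "tryptic_status")


def read_psm_table(path, default_tryptic: bool = False) -> list[PsmRecord]:
    """Read a PSM TSV.  ``is_decoy`` is optional (default false).

    ``tryptic_status`` may only be defaulted to ``fully`` when
    ``default_tryptic=True``; the semi-tryptic filter is meaningless on
    silently defaulted data, so by default a missing column is an error.
    """
    required = _PSM_COLUMNS if not default_tryptic else _PSM_COLUMNS[:-1]
    df = _read_tsv(path, required)
    records = []
    for i, row in df.iterrows():
        status = row["tryptic_status"] if "tryptic_status" in df.columns else "fully"
        decoy = row.get("is_decoy", "false").strip().lower() in ("1", "true", "yes")
        try:
            records.append(
                PsmRecord(
                    peptide=row["peptide"],
                    protein_id=row["protein_id"],
                    charge=int(row["charge"]),
                    xcorr=float(row["xcorr"]),
                    delta_cn=float(row["delta_cn"]),
                    tryptic_status=status,
                    is_decoy=decoy,
                )
            )
        except (ValueError, SchemaError) as exc:
            if isinstance(exc, SchemaError):
                raise
            raise ParseError(f"{path}: row {i + 2}: {exc}") from None
    return records


def write_psm_table(psms: Iterable[PsmRecord], path) -> None:
    rows = [
        {
            "peptide": p.peptide,
            "protein_id": p.protein_id,
            "charge": p.charge,
            "xcorr": repr(p.xcorr),
            "delta_cn": repr(p.delta_cn),
            "tryptic_status": p.tryptic_status,
            "is_decoy": str(p.is_decoy).lower(),
        }
        for p in psms
    ]
    _write_tsv(pd.DataFrame(rows, columns=list(_PSM_COLUMNS) + ["is_decoy"]), path,
               "peptide-spectrum matches")


# ---------------------------------------------------------------------------
# Ancestry call tables
# ---------------------------------------------------------------------------


def write_calls_table(calls, path) -> None:
    """Write ancestry calls as TSV (query_id, category, confidence, rule_fired,
    evidence_json)."""
    import json

    rows = [
        {
            "query_id": c.query_id,
            "category": c.category,
            "confidence": c.confidence,
            "rule_fired": c.rule_fired,
            "evidence_json": json.dumps(c.evidence, sort_keys=True),
        }
        for c in calls
    ]
    _write_tsv(
        pd.DataFrame(rows, columns=["query_id", "category", "confidence",
                                    "rule_fired", "evidence_json"]),
        path,
        "gene ancestry calls",
    )


def read_calls_table(path):
    """Inverse of :func:`write_calls_table`."""
    import json

    from .ancestry import AncestryCall

    df = _read_tsv(path, ("query_id", "category", "confidence", "rule_fired"))
    calls = []
    for _, row in df.iterrows():
        evidence = json.loads(row["evidence_json"]) if row.get("evidence_json") else {}
        calls.append(
            AncestryCall(
                query_id=row["query_id"],
                category=row["category"],
                confidence=row["confidence"],
                rule_fired=row["rule_fired"],
                evidence=evidence,
            )
        )
    return calls
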