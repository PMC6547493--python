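"""Curation of trait-associated sites (TAS) into gene-to-term tables.

An association-mapping study reports markers significantly associated with a
trait. Because marker-gene correlation decays over the linkage-disequilibrium
(LD) distance, a significant marker implicates every gene whose flanking
window of +/- d kb contains it. This module ingests association summary
tables, gates them on significance, maps markers to genes by LD windows at
one or more cutoffs (10/25 kb maize-style, 25/50 kb rice-style), resolves
free-text trait names to trait-ontology terms, and emits evidence-bearing
gene-to-term tables.

Coordinate conventions: GFF3 gene models and association tables are 1-based
inclusive at I/O. Window arithmetic is done at that convention; a marker at
position x links to a gene [start, end] at cutoff d bp iff
``start - d <= x <= end + d`` (both sides closed), with the lower bound
clamped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import re
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .ontology import Ontology, TermFrequencyTable, UnknownTermError

__all__ = [
    "CurationError",
    "SchemaError",
    "GenomeVersionError",
    "AssociationRecord",
    "GeneModel",
    "TraitDictionary",
    "GeneToTermTable",
    "LoadReport",
    "DEFAULT_SCHEMA",
    "load_association_table",
    "load_gff3",
    "filter_significant",
    "map_trait_to_terms",
    "assign_markers_to_genes",
    "build_gene_to_term_table",
    "top_fraction_filter",
    "query_genes_by_trait",
]


class CurationError(Exception):
    pass


class SchemaError(CurationError):
    pass


class GenomeVersionError(CurationError):
    pass


@dataclass(frozen=True)
class AssociationRecord:
    """One marker-trait association row from a summary table."""

    marker_name: str
    chromosome: str
    position: int  # 1-based bp
    p_value: float
    trait_name: str
    study_id: str
    variant_class: str = ""  # snp | indel
    maf: float | None = None
    pop_type: str = ""
    pop_size: str = ""
    marker_set: str = ""
    model: str = ""
    genome_version: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0,1], got {self.p_value}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must be in [0,0.5], got {self.maf}")
        if not self.study_id or not self.trait_name:
            raise ValueError("study_id and trait_name must be non-empty")


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: 1-based inclusive coordinates on a named chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


# canonical field -> source column header, mirroring the published
# 30-column association summary layout
DEFAULT_SCHEMA: dict[str, str] = {
    "marker_name": "Marker_name",
    "chromosome": "chr_ref",
    "position": "Marker_location",
    "p_value": "Pvalue",
    "variant_class": "indel/snp",
    "maf": "MAF",
    "trait_name": "Trait",
    "study_id": "ID_ref",
    "pop_type": "Pop_type",
    "pop_size": "Pop_size",
    "marker_set": "Marker_set",
    "model": "Model",
    "genome_version": "genome_version",
}

_MANDATORY = ("marker_name", "chromosome", "position", "p_value", "trait_name", "study_id")


@dataclass
class LoadReport:
    """Per-row rejection report from :func:`load_association_table`."""

    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def load_association_table(
    path,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[AssociationRecord], LoadReport]:
    """Read a TSV association summary into records.

    ``schema`` maps canonical field names to the file's column headers
    (defaults to the published 30-column layout). Rows whose position or
    p-value (or MAF, when present) cannot be parsed are not silently
    dropped: they are returned, with reasons, in the :class:`LoadReport`.

    Raises
    ------
    SchemaError
        If a mandatory column is absent, listing every missing field.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [f for f in _MANDATORY if schema[f] not in df.columns]
    if missing:
        raise SchemaError(
            "association table is missing mandatory columns: "
            + ", ".join(f"{f} (expected header {schema[f]!r})" for f in missing)
        )

    records: list[AssociationRecord] = []
    report = LoadReport()
    for idx, row in df.iterrows():
        def get(fieldname: str) -> str:
            col = schema.get(fieldname, "")
            return str(row[col]).strip() if col in df.columns else ""

        try:
            pos = int(float(get("position")))
            pval = float(get("p_value"))
            maf_raw = get("maf")
            maf = float(maf_raw) if maf_raw not in ("", "NA", "na", ".") else None
            rec = AssociationRecord(
                marker_name=get("marker_name"),
                chromosome=get("chromosome"),
                position=pos,
                p_value=pval,
                trait_name=get("trait_name"),
                study_id=get("study_id"),
                variant_class=get("variant_class"),
                maf=maf,
                pop_type=get("pop_type"),
                pop_size=get("pop_size"),
                marker_set=get("marker_set"),
                model=get("model"),
                genome_version=get("genome_version"),
            )
        except (ValueError, TypeError) as exc:
            report.rejected.append((int(idx), str(exc)))
            continue
        records.append(rec)
    return records, report


def load_gff3(path, feature_type: str = "gene", genome_version: str = "") -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Only features of ``feature_type`` are kept; the ID attribute names the
    gene. ``genome_version`` is attached to nothing here but is used by
    :func:`check_genome_version` callers to guard against build mismatches.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
            )
        )
    return genes


def check_genome_version(records: Sequence[AssociationRecord], expected: str) -> None:
    """Hard error on a genome-build mismatch; no lift-over is attempted."""
    if not expected:
        return
    bad = sorted({r.genome_version for r in records if r.genome_version and r.genome_version != expected})
    if bad:
        raise GenomeVersionError(
            f"association records use genome version(s) {bad} but gene models are {expected!r}"
        )


def filter_significant(
    records: Iterable[AssociationRecord],
    threshold: float = 1e-5,
    per_study: Mapping[str, float] | None = None,
) -> list[AssociationRecord]:
    """Keep records passing the significance gate p <= threshold.

    Each study may override the default with its own cutoff (studies apply
    their own significance criteria; the gate is configurable, not fixed).
    """
    per_study = per_study or {}
    return [r for r in records if r.p_value <= per_study.get(r.study_id, threshold)]


# --------------------------------------------------------------------------
# trait-name resolution


def _normalize(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip().lower())


def _tokens(label: str) -> frozenset[str]:
    return frozenset(re.findall(r"[a-z0-9]+", _normalize(label)))


class TraitDictionary:
    """Curated mapping from normalised trait labels to TO term sets.

    Entries carry a provenance note: ``curated`` for hand-assigned entries,
    ``similarity-suggested`` for entries admitted via the semantic-similarity
    fallback of :func:`map_trait_to_terms`.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]] | None = None,
                 ontology: Ontology | None = None):
        self._entries: dict[str, tuple[frozenset[str], str]] = {}
        self._ontology = ontology
        for label, terms in (entries or {}).items():
            self.add(label, terms, provenance="curated")

    def add(self, label: str, terms: Iterable[str], provenance: str = "curated") -> None:
        terms = frozenset(terms)
        if self._ontology is not None:
            unknown = [t for t in terms if t not in self._ontology]
            if unknown:
                raise CurationError(
                    f"trait {label!r} maps to terms absent from the ontology: {sorted(unknown)}"
                )
        self._entries[_normalize(label)] = (terms, provenance)

    def lookup(self, label: str) -> tuple[frozenset[str], str] | None:
        return self._entries.get(_normalize(label))

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return _normalize(label) in self._entries

    @classmethod
    def from_tsv(cls, path, ontology: Ontology | None = None) -> "TraitDictionary":
        """Read a two-column TSV: trait label, comma-separated term ids."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        d = cls(ontology=ontology)
        for _, row in df.iterrows():
            d.add(str(row.iloc[0]), [t for t in str(row.iloc[1]).split(",") if t])
        return d

    def to_tsv(self, path) -> None:
        rows = [
            {"trait": label, "term_ids": ",".join(sorted(terms)), "provenance": prov}
            for label, (terms, prov) in sorted(self._entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def map_trait_to_terms(
    trait_name: str,
    trait_dict: TraitDictionary,
    ontology: Ontology,
    freq: TermFrequencyTable | None = None,
    threshold: float = 0.4,
) -> tuple[frozenset[str], str]:
    """Resolve a free-text trait label to ontology terms.

    An exact hit on the normalised label returns the curated entry. For an
    unseen label, each ontology term's name is tokenised and the term whose
    token profile maximises the IC-weighted semantic similarity against the
    query's tokens is suggested — provided the score reaches ``threshold``.
    Token IC comes from ``freq`` (a token-frequency table); tokens the table
    has never seen get maximal surprisal ``-ln(1/(total+1))``.

    Returns ``(terms, provenance)`` with provenance one of ``curated``,
    ``similarity-suggested`` or ``unmapped`` (empty term set).
    """
    if not trait_name.strip():
        raise ValueError("trait_name must be non-empty")
    hit = trait_dict.lookup(trait_name)
    if hit is not None:
        return hit[0], "curated"
    if freq is None:
        return frozenset(), "unmapped"

    query = _tokens(trait_name)
    if not query:
        return frozenset(), "unmapped"
    unseen_ic = math.log(freq.total + 1)

    def ic(tok: str) -> float:
        return freq.information_content(tok) if freq.count(tok) > 0 else unseen_ic

    best_term, best_sim = None, -1.0
    for term in sorted(ontology, key=lambda t: t.term_id):
        cand = _tokens(term.name)
        if not cand:
            continue
        denom = sum(ic(t) for t in query | cand)
        sim = sum(ic(t) for t in query & cand) / denom if denom > 0 else 0.0
        if sim > best_sim:
            best_term, best_sim = term.term_id, sim
    if best_term is not None and best_sim >= threshold:
        return frozenset({best_term}), "similarity-suggested"
    return frozenset(), "unmapped"


# --------------------------------------------------------------------------
# marker -> gene assignment


def assign_markers_to_genes(
    records: Sequence[AssociationRecord],
    genes: Sequence[GeneModel],
    ld_distance_kb: float,
) -> list[tuple[str, AssociationRecord]]:
    """Link each marker to every gene whose LD flanking window contains it.

    A record links to a gene iff they share a chromosome and the marker
    position lies in ``[start - d, end + d]`` (closed, d in bp, lower bound
    clamped at 1). One marker may link to several overlapping genes; each
    (gene, record) link is emitted once. Strand is ignored.
    """
    if ld_distance_kb <= 0:
        raise ValueError(f"ld_distance_kb must be positive, got {ld_distance_kb}")
    d = int(round(ld_distance_kb * 1000))

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = max(1, g.start - d)
        hi = g.end + d
        trees.setdefault(g.chromosome, IntervalTree()).addi(lo, hi + 1, g.gene_id)

    links: list[tuple[str, AssociationRecord]] = []
    for rec in records:
        tree = trees.get(rec.chromosome)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.at(rec.position))
        links.extend((gid, rec) for gid in hits)
    return links


# --------------------------------------------------------------------------
# gene-to-term tables


_EVIDENCE_COLS = ["gene_id", "term_id", "ld_level_kb", "study_id", "marker_name", "p_value"]


class GeneToTermTable:
    """Evidence-bearing gene-to-term links at a stated LD level.

    ``evidence`` keeps one row per (link x term) with study provenance;
    ``pairs()`` is the deduplicated (gene, term) view used for counting —
    the published relationship counts collapse repeated support from
    different studies to one pair.
    """

    def __init__(self, evidence: pd.DataFrame, ld_levels: Sequence[float] = (10, 25)):
        missing = [c for c in _EVIDENCE_COLS if c not in evidence.columns]
        if missing:
            raise CurationError(f"evidence table missing columns: {missing}")
        self.evidence = evidence.reset_index(drop=True)
        self.ld_levels = tuple(sorted(float(x) for x in ld_levels))
        bad = set(self.evidence["ld_level_kb"].astype(float)) - set(self.ld_levels)
        if bad:
            raise CurationError(
                f"evidence contains ld_level_kb values {sorted(bad)} outside configured {self.ld_levels}"
            )

    def pairs(self, ld_level_kb: float | None = None) -> pd.DataFrame:
        """Unique (gene_id, term_id) pairs, optionally at one LD level."""
        ev = self.evidence
        if ld_level_kb is not None:
            ev = ev[ev["ld_level_kb"].astype(float) == float(ld_level_kb)]
        return (
            ev[["gene_id", "term_id"]]
            .drop_duplicates()
            .sort_values(["gene_id", "term_id"])
            .reset_index(drop=True)
        )

    def n_unique_genes(self, ld_level_kb: float | None = None) -> int:
        return self.pairs(ld_level_kb)["gene_id"].nunique()

    def n_unique_pairs(self, ld_level_kb: float | None = None) -> int:
        return len(self.pairs(ld_level_kb))

    def genes_for_term(self, term_id: str) -> frozenset[str]:
        p = self.pairs()
        return frozenset(p.loc[p["term_id"] == term_id, "gene_id"])

    def to_tsv(self, path) -> None:
        self.evidence[_EVIDENCE_COLS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, ld_levels: Sequence[float] | None = None) -> "GeneToTermTable":
        ev = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "term_id": str})
        if ld_levels is None:
            ld_levels = sorted(ev["ld_level_kb"].astype(float).unique())
        return cls(ev, ld_levels=ld_levels)


def build_gene_to_term_table(
    links: Sequence[tuple[str, AssociationRecord]],
    trait_terms: Mapping[str, frozenset[str]] | None,
    ld_level_kb: float,
    ld_levels: Sequence[float] = (10, 25),
    ontology: Ontology | None = None,
) -> GeneToTermTable:
    """Expand (gene, record) links into an evidence table at one LD level.

    ``trait_terms`` maps each record's trait name to its resolved term set
    (records resolving to an empty set contribute no rows). When an ontology
    is supplied every emitted term must exist in it.
    """
    if float(ld_level_kb) not in {float(x) for x in ld_levels}:
        raise CurationError(
            f"ld_level_kb={ld_level_kb} not in configured set {tuple(ld_levels)}"
        )
    rows = []
    for gene_id, rec in links:
        terms = (
            trait_terms.get(rec.trait_name, frozenset())
            if trait_terms is not None
            else frozenset()
        )
        for term in sorted(terms):
            if ontology is not None and term not in ontology:
                raise CurationError(f"term {term!r} absent from the loaded ontology")
            rows.append(
                {
                    "gene_id": gene_id,
                    "term_id": term,
                    "ld_level_kb": float(ld_level_kb),
                    "study_id": rec.study_id,
                    "marker_name": rec.marker_name,
                    "p_value": rec.p_value,
                }
            )
    ev = pd.DataFrame(rows, columns=_EVIDENCE_COLS).drop_duplicates().reset_index(drop=True)
    return GeneToTermTable(ev, ld_levels=ld_levels)


def top_fraction_filter(
    records: Sequence[AssociationRecord],
    fraction: float,
    per_study: bool = True,
) -> list[AssociationRecord]:
    """Keep the most significant fraction of records (smallest p-values).

    The cut keeps ``ceil(fraction * n)`` records per study (or globally when
    ``per_study`` is false); every record tied with the cutoff p-value is
    retained, so the result may exceed the ceiling — a record is never
    dropped while an equally significant one is kept.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0,1], got {fraction}")

    def cut(group: Sequence[AssociationRecord]) -> list[AssociationRecord]:
        k = math.ceil(fraction * len(group))
        ps = sorted(r.p_value for r in group)
        cutoff = ps[k - 1]
        return [r for r in group if r.p_value <= cutoff]

    if not per_study:
        return cut(list(records)) if records else []
    by_study: dict[str, list[AssociationRecord]] = {}
    for r in records:
        by_study.setdefault(r.study_id, []).append(r)
    out: list[AssociationRecord] = []
    for sid in sorted(by_study):
        out.extend(cut(by_study[sid]))
    return out


def query_genes_by_trait(
    table: GeneToTermTable,
    term_id: str,
    ontology: Ontology,
    descendants: bool = False,
) -> frozenset[str]:
    """Genes annotated to a trait term, optionally including all genes of
    its descendant terms (each gene reported once)."""
    if term_id not in ontology:
        raise UnknownTermError(term_id)
    terms = {term_id}
    if descendants:
        terms |= ontology.descendants(term_id)
    genes: set[str] = set()
    for t in terms:
        genes |= table.genes_for_term(t)
    return frozenset(genes)
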