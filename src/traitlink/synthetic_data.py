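"""Synthetic fixtures with known ground truth.

Every consumer module in this package reads field-standard formats (OBO,
GFF3, TSV). This module writes small instances of each with *planted*
structure — a toy trait ontology, toy chromosomes with gene models,
association studies whose causal genes are known, gene-to-term annotation
sources, and expression matrices with planted co-expression modules — so
the pipeline's output can be checked against an exhaustive truth table.

All generators are bit-reproducible from (spec, seed): the same
:class:`FixtureSpec` always yields byte-identical files.

Design of the planted association studies: markers tagging a causal gene
are placed *inside* the gene body and draw their p-value from the effect
distribution (a point mass at 1e-8 by default, far below any plausible
significance gate), while null markers are placed uniformly along the
chromosome with p ~ Uniform(0,1), which essentially never passes a 1e-5
gate. The truth table is then computed by exhaustive enumeration: for each
LD cutoff, every (gene, term) pair supported by a gate-passing marker
within the gene's flanking window — including genes that merely neighbour
a causal one — is listed. Recovery is therefore exactly decidable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import Ontology, OntologyTerm
from .tas_curation import AssociationRecord, GeneModel, TraitDictionary

__all__ = [
    "FixtureSpec",
    "generate_ontology",
    "ontology_to_obo",
    "generate_genes",
    "genes_to_gff3",
    "generate_trait_dictionary",
    "generate_association_study",
    "association_records_to_tsv",
    "generate_annotation",
    "generate_expression",
    "make_fixtures",
]

# the nine root trait groups of the plant trait ontology layout
TRAIT_GROUPS = (
    "yield trait",
    "stress trait",
    "sterility or fertility trait",
    "stature or vigor trait",
    "quality trait",
    "plant morphology trait",
    "plant growth and development trait",
    "biochemical trait",
    "miscellaneous trait",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape parameters for one synthetic study-condition set.

    Defaults describe a desk-scale analogue of the curated corpus: a
    9-root, 6-level ontology; two toy chromosomes; three traits with a few
    planted causal genes each; expression with four planted modules.
    """

    seed: int
    # ontology shape
    ontology_roots: int = 9
    ontology_depth: int = 6
    ontology_branching: int = 2
    second_parent_fraction: float = 0.1
    # genome shape
    n_chromosomes: int = 2
    chromosome_length: int = 2_000_000
    n_genes: int = 120
    gene_length_range: tuple[int, int] = (2_000, 6_000)
    # study shape
    n_traits: int = 3
    causal_genes_per_trait: int = 2
    markers_per_study: int = 60
    markers_per_causal_gene: int = 2
    effect_p_value: float = 1e-8
    effect_p_beta: tuple[float, float] | None = None  # optional Beta(a,b) alternative
    ld_levels_kb: tuple[float, ...] = (10.0, 25.0)
    significance_gate: float = 1e-5
    # expression shape
    n_modules: int = 4
    genes_per_module: int = 25
    n_samples: int = 40
    within_module_correlation: float = 0.8

    def __post_init__(self):
        if not (0.0 < self.within_module_correlation < 1.0):
            raise ValueError("within_module_correlation must be in (0,1)")
        for name in ("ontology_roots", "ontology_depth", "ontology_branching",
                     "n_chromosomes", "n_genes", "n_traits", "markers_per_study",
                     "n_modules", "genes_per_module", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.ontology_depth > 7:
            raise ValueError("ontology_depth capped at 7 layers")


# --------------------------------------------------------------------------
# ontology


def generate_ontology(spec: FixtureSpec) -> Ontology:
    """A rooted DAG: full ``branching``-ary trees under each root, with
    ~``second_parent_fraction`` of non-root terms given a second parent
    (drawn from one level shallower, preserving shortest-path levels) to
    exercise DAG handling."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA11CE]))
    terms: list[OntologyTerm] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"TO:{counter:07d}"

    levels: list[list[str]] = []
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    root_names = (
        TRAIT_GROUPS if spec.ontology_roots == len(TRAIT_GROUPS)
        else tuple(f"trait group {i + 1}" for i in range(spec.ontology_roots))
    )
    roots = []
    for name in root_names:
        tid = next_id()
        roots.append(tid)
        parents[tid] = set()
        names[tid] = name
    levels.append(roots)

    for depth in range(2, spec.ontology_depth + 1):
        layer = []
        for parent in levels[-1]:
            for c in range(spec.ontology_branching):
                tid = next_id()
                parents[tid] = {parent}
                names[tid] = f"{names[parent]} subtrait {depth}.{c + 1}"
                layer.append(tid)
        levels.append(layer)

    # second parents: pick eligible non-root terms; the extra parent sits one
    # level above the term so the shortest-path level is unchanged
    non_root = [t for layer in levels[1:] for t in layer]
    n_extra = int(round(spec.second_parent_fraction * len(non_root)))
    if n_extra:
        chosen = rng.choice(len(non_root), size=n_extra, replace=False)
        level_of = {t: i for i, layer in enumerate(levels) for t in layer}
        for idx in sorted(chosen):
            tid = non_root[idx]
            pool = [p for p in levels[level_of[tid] - 1] if p not in parents[tid]]
            if pool:
                parents[tid].add(pool[int(rng.integers(len(pool)))])

    for layer in levels:
        for tid in layer:
            terms.append(
                OntologyTerm(term_id=tid, name=names[tid],
                             parent_ids=frozenset(parents[tid]))
            )
    return Ontology(terms, max_depth=spec.ontology_depth)


def ontology_to_obo(ontology: Ontology) -> str:
    """Serialise to the OBO subset the parser consumes (deterministic
    byte-for-byte: terms sorted by accession)."""
    buf = io.StringIO()
    buf.write("format-version: 1.2\n")
    buf.write("ontology: traitlink-synthetic\n")
    for term in sorted(ontology, key=lambda t: t.term_id):
        buf.write("\n[Term]\n")
        buf.write(f"id: {term.term_id}\n")
        buf.write(f"name: {term.name}\n")
        for p in sorted(term.parent_ids):
            buf.write(f"is_a: {p} ! {ontology[p].name}\n")
    return buf.getvalue()


# --------------------------------------------------------------------------
# genome


def generate_genes(spec: FixtureSpec) -> list[GeneModel]:
    """Gene models laid out round-robin over toy chromosomes, evenly spaced
    with jitter, lengths uniform in ``gene_length_range``."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6E6E]))
    per_chrom = int(np.ceil(spec.n_genes / spec.n_chromosomes))
    genes: list[GeneModel] = []
    idx = 0
    for c in range(1, spec.n_chromosomes + 1):
        slot = spec.chromosome_length // (per_chrom + 1)
        for g in range(per_chrom):
            if idx >= spec.n_genes:
                break
            idx += 1
            length = int(rng.integers(*spec.gene_length_range))
            anchor = (g + 1) * slot
            jitter = int(rng.integers(-slot // 4, slot // 4 + 1))
            start = max(1, anchor + jitter)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"Gene{idx:04d}", chromosome=f"chr{c}",
                    start=start, end=start + length - 1, strand=strand,
                )
            )
    return genes


def genes_to_gff3(genes: Sequence[GeneModel], genome_version: str = "Toy1.0") -> str:
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    buf.write(f"# genome-version {genome_version}\n")
    for g in sorted(genes, key=lambda x: (x.chromosome, x.start, x.gene_id)):
        buf.write(
            f"{g.chromosome}\ttraitlink\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}\n"
        )
    return buf.getvalue()


# --------------------------------------------------------------------------
# traits & association studies


def generate_trait_dictionary(spec: FixtureSpec, ontology: Ontology) -> TraitDictionary:
    """One curated trait label per planted trait, each mapping to one leaf
    term (deterministic: the first ``n_traits`` leaves by accession)."""
    leaves = sorted(t.term_id for t in ontology if not ontology.descendants(t.term_id))
    if len(leaves) < spec.n_traits:
        raise ValueError("ontology too small for the requested trait count")
    d = TraitDictionary(ontology=ontology)
    for i in range(spec.n_traits):
        d.add(f"trait {i + 1}", {leaves[i]}, provenance="curated")
    return d


@dataclass
class AssociationTruth:
    """Ground truth for a planted association fixture.

    ``causal_genes`` maps trait label -> planted causal gene ids.
    ``pairs_by_ld`` maps LD cutoff (kb) -> the exhaustive set of (gene_id,
    term_id) pairs recoverable at that cutoff under the significance gate.
    """

    causal_genes: dict[str, tuple[str, ...]]
    pairs_by_ld: dict[float, frozenset[tuple[str, str]]]


def generate_association_study(
    spec: FixtureSpec,
    genes: Sequence[GeneModel],
    trait_terms: Mapping[str, frozenset[str]],
    causal_genes: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[AssociationRecord], AssociationTruth]:
    """Emit one study per trait with planted causal markers plus nulls.

    ``trait_terms`` maps trait labels to their curated term sets; traits are
    the sorted keys. ``causal_genes`` may pin the planted genes per trait
    (all must exist in ``genes``); otherwise they are drawn without
    replacement. The returned truth table enumerates, per LD cutoff, every
    (gene, term) pair a gate-passing marker supports.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x455C]))
    gene_ids = [g.gene_id for g in genes]
    by_id = {g.gene_id: g for g in genes}
    traits = sorted(trait_terms)

    if causal_genes is not None:
        for t, cg in causal_genes.items():
            missing = [g for g in cg if g not in by_id]
            if missing:
                raise ValueError(f"causal genes not in gene list: {missing}")
        chosen = {t: tuple(causal_genes[t]) for t in traits}
    else:
        chosen = {}
        for t in traits:
            pick = rng.choice(len(gene_ids), size=spec.causal_genes_per_trait,
                              replace=False)
            chosen[t] = tuple(gene_ids[i] for i in sorted(pick))

    records: list[AssociationRecord] = []
    marker_no = 0
    for study_idx, trait in enumerate(traits, start=1):
        study_id = f"study{study_idx:02d}"
        # effect markers inside each causal gene
        for gid in chosen[trait]:
            g = by_id[gid]
            for _ in range(spec.markers_per_causal_gene):
                marker_no += 1
                pos = int(rng.integers(g.start, g.end + 1))
                if spec.effect_p_beta is not None:
                    a, b = spec.effect_p_beta
                    pval = float(np.clip(rng.beta(a, b), 1e-300, 1.0))
                else:
                    pval = spec.effect_p_value
                records.append(
                    AssociationRecord(
                        marker_name=f"M{marker_no:05d}", chromosome=g.chromosome,
                        position=pos, p_value=pval, trait_name=trait,
                        study_id=study_id, variant_class="snp",
                        maf=float(np.round(rng.uniform(0.05, 0.5), 3)),
                        genome_version="Toy1.0",
                    )
                )
        # null markers uniform along the genome
        n_null = max(0, spec.markers_per_study
                     - spec.markers_per_causal_gene * len(chosen[trait]))
        for _ in range(n_null):
            marker_no += 1
            chrom = f"chr{int(rng.integers(1, spec.n_chromosomes + 1))}"
            pos = int(rng.integers(1, spec.chromosome_length + 1))
            pval = float(np.clip(rng.uniform(), 1e-300, 1.0))
            records.append(
                AssociationRecord(
                    marker_name=f"M{marker_no:05d}", chromosome=chrom,
                    position=pos, p_value=pval, trait_name=trait,
                    study_id=study_id, variant_class="snp",
                    maf=float(np.round(rng.uniform(0.05, 0.5), 3)),
                    genome_version="Toy1.0",
                )
            )

    # exhaustive truth: brute-force scan over gate-passing markers x genes
    pairs_by_ld: dict[float, frozenset[tuple[str, str]]] = {}
    for ld in spec.ld_levels_kb:
        d = int(round(ld * 1000))
        pairs: set[tuple[str, str]] = set()
        for rec in records:
            if rec.p_value > spec.significance_gate:
                continue
            for g in genes:
                if g.chromosome == rec.chromosome and \
                        max(1, g.start - d) <= rec.position <= g.end + d:
                    for term in trait_terms[rec.trait_name]:
                        pairs.add((g.gene_id, term))
        pairs_by_ld[float(ld)] = frozenset(pairs)

    truth = AssociationTruth(causal_genes=chosen, pairs_by_ld=pairs_by_ld)
    return records, truth


def association_records_to_tsv(records: Sequence[AssociationRecord]) -> str:
    """Serialise records with the published column headers."""
    rows = [
        {
            "Marker_name": r.marker_name, "chr_ref": r.chromosome,
            "Marker_location": r.position, "Pvalue": r.p_value,
            "indel/snp": r.variant_class, "MAF": "" if r.maf is None else r.maf,
            "Trait": r.trait_name, "ID_ref": r.study_id,
            "Pop_type": r.pop_type, "Pop_size": r.pop_size,
            "Marker_set": r.marker_set, "Model": r.model,
            "genome_version": r.genome_version,
        }
        for r in records
    ]
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


# --------------------------------------------------------------------------
# annotation sources (for enrichment / FPR experiments)


def generate_annotation(
    n_genes: int,
    n_terms: int,
    genes_per_term: int,
    seed: int,
    source: str = "TO",
) -> "AnnotationSet":
    """A toy annotation source: ``n_terms`` terms each annotating
    ``genes_per_term`` genes drawn without replacement from an
    ``n_genes``-gene background."""
    from .enrichment import AnnotationSet

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA770]))
    background = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    mapping = {}
    for t in range(1, n_terms + 1):
        pick = rng.choice(n_genes, size=genes_per_term, replace=False)
        mapping[f"{source}:{t:07d}"] = {background[i] for i in sorted(pick)}
    return AnnotationSet(mapping, background=background, source=source)


# --------------------------------------------------------------------------
# expression


def generate_expression(spec: FixtureSpec) -> tuple[pd.DataFrame, dict[str, int]]:
    """Expression matrix with planted co-expression modules.

    Each module draws a latent N(0,1) sample profile; member genes are
    ``latent + sigma * noise`` with sigma chosen so the expected
    within-module correlation is ``spec.within_module_correlation``
    (rho = 1 / (1 + sigma^2)). Modules share no latent factor, so expected
    between-module correlation is 0. Returns the matrix and the planted
    gene -> module labels.
    """
    if spec.n_samples < 10:
        raise ValueError("need >= 10 samples for stable correlations")
    rho = spec.within_module_correlation
    sigma = float(np.sqrt(1.0 / rho - 1.0))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xE897]))
    rows, labels = [], {}
    gene_no = 0
    for m in range(1, spec.n_modules + 1):
        latent = rng.standard_normal(spec.n_samples)
        for _ in range(spec.genes_per_module):
            gene_no += 1
            gid = f"EGene{gene_no:04d}"
            rows.append(latent + sigma * rng.standard_normal(spec.n_samples))
            labels[gid] = m
    matrix = pd.DataFrame(
        np.array(rows),
        index=list(labels),
        columns=[f"sample{j:02d}" for j in range(1, spec.n_samples + 1)],
    )
    return matrix, labels


# --------------------------------------------------------------------------
# one-call fixture bundle


def make_fixtures(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Write the full fixture bundle to ``outdir`` and return the paths.

    Files: ontology.obo, genes.gff3, traits.tsv (trait dictionary),
    association.tsv, truth_<ld>kb.tsv per LD cutoff, expression.tsv,
    expression_labels.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ont = generate_ontology(spec)
    paths["ontology"] = outdir / "ontology.obo"
    paths["ontology"].write_text(ontology_to_obo(ont))

    genes = generate_genes(spec)
    paths["genes"] = outdir / "genes.gff3"
    paths["genes"].write_text(genes_to_gff3(genes))

    tdict = generate_trait_dictionary(spec, ont)
    paths["traits"] = outdir / "traits.tsv"
    tdict.to_tsv(paths["traits"])

    trait_terms = {f"trait {i + 1}": tdict.lookup(f"trait {i + 1}")[0]
                   for i in range(spec.n_traits)}
    records, truth = generate_association_study(spec, genes, trait_terms)
    paths["association"] = outdir / "association.tsv"
    paths["association"].write_text(association_records_to_tsv(records))
    for ld, pairs in sorted(truth.pairs_by_ld.items()):
        p = outdir / f"truth_{ld:g}kb.tsv"
        pd.DataFrame(sorted(pairs), columns=["gene_id", "term_id"]).to_csv(
            p, sep="\t", index=False
        )
        paths[f"truth_{ld:g}kb"] = p

    expr, labels = generate_expression(spec)
    paths["expression"] = outdir / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t")
    paths["expression_labels"] = outdir / "expression_labels.tsv"
    pd.DataFrame(sorted(labels.items()), columns=["gene_id", "module_id"]).to_csv(
        paths["expression_labels"], sep="\t", index=False
    )
    return paths
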