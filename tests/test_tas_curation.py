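"""Association-table ingestion, LD-window gene mapping, gene-to-term tables."""

import math
import random

import pandas as pd
import pytest

from traitlink.ontology import Ontology, OntologyTerm, TermFrequencyTable, UnknownTermError
from traitlink.tas_curation import (
    AssociationRecord,
    CurationError,
    GeneModel,
    GeneToTermTable,
    GenomeVersionError,
    SchemaError,
    TraitDictionary,
    assign_markers_to_genes,
    build_gene_to_term_table,
    check_genome_version,
    filter_significant,
    load_association_table,
    load_gff3,
    map_trait_to_terms,
    query_genes_by_trait,
    top_fraction_filter,
)


def _rec(marker="m1", chrom="chr1", pos=1000, p=1e-6, trait="plant height",
         study="s1", **kw):
    return AssociationRecord(
        marker_name=marker, chromosome=chrom, position=pos, p_value=p,
        trait_name=trait, study_id=study, **kw,
    )


ASSOC_HEADER = "Marker_name\tchr_ref\tMarker_location\tPvalue\tindel/snp\tMAF\tTrait\tID_ref\n"


class TestLoadAssociationTable:
    def test_well_formed_rows(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            ASSOC_HEADER
            + "m1\tchr1\t100\t1e-6\tsnp\t0.1\theight\ts1\n"
            + "m2\tchr1\t200\t1e-7\tsnp\t0.2\theight\ts1\n"
            + "m3\tchr2\t300\t0.5\tindel\t\theight\ts1\n"
        )
        records, report = load_association_table(p)
        assert len(records) == 3 and report.n_rejected == 0
        assert records[2].maf is None and records[2].variant_class == "indel"

    def test_unparseable_pvalue_reported_not_dropped_silently(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            ASSOC_HEADER
            + "m1\tchr1\t100\t1e-6\tsnp\t0.1\theight\ts1\n"
            + "m2\tchr1\t200\tNA\tsnp\t0.2\theight\ts1\n"
            + "m3\tchr2\t300\t0.5\tsnp\t0.3\theight\ts1\n"
        )
        records, report = load_association_table(p)
        assert len(records) == 2
        assert report.n_rejected == 1
        assert report.rejected[0][0] == 1  # row index of the bad row

    def test_header_alias_via_schema(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "snp_id\tchr_ref\tMarker_location\tPvalue\tTrait\tID_ref\n"
            "m1\tchr1\t100\t1e-6\theight\ts1\n"
        )
        records, _ = load_association_table(p, schema={"marker_name": "snp_id"})
        assert records[0].marker_name == "m1"

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("Marker_name\tchr_ref\tTrait\tID_ref\nm1\tchr1\theight\ts1\n")
        with pytest.raises(SchemaError, match="position"):
            load_association_table(p)


class TestRecordInvariants:
    @pytest.mark.parametrize(
        "kw",
        [
            {"pos": 0},
            {"p": 0.0},
            {"p": 1.5},
            {"trait": ""},
            {"study": ""},
        ],
    )
    def test_invalid_fields_rejected(self, kw):
        args = {"pos": 10, "p": 0.5, "trait": "t", "study": "s"}
        args.update(kw)
        with pytest.raises(ValueError):
            _rec(pos=args["pos"], p=args["p"], trait=args["trait"], study=args["study"])

    def test_maf_bounds(self):
        with pytest.raises(ValueError):
            _rec(maf=0.6)
        assert _rec(maf=0.5).maf == 0.5


class TestGff3:
    def test_round_trip(self, tmp_path, genes):
        from traitlink.synthetic_data import genes_to_gff3

        p = tmp_path / "g.gff3"
        p.write_text(genes_to_gff3(genes))
        loaded = load_gff3(p)
        assert sorted(loaded, key=lambda g: g.gene_id) == sorted(
            genes, key=lambda g: g.gene_id
        )


class TestGenomeVersion:
    def test_mismatch_is_hard_error(self):
        recs = [_rec(genome_version="V3"), _rec(marker="m2", genome_version="V4")]
        with pytest.raises(GenomeVersionError):
            check_genome_version(recs, "V3")

    def test_match_and_blank_pass(self):
        check_genome_version([_rec(genome_version="V3"), _rec(marker="m2")], "V3")


class TestMapTraitToTerms:
    @pytest.fixture
    def toy(self):
        ont = Ontology(
            [
                OntologyTerm("TO:1", name="stature trait"),
                OntologyTerm("TO:2", name="plant height", parent_ids=frozenset({"TO:1"})),
                OntologyTerm("TO:3", name="grain weight", parent_ids=frozenset({"TO:1"})),
            ]
        )
        d = TraitDictionary({"plant height": {"TO:2"}}, ontology=ont)
        freq = TermFrequencyTable(
            {"plant": 20, "height": 10, "grain": 10, "weight": 10, "stature": 5,
             "trait": 40, "culm": 2}, total=100,
        )
        return ont, d, freq

    def test_curated_hit(self, toy):
        ont, d, freq = toy
        terms, prov = map_trait_to_terms("Plant height", d, ont, freq)
        assert terms == {"TO:2"} and prov == "curated"

    def test_normalization(self, toy):
        ont, d, freq = toy
        assert map_trait_to_terms("plant  Height ", d, ont, freq)[0] == {"TO:2"}

    def test_similarity_fallback_matches_brute_force(self, toy):
        ont, d, freq = toy

        def ic(tok):
            return (freq.information_content(tok) if freq.count(tok) > 0
                    else math.log(freq.total + 1))

        def brute(query_tokens):
            best = (None, -1.0)
            for term in sorted(ont, key=lambda t: t.term_id):
                cand = set(term.name.split())
                denom = sum(ic(t) for t in query_tokens | cand)
                s = sum(ic(t) for t in query_tokens & cand) / denom
                if s > best[1]:
                    best = (term.term_id, s)
            return best

        expect_term, expect_sim = brute({"culm", "height"})
        terms, prov = map_trait_to_terms("culm height", d, ont, freq, threshold=0.4)
        if expect_sim >= 0.4:
            assert terms == {expect_term} and prov == "similarity-suggested"
        else:
            assert terms == frozenset() and prov == "unmapped"

    def test_below_threshold_unmapped(self, toy):
        ont, d, freq = toy
        terms, prov = map_trait_to_terms("flowering time", d, ont, freq, threshold=0.99)
        assert terms == frozenset() and prov == "unmapped"

    def test_dictionary_rejects_unknown_terms(self, toy):
        ont, _, _ = toy
        with pytest.raises(CurationError):
            TraitDictionary({"x": {"TO:99"}}, ontology=ont)


class TestAssignMarkersToGenes:
    GENE = GeneModel("g1", "chr1", 10_000, 12_000)

    def test_marker_inside_window(self):
        links = assign_markers_to_genes([_rec(pos=1000)], [self.GENE], 10)
        assert links == [("g1", _rec(pos=1000))]

    def test_boundaries_closed(self):
        assert assign_markers_to_genes([_rec(pos=22_000)], [self.GENE], 10)
        assert not assign_markers_to_genes([_rec(pos=22_001)], [self.GENE], 10)
        assert assign_markers_to_genes([_rec(pos=1)], [self.GENE], 10)

    def test_one_marker_two_overlapping_genes(self):
        genes = [self.GENE, GeneModel("g2", "chr1", 11_000, 13_000)]
        links = assign_markers_to_genes([_rec(pos=11_500)], genes, 10)
        assert sorted(g for g, _ in links) == ["g1", "g2"]

    def test_chromosome_must_match(self):
        assert not assign_markers_to_genes([_rec(chrom="chr2", pos=11_000)], [self.GENE], 10)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            assign_markers_to_genes([_rec()], [self.GENE], -1)

    def test_agrees_with_exhaustive_pair_scan(self, spec, genes, trait_terms):
        from traitlink.synthetic_data import generate_association_study

        records, _ = generate_association_study(spec, genes, trait_terms)
        for d_kb in (10, 25):
            d = d_kb * 1000
            oracle = sorted(
                (g.gene_id, r.marker_name)
                for r in records
                for g in genes
                if g.chromosome == r.chromosome
                and max(1, g.start - d) <= r.position <= g.end + d
            )
            got = sorted((g, r.marker_name)
                         for g, r in assign_markers_to_genes(records, genes, d_kb))
            assert got == oracle


class TestGeneToTermTable:
    def test_term_fanout(self):
        links = [("g1", _rec())]
        table = build_gene_to_term_table(
            links, {"plant height": frozenset({"TO:1", "TO:2"})}, 10, ld_levels=(10, 25)
        )
        assert len(table.evidence) == 2
        assert table.n_unique_pairs(10) == 2

    def test_cross_study_support_collapses_to_one_pair(self):
        links = [("g1", _rec(study="s1")), ("g1", _rec(marker="m2", study="s2"))]
        table = build_gene_to_term_table(
            links, {"plant height": frozenset({"TO:1"})}, 10, ld_levels=(10, 25)
        )
        assert len(table.evidence) == 2
        assert table.n_unique_pairs(10) == 1

    def test_unconfigured_ld_level_rejected(self):
        with pytest.raises(CurationError):
            build_gene_to_term_table([], {}, 15, ld_levels=(10, 25))

    def test_idempotent_on_own_evidence(self, spec, genes, trait_terms):
        from traitlink.synthetic_data import generate_association_study

        records, _ = generate_association_study(spec, genes, trait_terms)
        kept = filter_significant(records, spec.significance_gate)
        links = assign_markers_to_genes(kept, genes, 10)
        t1 = build_gene_to_term_table(links, trait_terms, 10, ld_levels=(10, 25))
        t2 = GeneToTermTable(t1.evidence.copy(), ld_levels=(10, 25))
        pd.testing.assert_frame_equal(t1.pairs(), t2.pairs())

    def test_shuffled_input_same_dedup_output(self, spec, genes, trait_terms):
        from traitlink.synthetic_data import generate_association_study

        records, _ = generate_association_study(spec, genes, trait_terms)
        kept = filter_significant(records, spec.significance_gate)
        shuffled = kept.copy()
        random.Random(0).shuffle(shuffled)
        t1 = build_gene_to_term_table(
            assign_markers_to_genes(kept, genes, 25), trait_terms, 25, ld_levels=(10, 25))
        t2 = build_gene_to_term_table(
            assign_markers_to_genes(shuffled, genes, 25), trait_terms, 25, ld_levels=(10, 25))
        pd.testing.assert_frame_equal(t1.pairs(25), t2.pairs(25))

    def test_tsv_round_trip(self, tmp_path):
        links = [("g1", _rec())]
        table = build_gene_to_term_table(
            links, {"plant height": frozenset({"TO:1"})}, 10, ld_levels=(10, 25))
        p = tmp_path / "t.tsv"
        table.to_tsv(p)
        back = GeneToTermTable.from_tsv(p, ld_levels=(10, 25))
        pd.testing.assert_frame_equal(table.pairs(), back.pairs())


class TestLdMonotonicity:
    def test_counts_non_decreasing_in_ld(self, spec, genes, trait_terms):
        from traitlink.synthetic_data import generate_association_study

        records, _ = generate_association_study(spec, genes, trait_terms)
        kept = filter_significant(records, spec.significance_gate)
        counts = []
        for d in (10, 25, 50):
            links = assign_markers_to_genes(kept, genes, d)
            t = build_gene_to_term_table(links, trait_terms, d, ld_levels=(10, 25, 50))
            counts.append((t.n_unique_genes(d), t.n_unique_pairs(d)))
        for (g1, p1), (g2, p2) in zip(counts, counts[1:]):
            assert g1 <= g2 and p1 <= p2


class TestTopFractionFilter:
    def _study(self, n, study="s1", seed=0):
        rnd = random.Random(seed)
        return [
            _rec(marker=f"m{i}", p=rnd.uniform(1e-8, 1), study=study) for i in range(n)
        ]

    def test_keeps_ceil_fraction(self):
        recs = self._study(20)
        kept = top_fraction_filter(recs, 0.1)
        assert len(kept) == 2
        assert {r.p_value for r in kept} == set(sorted(r.p_value for r in recs)[:2])

    def test_ties_at_cutoff_all_retained(self):
        recs = [_rec(marker=f"m{i}", p=0.5) for i in range(3)] + [_rec(marker="m4", p=0.9)]
        kept = top_fraction_filter(recs, 0.25)  # ceil(1) = 1 but 3-way tie
        assert len(kept) == 3

    def test_per_study_enumeration(self):
        recs = self._study(10, "s1", seed=1) + self._study(10, "s2", seed=2)
        kept = top_fraction_filter(recs, 0.1, per_study=True)
        by_study = {}
        for r in kept:
            by_study.setdefault(r.study_id, []).append(r)
        for sid in ("s1", "s2"):
            pool = [r for r in recs if r.study_id == sid]
            assert [r.p_value for r in by_study[sid]] == [min(r.p_value for r in pool)]

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            top_fraction_filter([_rec()], 0.0)
        with pytest.raises(ValueError):
            top_fraction_filter([_rec()], 1.1)


class TestQueryGenesByTrait:
    @pytest.fixture
    def setup(self):
        ont = Ontology(
            [
                OntologyTerm("TO:p"),
                OntologyTerm("TO:c1", parent_ids=frozenset({"TO:p"})),
                OntologyTerm("TO:c2", parent_ids=frozenset({"TO:p"})),
                OntologyTerm("TO:gc", parent_ids=frozenset({"TO:c1", "TO:c2"})),
            ]
        )
        ev = pd.DataFrame(
            [
                ("g1", "TO:c1", 10.0, "s1", "m1", 1e-6),
                ("g2", "TO:c1", 10.0, "s1", "m2", 1e-6),
                ("g3", "TO:gc", 10.0, "s1", "m3", 1e-6),
                ("g1", "TO:gc", 10.0, "s2", "m4", 1e-6),
            ],
            columns=["gene_id", "term_id", "ld_level_kb", "study_id", "marker_name", "p_value"],
        )
        return ont, GeneToTermTable(ev, ld_levels=(10,))

    def test_direct_only(self, setup):
        ont, table = setup
        assert query_genes_by_trait(table, "TO:c1", ont) == {"g1", "g2"}

    def test_descendants_pulled_in(self, setup):
        ont, table = setup
        assert query_genes_by_trait(table, "TO:c2", ont, descendants=True) == {"g1", "g3"}

    def test_diamond_descendant_counts_gene_once(self, setup):
        ont, table = setup
        genes = query_genes_by_trait(table, "TO:p", ont, descendants=True)
        assert genes == {"g1", "g2", "g3"}

    def test_unknown_term(self, setup):
        ont, table = setup
        with pytest.raises(UnknownTermError):
            query_genes_by_trait(table, "TO:zzz", ont)
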