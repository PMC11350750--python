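"""Criterion classification from variant evidence."""

import logging

import pytest
from hypothesis import given, strategies as st

from equiprio.annotation import (
    CriterionFlags,
    VariantAnnotation,
    annotate,
    build_annotation_index,
    classify_protein_effect,
    compute_flags,
    constrained_flag,
    gerp_flag,
    normalize_consequence,
    regulatory_flag,
)
from equiprio.core import ConflictingAnnotationError, GenomicInterval
from equiprio.markers import MarkerLocus


def cons(*terms, canonical_first=True):
    return tuple(
        (f"tx{i}", t, canonical_first and i == 0) for i, t in enumerate(terms)
    )


class TestProteinEffect:
    @pytest.mark.parametrize(
        "term, expected",
        [
            ("missense variant", True),
            ("missense_variant", True),
            ("stop-lost", True),
            ("stop lost", True),
            ("splice donor region variant", True),
            ("frameshift variant", True),
            ("intronic variant", False),
            ("intron_variant", False),
            ("3 prime UTR variant", False),
            ("3_prime_UTR_variant", False),
            ("5 prime UTR variant", False),
            ("upstream gene variant", False),
            ("synonymous variant", False),
        ],
    )
    def test_term_classification(self, term, expected):
        assert classify_protein_effect(cons(term)) is expected

    def test_any_transcript_counts_not_only_canonical(self):
        # missense on the canonical plus UTR elsewhere -> protein effect;
        # and missense only on a NON-canonical transcript still counts
        assert classify_protein_effect(cons("missense variant", "5 prime UTR variant"))
        assert classify_protein_effect(cons("5 prime UTR variant", "missense variant"))

    def test_unknown_term_warns_and_is_benign(self, caplog):
        with caplog.at_level(logging.WARNING, logger="equiprio"):
            assert not classify_protein_effect(cons("mystery effect"))
        assert "mystery effect" in caplog.text

    def test_normalization_round_trips_display_and_vep_spellings(self):
        assert normalize_consequence("3 prime UTR variant") == normalize_consequence(
            "3_prime_UTR_variant"
        )
        assert normalize_consequence("stop-lost") == "stop_lost"


class TestGerpFlag:
    @pytest.mark.parametrize(
        "score, expected",
        [(4.15, True), (0.72, False), (2.0, False), (2.0000001, True), (None, False)],
    )
    def test_strict_threshold(self, score, expected):
        assert gerp_flag(score) is expected

    def test_missing_distinct_from_zero(self):
        assert gerp_flag(0.0, threshold=-1.0) is True
        assert gerp_flag(None, threshold=-1.0) is False

    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(0, 5))
    def test_monotone_in_score(self, s1, s2, thr):
        lo, hi = sorted((s1, s2))
        assert not (gerp_flag(lo, thr) and not gerp_flag(hi, thr))


class TestConstrainedFlag:
    ELEMENTS = [GenomicInterval("1", 100, 200)]

    @pytest.mark.parametrize(
        "chrom, pos, expected",
        [("1", 150, True), ("1", 100, True), ("1", 200, True), ("1", 99, False),
         ("1", 201, False), ("2", 150, False)],
    )
    def test_closed_boundaries(self, chrom, pos, expected):
        assert constrained_flag(chrom, pos, self.ELEMENTS) is expected

    def test_empty_element_set(self):
        assert not constrained_flag("1", 150, [])


class TestRegulatoryFlag:
    @pytest.mark.parametrize(
        "ftype, expected",
        [("enhancer", True), ("promoter", True), ("open_chromatin", True),
         ("none", False), ("ctcf_binding_site", False), ("tf_binding_site", False)],
    )
    def test_qualifying_types(self, ftype, expected):
        ann = VariantAnnotation("rs1", "1", 50, regulatory_feature=ftype)
        assert regulatory_flag(ann) is expected


class TestAnnotate:
    def test_published_table_flags_recomputed_exactly(self, published):
        """Flags recomputed from raw evidence equal the transcribed
        checkmarks on all 28 rows."""
        rows = annotate(published["loci"], published["annotations"], published["constrained"])
        got = {(r.gene_id, r.probe_name, r.snp_id): r.flags.as_tuple() for r in rows}
        df = published["rows"]
        assert len(rows) == len(df) == 28
        for _, r in df.iterrows():
            key = (r.gene_symbol, r.probe_name, r.snp_id)
            assert got[key] == (
                r.protein_effect, r.gerp_gt2, r.constrained, r.regulatory
            ), f"flag mismatch for {key}"

    def test_unannotated_locus_gets_all_false_flags(self):
        locus = MarkerLocus("9", 123, probe_names=("pX",), gene_ids=("g",))
        (row,) = annotate([locus], {}, [])
        assert row.flags == CriterionFlags()
        assert row.snp_id == "9_123"

    def test_conflicting_snp_ids_at_one_position_raise(self):
        vep = {
            "rs1": {"location": ("1", 100), "consequences": [("t", "intron_variant", True)]},
            "rs2": {"location": ("1", 100), "consequences": [("t", "intron_variant", True)]},
        }
        with pytest.raises(ConflictingAnnotationError):
            build_annotation_index(vep, {}, [])

    def test_reannotation_idempotent_and_order_independent(self, published):
        rows1 = annotate(published["loci"], published["annotations"], published["constrained"])
        rows2 = annotate(published["loci"][::-1], published["annotations"], published["constrained"])
        assert set(rows1) == set(rows2)
        assert annotate(published["loci"], published["annotations"], published["constrained"]) == rows1

    def test_flags_recovered_on_synthetic_tracks(self, scenario):
        """Brute-force rescan of the emitted tracks equals the planted
        criterion memberships."""
        from equiprio.io import (
            read_bed,
            read_gene_table,
            read_gerp_table,
            read_manifest,
            read_regulatory_bed,
            read_vep_table,
        )
        from equiprio.markers import extract_candidate_loci

        paths, truth = scenario
        genes = read_gene_table(paths["target_genes.tsv"])
        candidates = [g for g in genes if g.gene_id in truth.ortholog_target_genes]
        loci = extract_candidate_loci(read_manifest(paths["manifest.csv"]), candidates)
        index = build_annotation_index(
            read_vep_table(paths["vep.tsv"]),
            read_gerp_table(paths["gerp.tsv"]),
            read_regulatory_bed(paths["regulatory.bed"]),
        )
        constrained = read_bed(paths["constrained.bed"])
        rows = annotate(loci, index, constrained)
        got = {"protein_effect": set(), "gerp_gt2": set(), "constrained": set(), "regulatory": set()}
        for r in rows:
            for crit in got:
                if getattr(r.flags, crit):
                    got[crit].add(r.snp_id)
        assert got == truth.criterion_snps
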