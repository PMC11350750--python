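"""Breed genotype contrast and ortholog similarity validation."""

from functools import lru_cache

import pytest
from hypothesis import given, settings, strategies as st

from equiprio.core import InputError, OrthologPair
from equiprio.validate import (
    allele_sets_differ,
    contrast_breeds,
    genotypes_differ,
    global_percent_identity,
    similarity_gate,
)
from equiprio.annotation import annotate
from equiprio.prioritize import prioritize


def identity_oracle(a: str, b: str, match=1, mismatch=0, gap=-1) -> float:
    """Independent oracle: enumerate every achievable (score, matches,
    columns) triple of a global alignment by exhaustive recursion, then
    apply the statistic's selection rule (max score, then max matches,
    then min columns)."""

    @lru_cache(maxsize=None)
    def achievable(i: int, j: int) -> frozenset:
        if i == len(a) and j == len(b):
            return frozenset({(0, 0, 0)})
        out = set()
        if i < len(a):
            out.update((s + gap, m, c + 1) for s, m, c in achievable(i + 1, j))
        if j < len(b):
            out.update((s + gap, m, c + 1) for s, m, c in achievable(i, j + 1))
        if i < len(a) and j < len(b):
            eq = a[i] == b[j]
            w = match if eq else mismatch
            out.update(
                (s + w, m + int(eq), c + 1) for s, m, c in achievable(i + 1, j + 1)
            )
        return frozenset(out)

    triples = achievable(0, 0)
    best_score = max(s for s, _, _ in triples)
    at_best = [(m, c) for s, m, c in triples if s == best_score]
    best_m = max(m for m, _ in at_best)
    best_c = min(c for m, c in at_best if m == best_m)
    return 100.0 * best_m / best_c


class TestGenotypesDiffer:
    @pytest.mark.parametrize(
        "g1, g2, expected",
        [
            (("G", "A"), ("A", "A"), True),  # het vs hom differs
            (("A", "G"), ("G", "A"), False),  # unordered
            (("A", "A"), ("A", "A"), False),
            (("C", "C"), ("T", "T"), True),  # opposite homozygotes
            (("A", "A"), ("A", "G"), True),
        ],
    )
    def test_multiset_comparison(self, g1, g2, expected):
        assert genotypes_differ(g1, g2) is expected
        assert genotypes_differ(g2, g1) is expected  # symmetric

    def test_missing_genotype_rejected(self):
        with pytest.raises(InputError):
            genotypes_differ(None, ("A", "A"))

    def test_allele_set_rule_requires_disjoint_sets(self):
        assert allele_sets_differ([("A", "A"), ("A", "A")], [("G", "G")])
        assert not allele_sets_differ([("A", "G")], [("G", "G")])


class TestContrastBreeds:
    PRINTED_PAIRS = [
        # the seven genotype pairs published for the large-vs-small contrast
        "rs68603064", "rs68454110", "rs68514854", "rs68875002",
        "rs69126368", "rs68555658", "rs68520444",
    ]

    def _calls(self, published):
        rows = annotate(published["loci"], published["annotations"], published["constrained"])
        return prioritize(rows, published["phenotype_genes"])

    def test_published_pairs_all_classified_as_differing(self, published):
        calls = self._calls(published)
        results, strong = contrast_breeds(calls, published["genotypes"], "P", "AM")
        by_snp = {r.snp_id: r for r in results}
        for snp in self.PRINTED_PAIRS:
            assert by_snp[snp].differs, snp

    def test_strong_candidate_count_ten_snps_ten_genes(self, published):
        calls = self._calls(published)
        _, strong = contrast_breeds(calls, published["genotypes"], "P", "AM")
        assert len(strong["snp_ids"]) == 10
        assert len(strong["genes"]) == 10

    def test_symmetric_in_breed_order(self, published):
        calls = self._calls(published)
        _, s1 = contrast_breeds(calls, published["genotypes"], "P", "AM")
        _, s2 = contrast_breeds(calls, published["genotypes"], "AM", "P")
        assert s1 == s2

    def test_strong_set_subset_of_prioritized(self, published):
        calls = self._calls(published)
        _, strong = contrast_breeds(calls, published["genotypes"], "P", "AM")
        prioritized_snps = {c.snp_id for c in calls if c.prioritized}
        assert strong["snp_ids"] <= prioritized_snps

    def test_missing_snp_reported_non_evaluable(self, published, caplog):
        import logging

        calls = self._calls(published)
        genotypes = {k: v for k, v in published["genotypes"].items() if k[0] != "rs68603064"}
        with caplog.at_level(logging.INFO, logger="equiprio"):
            results, strong = contrast_breeds(calls, genotypes, "P", "AM")
        r = {x.snp_id: x for x in results}["rs68603064"]
        assert not r.evaluable and not r.differs
        assert "rs68603064" not in strong["snp_ids"]

    def test_identical_homozygotes_excluded_from_strong_set(self, published):
        calls = self._calls(published)
        _, strong = contrast_breeds(calls, published["genotypes"], "P", "AM")
        assert "rs396701927" not in strong["snp_ids"]


class TestGlobalPercentIdentity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACDE", "ACDE", 100.0),
            ("ACDE", "ACDF", 75.0),  # ungapped optimal: 3 identities / 4 cols
            ("A", "G", 0.0),  # single mismatching column beats two gaps
        ],
    )
    def test_reference_values(self, a, b, expected):
        assert global_percent_identity(a, b) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            global_percent_identity("", "ACD")

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=8),
        st.text(alphabet="ACGT", min_size=1, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_exhaustive_oracle(self, a, b):
        assert global_percent_identity(a, b) == pytest.approx(identity_oracle(a, b))

    @given(
        st.text(alphabet="ACDEFG", min_size=1, max_size=10),
        st.text(alphabet="ACDEFG", min_size=1, max_size=10),
    )
    @settings(max_examples=80, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        v = global_percent_identity(a, b)
        assert 0.0 <= v <= 100.0
        assert v == pytest.approx(global_percent_identity(b, a))
        if a == b:
            assert v == pytest.approx(100.0)


class TestSimilarityGate:
    def test_threshold_inclusive(self):
        pairs = [
            OrthologPair("s1", "t1", 90.0, 94.5),
            OrthologPair("s2", "t2", 55.0, 59.9),
            OrthologPair("s3", "t3", 58.0, 60.0),
        ]
        gates = similarity_gate(pairs)
        assert gates["t1"].passed and gates["t1"].provenance == "table"
        assert gates["t2"].passed is False
        assert gates["t3"].passed  # exactly 60.0 passes

    def test_computed_fallback_from_sequences(self):
        pairs = [OrthologPair("s1", "t1")]
        gates = similarity_gate(pairs, sequences={"s1": "ACDE", "t1": "ACDF"})
        assert gates["t1"].provenance == "computed"
        assert gates["t1"].value == pytest.approx(75.0)
        assert gates["t1"].passed

    def test_non_evaluable_without_value_or_sequences(self):
        gates = similarity_gate([OrthologPair("s1", "t1")])
        assert gates["t1"].passed is None and gates["t1"].provenance == "none"
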