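"""Variant retention rules, alteration frequencies, co-mutation, concordance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyromics.landscape import (
    FilterParams,
    alteration_frequency,
    cooccurrence,
    filter_variants,
    platform_concordance,
    split_somatic_germline,
    tmb_records,
)

from conftest import make_variant


class TestFilter:
    def test_common_missense_dropped_despite_predictions(self):
        v = make_variant(effect="missense", popmax_af=0.005,
                         polyphen_call="deleterious", sift_call="deleterious")
        assert filter_variants([v]) == []

    def test_lof_retained_unconditionally(self):
        v = make_variant(effect="frameshift", popmax_af=None)
        assert filter_variants([v]) == [v]

    def test_either_predictor_suffices(self):
        v = make_variant(effect="missense", popmax_af=0.0,
                         polyphen_call="benign", sift_call="deleterious")
        assert filter_variants([v]) == [v]

    def test_missense_without_deleterious_call_dropped(self):
        v = make_variant(effect="missense", popmax_af=0.0)
        assert filter_variants([v]) == []

    def test_synonymous_always_dropped(self):
        v = make_variant(effect="synonymous", popmax_af=0.0)
        assert filter_variants([v]) == []

    def test_promoter_kept_only_for_telomere_genes(self):
        tert = make_variant(effect="promoter", gene="TERT", ref="G", alt="A")
        other = make_variant(effect="promoter", gene="TP53", ref="G", alt="A")
        assert filter_variants([tert, other]) == [tert]

    def test_boundary_af_is_exclusive(self):
        at = make_variant(effect="frameshift", popmax_af=0.001)
        below = make_variant(effect="frameshift", popmax_af=0.0009999)
        assert filter_variants([at, below]) == [below]

    @given(
        st.lists(
            st.builds(
                make_variant,
                effect=st.sampled_from(
                    ["missense", "nonsense", "splice", "frameshift",
                     "synonymous", "promoter"]
                ),
                popmax_af=st.one_of(st.none(), st.floats(0, 0.01)),
                polyphen_call=st.sampled_from(["deleterious", "benign", "missing"]),
                sift_call=st.sampled_from(["deleterious", "benign", "missing"]),
            ),
            max_size=30,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_idempotent_and_subset(self, records):
        once = filter_variants(records)
        assert all(r in records for r in once)
        assert filter_variants(once) == once


class TestSomaticSplit:
    def test_wgs_somatic_confirms_gene(self):
        wgs = make_variant(gene="TP53", somatic_status="somatic", platform="WGS")
        targeted = [
            make_variant(gene="TP53", somatic_status="unknown",
                         platform="targeted", sample=f"t{i}")
            for i in range(5)
        ]
        confirmed, suspect = split_somatic_germline([wgs, *targeted])
        assert confirmed == {"TP53"} and suspect == set()

    def test_targeted_only_gene_is_suspect(self):
        v = make_variant(gene="ATM", somatic_status="unknown", platform="targeted")
        confirmed, suspect = split_somatic_germline([v])
        assert confirmed == set() and suspect == {"ATM"}

    def test_empty(self):
        assert split_somatic_germline([]) == (set(), set())


class TestFrequencies:
    def test_absent_gene_frequency_zero(self, oncoprint_fixture):
        assert alteration_frequency(oncoprint_fixture, "BRAF", "ATC") == 0.0

    def test_unknown_gene_errors(self, oncoprint_fixture):
        with pytest.raises(ValueError, match="unknown gene"):
            alteration_frequency(oncoprint_fixture, "NOTAGENE", "ATC")

    def test_empty_stratum_errors(self, oncoprint_fixture):
        with pytest.raises(ValueError, match="histology"):
            alteration_frequency(oncoprint_fixture, "TERT", "PDTC")

    def test_sample_order_invariance(self, oncoprint_fixture):
        m = oncoprint_fixture
        f1 = alteration_frequency(m, "TERT", "ATC")
        m.samples = list(reversed(m.samples))
        assert alteration_frequency(m, "TERT", "ATC") == f1
        assert 0.0 <= f1 <= 100.0


def _fisher_two_sided_enumeration(table):
    """Brute-force two-sided Fisher: sum hypergeometric probabilities of all
    tables with the observed margins whose probability <= the observed one."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestCooccurrence:
    def _matrix(self, pattern):
        from thyromics.landscape import AlterationMatrix

        n = len(pattern)
        samples = [f"s{i}" for i in range(n)]
        hist = {s: "ATC" for s in samples}
        m = AlterationMatrix(samples, hist, ["A1", "B1"])
        for s, (in_a, in_b) in zip(samples, pattern):
            if in_a:
                m.add(s, "A1", "missense")
            if in_b:
                m.add(s, "B1", "missense")
        return m

    def test_perfect_exclusivity_odds_zero(self):
        pattern = [(1, 0)] * 3 + [(0, 1)] * 4
        m = self._matrix(pattern)
        table, odds, _ = cooccurrence(m, ["A1"], ["B1"], "ATC")
        assert odds == 0.0
        assert table[0, 0] == 0 and table[1, 1] == 0

    def test_p_matches_enumeration_oracle(self):
        pattern = (
            [(1, 1)] * 2 + [(1, 0)] * 3 + [(0, 1)] * 4 + [(0, 0)] * 5
        )
        m = self._matrix(pattern)
        table, _, p = cooccurrence(m, ["A1"], ["B1"], "ATC")
        assert np.allclose(table, [[2, 3], [4, 5]])
        assert p == pytest.approx(_fisher_two_sided_enumeration(table), rel=1e-9)

    def test_overlapping_sets_rejected(self):
        m = self._matrix([(1, 0)] * 4)
        with pytest.raises(ValueError, match="overlap"):
            cooccurrence(m, ["A1"], ["A1"], "ATC")

    def test_empty_stratum_rejected(self):
        m = self._matrix([(1, 0)] * 4)
        with pytest.raises(ValueError, match="histology"):
            cooccurrence(m, ["A1"], ["B1"], "wiFTC")


class TestConcordance:
    def _calls(self, n, sample="s1", start=1000):
        return [
            make_variant(pos=start + i, sample=sample, ref="C", alt="T")
            for i in range(n)
        ]

    def test_identical_sets_100(self):
        calls = self._calls(10)
        assert platform_concordance(calls, list(calls)) == 100.0

    def test_region_excludes_calls_from_denominator(self):
        inside = self._calls(5, start=1000)
        outside = self._calls(3, start=90_000)
        region = [("1", 0, 10_000)]
        assert platform_concordance(inside + outside, inside, region) == 100.0

    def test_symmetric_under_union_denominator(self):
        a = self._calls(30)
        b = self._calls(28, start=1002)  # 28 shared with a
        assert platform_concordance(a, b) == platform_concordance(b, a)

    def test_no_shared_samples_errors(self):
        with pytest.raises(ValueError, match="shared samples"):
            platform_concordance(self._calls(2, "s1"), self._calls(2, "s2"))


def test_tmb_definition():
    retained = [
        make_variant(sample="s1", pos=i + 1, effect="missense") for i in range(30)
    ]
    (rec,) = tmb_records(retained, target_size_mb=1.5)
    assert rec.tmb == pytest.approx(20.0)
    with pytest.raises(ValueError):
        tmb_records(retained, target_size_mb=0)
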