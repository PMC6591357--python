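"""TDS/ERK centered scores, ssGSEA against a brute-force oracle, BRS signs."""

import numpy as np
import pandas as pd
import pytest

from thyromics.scores import (
    GeneSignature,
    brs,
    centered_set_score,
    load_signature,
    registry,
    ssgsea,
    write_signature,
)


def ssgsea_oracle(values: dict[str, float], gene_set: set[str], alpha: float) -> float:
    """Independent step-by-step running-sum computation (pure python)."""
    ordered = sorted(values, key=lambda g: -values[g])  # stable on input order
    n = len(ordered)
    n_out = n - len([g for g in ordered if g in gene_set])
    denom = sum(
        (n - i) ** alpha for i, g in enumerate(ordered) if g in gene_set
    )
    ecdf_in = ecdf_out = 0.0
    score = 0.0
    for i, g in enumerate(ordered):
        if g in gene_set:
            ecdf_in += (n - i) ** alpha / denom
        else:
            ecdf_out += 1.0 / n_out
        score += ecdf_in - ecdf_out
    return score


class TestCenteredScore:
    def test_sample_at_cohort_median_scores_zero(self):
        m = pd.DataFrame({"s1": [1.0, 10.0], "s2": [2.0, 20.0], "s3": [3.0, 30.0]},
                         index=["g1", "g2"])
        sig = GeneSignature("t", ("g1", "g2"))
        scores = centered_set_score(m, sig)
        # medians 2 and 20; hand-computed means of centered columns
        assert scores["s2"] == pytest.approx(0.0)
        assert scores["s1"] == pytest.approx(-5.5)
        assert scores["s3"] == pytest.approx(5.5)

    def test_antisymmetry_under_negation(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (4, 5))
        vals = np.concatenate([vals, -vals], axis=1)  # symmetric: medians 0
        m = pd.DataFrame(vals, index=[f"g{i}" for i in range(4)],
                         columns=[f"s{i}" for i in range(10)])
        sig = GeneSignature("t", tuple(m.index))
        scores = centered_set_score(m, sig)
        flipped = centered_set_score(-m, sig)
        assert np.allclose(flipped.to_numpy(), -scores.to_numpy())

    def test_missing_genes_skipped_with_warning(self, toy_expression):
        sig = GeneSignature("t", ("g0", "g1", "NOT_PRESENT"))
        with pytest.warns(UserWarning, match="absent"):
            scores = centered_set_score(toy_expression, sig)
        assert len(scores) == toy_expression.shape[1]

    def test_no_gene_present_errors(self, toy_expression):
        with pytest.raises(ValueError, match="no gene"):
            centered_set_score(toy_expression, GeneSignature("t", ("nope",)))


class TestSsgsea:
    def test_top_ranked_set_is_positive_and_maximal(self):
        genes = [f"g{i}" for i in range(10)]
        base = np.arange(10, 0, -1, dtype=float)
        scores = {}
        for placement in range(9):  # set occupies ranks (placement, placement+1)
            m = pd.DataFrame({"s": base}, index=genes)
            gene_set = [genes[placement], genes[placement + 1]]
            scores[placement] = ssgsea(m, gene_set)["s"]
        assert scores[0] > 0
        assert scores[0] == max(scores.values())

    def test_matches_oracle_on_toy_matrix(self):
        m = pd.DataFrame(
            {"s1": [5.0, 3.0, 4.0, 1.0, 2.0], "s2": [1.0, 2.0, 3.0, 4.0, 5.0]},
            index=["a", "b", "c", "d", "e"],
        )
        result = ssgsea(m, ["a", "c"], weight_exponent=0.25)
        for s in m.columns:
            expected = ssgsea_oracle(m[s].to_dict(), {"a", "c"}, 0.25)
            assert result[s] == pytest.approx(expected, abs=1e-12)

    def test_reversed_ranking_swaps_complementary_set_order(self):
        genes = [f"g{i}" for i in range(6)]
        vals = np.array([6.0, 5, 4, 3, 2, 1])
        m = pd.DataFrame({"s": vals}, index=genes)
        m_rev = pd.DataFrame({"s": vals[::-1]}, index=genes)
        top, bottom = genes[:3], genes[3:]
        assert ssgsea(m, top)["s"] > ssgsea(m, bottom)["s"]
        assert ssgsea(m_rev, top)["s"] < ssgsea(m_rev, bottom)["s"]

    def test_property_500_random_instances_match_oracle(self):
        """ssGSEA equals the brute-force ECDF oracle to 1e-9 on random
        6-gene instances."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(6)]
        for _ in range(500):
            vals = rng.normal(0, 1, 6)
            k = int(rng.integers(1, 6))
            gene_set = list(rng.choice(genes, size=k, replace=False))
            m = pd.DataFrame({"s": vals}, index=genes)
            got = ssgsea(m, gene_set)["s"]
            want = ssgsea_oracle(dict(zip(genes, vals)), set(gene_set), 0.25)
            assert abs(got - want) <= 1e-9

    def test_constant_sample_errors(self):
        m = pd.DataFrame({"s": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="all-constant"):
            ssgsea(m, ["a"])

    def test_empty_overlap_errors(self, toy_expression):
        with pytest.raises(ValueError, match="no overlap"):
            ssgsea(toy_expression, ["absent_gene"])


class TestBrs:
    def _signature(self):
        braf = [f"b{i}" for i in range(5)]
        ras = [f"r{i}" for i in range(5)]
        labels = {**{g: "BRAF-like" for g in braf}, **{g: "RAS-like" for g in ras}}
        return GeneSignature("brs", tuple(braf + ras), class_labels=labels), braf, ras

    def _matrix(self, braf, ras, braf_high, seed=0):
        rng = np.random.default_rng(seed)
        genes = braf + ras + [f"o{i}" for i in range(20)]
        base = rng.normal(5, 0.1, (len(genes), 3))
        m = pd.DataFrame(base, index=genes, columns=["x", "y", "z"])
        boost = braf if braf_high else ras
        m.loc[boost] += 3.0
        return m

    def test_braf_overexpression_negative(self):
        sig, braf, ras = self._signature()
        m = self._matrix(braf, ras, braf_high=True)
        assert (brs(m, sig) < 0).all()

    def test_ras_overexpression_positive(self):
        sig, braf, ras = self._signature()
        m = self._matrix(braf, ras, braf_high=False)
        assert (brs(m, sig) > 0).all()

    def test_symmetric_expression_near_zero(self):
        sig, braf, ras = self._signature()
        m = self._matrix(braf, ras, braf_high=True)
        ras_high = self._matrix(braf, ras, braf_high=False)
        m["ras_sample"] = ras_high["x"]
        # symmetric sample: the two sub-signatures perfectly interleave
        sym = np.zeros(len(m))
        for i in range(5):
            sym[i] = 10.0 - 2 * i          # BRAF-like genes
            sym[5 + i] = 9.9 - 2 * i       # RAS-like genes, interleaved
        m["sym_sample"] = sym
        result = brs(m, sig)
        assert result["x"] < 0 < result["ras_sample"]
        assert abs(result["sym_sample"]) <= 0.2

    def test_missing_labels_error(self, toy_expression):
        sig = GeneSignature("nolabel", ("g1", "g2"))
        with pytest.raises(ValueError, match="class labels"):
            brs(toy_expression, sig)


class TestRegistryAndFiles:
    def test_registry_sizes(self):
        reg = registry()
        assert len(reg["TDS"].genes) == 16
        assert len(reg["ERK"].genes) == 52
        assert len(reg["BRS"].genes) == 71
        labels = reg["BRS"].class_labels
        assert set(labels.values()) == {"BRAF-like", "RAS-like"}

    def test_signature_file_round_trip(self, tmp_path):
        sig = GeneSignature(
            "x", ("a", "b"), class_labels={"a": "BRAF-like", "b": "RAS-like"}
        )
        path = tmp_path / "x.tsv"
        write_signature(sig, path)
        back = load_signature(path, name="x")
        assert back.genes == sig.genes and back.class_labels == sig.class_labels
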