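"""Generator contracts: determinism, calibration, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from thyromics.io import write_alignments
from thyromics.methylation import call_sample, scan_ccgg
from thyromics.synthetic import (
    CohortSpec,
    DigestSpec,
    ExpressionSpec,
    calibrate_baseline_hazard,
    generate_cohort,
    generate_expression,
    generate_hpaii_reads,
    generate_peaks,
)


class TestCohort:
    def test_degenerate_prevalence_all_altered(self):
        spec = CohortSpec(
            n_per_histology={"wiFTC": 12},
            alteration_prevalence={("wiFTC", "TERT"): 1.0},
            seed=0,
        )
        matrix, _ = generate_cohort(spec)
        assert all(matrix.has_alteration(s, "TERT") for s in matrix.samples)
        assert len(matrix.samples) == 12

    def test_determinism_byte_identical(self, tmp_path):
        spec = CohortSpec(seed=42)
        out = []
        for run in range(2):
            matrix, clinical = generate_cohort(spec)
            p1, p2 = tmp_path / f"m{run}.tsv", tmp_path / f"c{run}.tsv"
            matrix.write(p1)
            clinical.to_csv(p2, sep="\t")
            out.append((p1.read_bytes(), p2.read_bytes()))
        assert out[0] == out[1]

    def test_validation(self):
        with pytest.raises(ValueError, match="negative"):
            CohortSpec(n_per_histology={"ATC": -1})
        with pytest.raises(ValueError, match="prevalence"):
            CohortSpec(alteration_prevalence={("ATC", "X"): 1.5})
        with pytest.raises(ValueError, match="hazard_ratio"):
            CohortSpec(hazard_ratio_cdkn2a=0.0)

    def test_marginal_calibration_within_3_se(self):
        p = 0.3
        n = 1000
        spec = CohortSpec(
            n_per_histology={"ATC": n},
            alteration_prevalence={("ATC", "TP53"): p},
            seed=7,
        )
        matrix, _ = generate_cohort(spec)
        freq = np.mean([matrix.has_alteration(s, "TP53") for s in matrix.samples])
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) <= 3 * se

    def test_hazard_calibration_mixture_median(self):
        lam = calibrate_baseline_hazard(6.9, 0.2222, 6.67)
        q, h, M = 0.2222, 6.67, 6.9
        mix_surv = q * np.exp(-h * lam * M) + (1 - q) * np.exp(-lam * M)
        assert mix_surv == pytest.approx(0.5, abs=1e-10)

    def test_cox_recovers_generating_hr(self):
        spec = CohortSpec(
            n_per_histology={"ATC": 1000},
            alteration_prevalence={("ATC", "CDKN2A"): 0.5},
            hazard_ratio_cdkn2a=6.67,
            seed=3,
        )
        _, clinical = generate_cohort(spec)
        from thyromics.outcome import cox_ph

        clinical["cdkn2a_del"] = (clinical["cdkn2a_status"] == "del").astype(int)
        fit = cox_ph(clinical, "cdkn2a_del")
        assert fit["ci_low"] <= 6.67 <= fit["ci_high"]


class TestExpression:
    def test_zero_noise_identical_marker_values(self):
        spec = ExpressionSpec(noise_sd=0.0, n_per_subtype=3, n_genes=300, seed=0)
        matrix, truth, markers = generate_expression(spec)
        for sub in spec.subtypes:
            cols = truth.index[truth == sub]
            sub_m = matrix.loc[markers[sub], cols]
            assert (sub_m.nunique(axis=1) == 1).all()

    def test_one_sample_per_subtype_distinct_rows(self):
        spec = ExpressionSpec(n_per_subtype=1, n_genes=300, seed=1)
        matrix, truth, _ = generate_expression(spec)
        assert matrix.shape[1] == 4
        assert matrix.T.drop_duplicates().shape[0] == 4

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="marker genes"):
            ExpressionSpec(n_genes=100, n_markers_per_subtype=50)

    def test_determinism(self):
        a, _, _ = generate_expression(ExpressionSpec(seed=9))
        b, _, _ = generate_expression(ExpressionSpec(seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestHpaiiReads:
    def _sites(self, k=10, start=2000, step=1500):
        return [start + i * step for i in range(k)]

    def test_fully_methylated_no_cut_boundaries(self):
        sites = self._sites()
        spec = DigestSpec(
            ccgg_positions=sites,
            methylation_truth={p: 1.0 for p in sites},
            depth=40,
            low_mapq_fraction=0.0,
            seed=0,
        )
        sim = generate_hpaii_reads(spec)
        frags = sim.reads.fragments()
        cuts = {p + 1 for p in sites}
        assert not any(s in cuts or e in cuts
                       for s, e in zip(frags["start"], frags["end"]))

    def test_fully_unmethylated_levels_near_zero(self):
        sites = self._sites()
        spec = DigestSpec(
            ccgg_positions=sites,
            methylation_truth={p: 0.0 for p in sites},
            depth=100,
            low_mapq_fraction=0.0,
            seed=1,
        )
        sim = generate_hpaii_reads(spec)
        calls = call_sample(sim.reads, [(spec.chrom, p) for p in sites])
        assert all(c.level == 0.0 for c in calls)

    def test_intermediate_level_recovered_binomial_bound(self):
        sites = [5000]
        spec = DigestSpec(
            ccgg_positions=sites,
            methylation_truth={5000: 0.7},
            depth=200,
            low_mapq_fraction=0.0,
            seed=2,
        )
        sim = generate_hpaii_reads(spec)
        (call,) = call_sample(sim.reads, [(spec.chrom, 5000)])
        assert call.level == pytest.approx(0.7, abs=0.1)

    def test_sequence_contains_motifs_exactly_at_sites(self):
        sites = self._sites(5)
        spec = DigestSpec(ccgg_positions=sites, seed=3)
        sim = generate_hpaii_reads(spec)
        assert scan_ccgg(sim.sequence) == sites

    def test_read_length_validation(self):
        with pytest.raises(ValueError, match="read_length"):
            DigestSpec(read_length=400, fragment_length_mean=300)

    def test_round_trip_determinism(self, tmp_path):
        spec = DigestSpec(seed=5, depth=5)
        a = generate_hpaii_reads(spec)
        b = generate_hpaii_reads(spec)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_alignments(a.reads, pa)
        write_alignments(b.reads, pb)
        assert pa.read_bytes() == pb.read_bytes()


def test_peaks_heavy_tailed_and_clustered():
    peaks, tss = generate_peaks(n_loci=50, seed=0)
    signals = np.array([p.signal for p in peaks])
    assert signals.max() / np.median(signals) > 10  # heavy tail
    assert len(tss) >= 11
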