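"""Generator correctness: determinism, planted truth, and moment checks."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from mbdpanel import synthetic
from mbdpanel.ddpcr import poisson_copies


class TestBetaCohort:
    def test_same_seed_is_byte_identical(self, noiseless_cohort):
        spec, result = noiseless_cohort
        again = synthetic.simulate_beta_cohort(spec)
        for group in result.matrices:
            assert_frame_equal(result.matrices[group], again.matrices[group])
        assert_frame_equal(result.annotation, again.annotation)
        assert result.truth_markers == again.truth_markers

    def test_planted_genes_present_in_annotation(self, noiseless_cohort):
        spec, result = noiseless_cohort
        assert len(result.truth_markers) == spec.n_planted_marker_genes
        genes = set(result.annotation["gene"])
        assert set(result.truth_markers) <= genes

    def test_noiseless_fold_change_is_exact(self, noiseless_cohort):
        _, result = noiseless_cohort
        planted = result.annotation["gene"].isin(result.truth_markers)
        tumor = result.matrices["tumor"].loc[planted.to_numpy()]
        normal = result.matrices["normal_pancreas"].loc[planted.to_numpy()]
        fold = tumor.mean(axis=1) / normal.mean(axis=1)
        assert np.allclose(fold, 0.8 / 0.05)

    def test_planted_probes_unflagged_islands(self, noiseless_cohort):
        _, result = noiseless_cohort
        ann = result.annotation
        special = ann["gene"].isin(
            result.truth_markers + result.truth_shared
            + result.truth_pan_cancer + result.truth_blood
        )
        sub = ann[special]
        assert sub["cpg_island"].all()
        assert not sub["snp_overlap"].any()
        assert not sub["problematic"].any()
        assert not sub["chromosome"].isin(["chrX", "chrY"]).any()

    def test_empirical_mean_matches_truncated_normal(self):
        spec = synthetic.CohortSpec(
            n_tumor=40, n_blood=40, n_probes=500,
            beta_noise_sd=0.1, background_beta_mean=0.05,
            tumor_meth_beta_mean=0.6, seed=5,
        )
        result = synthetic.simulate_beta_cohort(spec)
        background = ~result.annotation["gene"].isin(
            result.truth_markers + result.truth_shared
            + result.truth_pan_cancer + result.truth_blood
        )
        values = result.matrices["tumor"].loc[background.to_numpy()].to_numpy().ravel()
        expected = synthetic.truncated_beta_mean(0.05, 0.1)
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - expected) < 3 * se

    def test_too_many_planted_genes_rejected(self):
        with pytest.raises(ValueError, match="n_probes too small"):
            synthetic.CohortSpec(n_probes=10, n_planted_marker_genes=5,
                                 probes_per_gene=10)


class TestMixtureSeries:
    def test_noiseless_evaluates_the_line(self):
        spec = synthetic.DdpcrSimSpec(0.4548, 3.295, noise="none")
        points = dict(synthetic.simulate_mixture_series(spec))
        assert points[0.0] == pytest.approx(3.295)
        assert points[100.0] == pytest.approx(48.775)

    def test_identity_line(self):
        spec = synthetic.DdpcrSimSpec(1.0, 0.0, ratios=[0, 50, 100], noise="none")
        assert dict(synthetic.simulate_mixture_series(spec))[50.0] == pytest.approx(50.0)

    def test_poisson_mean_matches_analytic(self):
        # Monte-Carlo mean at x=100 vs the analytic mean 48.775, within 3 SE
        means = []
        for seed in range(10_000):
            spec = synthetic.DdpcrSimSpec(0.4548, 3.295, ratios=[100.0], seed=seed)
            means.append(synthetic.simulate_mixture_series(spec)[0][1])
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 48.775) < 3 * se

    def test_negative_expected_copies_clamped(self, caplog):
        spec = synthetic.DdpcrSimSpec(-1.0, 10.0, ratios=[0, 50, 100], noise="none")
        with caplog.at_level("WARNING"):
            points = synthetic.simulate_mixture_series(spec)
        assert points[-1][1] == 0.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_total_copies_scales_the_response(self):
        spec = synthetic.DdpcrSimSpec(0.4548, 3.295, total_copies=2000, noise="none")
        points = dict(synthetic.simulate_mixture_series(spec))
        assert points[100.0] == pytest.approx(2 * 48.775)

    def test_determinism(self):
        spec = synthetic.DdpcrSimSpec(1.2164, 1.7287, seed=7)
        assert (synthetic.simulate_mixture_series(spec)
                == synthetic.simulate_mixture_series(spec))


class TestDropletWell:
    def test_zero_copies_no_positives(self):
        well = synthetic.simulate_droplet_well(0, seed=1)
        assert well.positive_droplets == 0

    def test_saturation_at_huge_copy_number(self):
        well = synthetic.simulate_droplet_well(1e9, n_droplets=5000, seed=1)
        assert well.positive_droplets == well.total_droplets == 5000

    def test_positive_fraction_matches_occupancy_model(self):
        # 1 - exp(-2107/20000) = 0.100; check within 3 binomial SE
        p = -np.expm1(-2107 / 20000)
        assert p == pytest.approx(0.100, abs=5e-4)
        well = synthetic.simulate_droplet_well(2107, 20000, seed=9)
        se = np.sqrt(p * (1 - p) / 20000)
        assert abs(well.positive_droplets / 20000 - p) < 3 * se

    def test_rejects_negative_copies(self):
        with pytest.raises(ValueError):
            synthetic.simulate_droplet_well(-1)


class TestCfdnaCohort:
    def test_zero_shed_probabilities_all_negative(self):
        cohort = synthetic.simulate_cfdna_cohort(
            n_cancer=10, n_normal=4, marker_shed_prob=0.0,
            kras_shed_prob=0.0, normal_false_positive_rate=0.0, seed=2,
        )
        markers = [c for c in cohort.call_matrix.columns if c not in ("kras", "truth")]
        assert not cohort.call_matrix[markers].to_numpy().any()
        assert not cohort.call_matrix["kras"].any()

    def test_seed_reproducibility(self):
        a = synthetic.simulate_cfdna_cohort(seed=3)
        b = synthetic.simulate_cfdna_cohort(seed=3)
        assert_frame_equal(a.call_matrix, b.call_matrix)

    def test_deterministic_mode_decodes_to_given_calls(self):
        calls = pd.DataFrame(
            {
                "ADAMTS2": [True, False], "HOXA1": [False, False],
                "PCDH10": [False, True], "SEMA5A": [False, False],
                "SPSB4": [False, False], "kras": [True, False],
                "truth": ["cancer", "non-cancer"],
            },
            index=["s1", "s2"],
        )
        cohort = synthetic.simulate_cfdna_cohort(call_matrix=calls, seed=4)
        # positive markers decode to well over 100 copies, negative well under
        pos = poisson_copies(cohort.marker_wells["s1"]["ADAMTS2"])[0]
        neg = poisson_copies(cohort.marker_wells["s1"]["HOXA1"])[0]
        assert pos > 1000 and neg < 100
        assert poisson_copies(cohort.kras_wells["s2"][1])[0] == 0


class TestPairedPeaks:
    @pytest.mark.parametrize("fraction,expected", [(1.0, 100.0), (0.0, 0.0)])
    def test_extreme_shared_fractions(self, fraction, expected):
        a, b = synthetic.simulate_paired_peaks(50, fraction, seed=1)
        from mbdpanel.concordance import peak_overlap

        report = peak_overlap(a, b)
        assert report.overlap_pct_a == expected
        assert report.overlap_pct_b == expected

    def test_construction_hits_requested_fraction(self):
        from mbdpanel.concordance import peak_overlap

        a, b = synthetic.simulate_paired_peaks(1000, 0.83, seed=6)
        report = peak_overlap(a, b)
        assert abs(report.overlap_pct_a - 83.0) <= 2.0
        assert abs(report.overlap_pct_b - 83.0) <= 2.0

    def test_intervals_sorted_half_open(self):
        a, _ = synthetic.simulate_paired_peaks(100, 0.5, seed=8)
        assert (a["start"] < a["end"]).all()
        assert a["start"].is_monotonic_increasing
        assert (a["start"] >= 0).all()
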