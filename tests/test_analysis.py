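"""Powder averaging, slope test, mode/HDI, repeatability, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gmexi.analysis import (
    compare_difference_distributions,
    correlate_roi_maps,
    mode_hdi,
    powder_average,
    repeatability,
    roi_table,
    slope_test,
)
from gmexi.forward import nexi_signal
from gmexi.protocol import AcquisitionProtocol, Shell, default_clinical_protocol
from gmexi.synthetic import generate_dataset, sample_ground_truth


class TestPowderAverage:
    def test_constant_volume_gives_unit_curve(self, clinical_protocol):
        table = clinical_protocol.volume_table()
        vols = np.ones((4, len(table)))
        curves, _, b0 = powder_average(vols, table)
        np.testing.assert_array_equal(curves, 1.0)
        np.testing.assert_array_equal(b0, 1.0)

    def test_matches_generator_curves_bit_exactly(self, clinical_protocol):
        gt = sample_ground_truth(6, seed=2)
        curves, vols, table = generate_dataset(
            gt, clinical_protocol, "nexi", sigma=0.03, seed=5, return_volumes=True
        )
        recomputed, _, _ = powder_average(vols, table)
        np.testing.assert_array_equal(recomputed, curves)

    def test_scale_invariance_per_diffusion_time(self, clinical_protocol):
        table = clinical_protocol.volume_table()
        rng = np.random.default_rng(0)
        vols = rng.uniform(0.5, 1.5, size=(3, len(table)))
        base, _, _ = powder_average(vols, table)
        scaled = vols.copy()
        sel = table["Delta"].to_numpy() == 45.0
        scaled[:, sel] *= 2.0
        out, _, _ = powder_average(scaled, table)
        np.testing.assert_allclose(out, base, rtol=1e-12)

    def test_b0_entries_exactly_one(self, clinical_protocol):
        table = clinical_protocol.volume_table()
        rng = np.random.default_rng(1)
        vols = rng.uniform(0.5, 1.5, size=(3, len(table)))
        curves, _, _ = powder_average(vols, table)
        b0_shells = [i for i, s in enumerate(clinical_protocol.shells) if s.is_b0]
        np.testing.assert_array_equal(curves[:, b0_shells], 1.0)

    def test_missing_b0_for_a_diffusion_time_rejected(self):
        proto = AcquisitionProtocol((Shell(b=1.0, Delta=45.0, delta=16.5, n_dirs=3),))
        table = proto.volume_table()
        with pytest.raises(ValueError, match="no b = 0"):
            powder_average(np.ones((2, 3)), table)

    def test_volume_count_mismatch_rejected(self, clinical_protocol):
        with pytest.raises(ValueError, match="volumes"):
            powder_average(np.ones((2, 10)), clinical_protocol.volume_table())

    def test_zero_voxel_yields_nan(self, clinical_protocol):
        table = clinical_protocol.volume_table()
        vols = np.zeros((1, len(table)))
        curves, _, _ = powder_average(vols, table)
        assert np.all(np.isnan(curves))


class TestSlopeTest:
    def test_exact_linear_decrease(self):
        D = np.array([28.3, 36.0, 45.0, 55.0, 65.0])
        s, p = slope_test(1.0 - 0.001 * D, D)
        assert s == pytest.approx(-0.001, rel=1e-9)
        assert p < 1e-10

    def test_constant_signal_has_zero_slope(self):
        s, _ = slope_test(np.full(5, 0.42), [28.3, 36.0, 45.0, 55.0, 65.0])
        assert s == pytest.approx(0.0, abs=1e-15)

    def test_exchange_signature_of_forward_model(self):
        Deltas = (28.3, 36.0, 45.0, 55.0, 65.0)
        proto = AcquisitionProtocol(tuple(Shell(b=2.0, Delta=D, delta=16.5) for D in Deltas))
        S = nexi_signal([20.0, 3.0, 1.0, 0.4], proto)
        s, p = slope_test(S, Deltas)
        assert s < 0 and p / 2 < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            slope_test([1.0, 0.9], [10.0, 20.0])

    def test_null_p_values_are_uniform(self):
        # constant signal + Gaussian noise: p should be U(0,1)
        rng = np.random.default_rng(12)
        D = np.array([28.3, 36.0, 45.0, 55.0, 65.0])
        pvals = [slope_test(0.5 + rng.normal(0, 0.01, 5), D)[1] for _ in range(1000)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestModeHdi:
    def test_standard_normal_against_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20000)
        mode, (lo, hi) = mode_hdi(x, 0.95)
        assert mode == pytest.approx(0.0, abs=0.1)
        assert lo == pytest.approx(-1.96, abs=0.15)
        assert hi == pytest.approx(1.96, abs=0.15)

    def test_interval_mass_by_counting(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20000)
        _, (lo, hi) = mode_hdi(x, 0.95)
        frac = np.mean((x >= lo) & (x <= hi))
        assert abs(frac - 0.95) < 0.03

    def test_degenerate_sample(self):
        mode, (lo, hi) = mode_hdi(np.full(50, 3.7), 0.95)
        assert mode == lo == hi == 3.7

    def test_skewed_sample_mode_below_mean(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0.0, 0.8, 20000)
        mode, (lo, hi) = mode_hdi(x, 0.95)
        assert mode < x.mean()
        assert lo <= mode <= hi

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mode_hdi([1.0] * 5, 0.95)
        with pytest.raises(ValueError):
            mode_hdi(np.arange(20.0), 1.5)


def _cohort(n_subj=8, n_roi=20, subj_sd=1.0, sess_sd=0.05, seed=0):
    """Synthetic two-session cohort with subject-level offsets."""
    rng = np.random.default_rng(seed)
    roi_effect = rng.normal(0, 1, n_roi)
    rows = []
    for s in range(n_subj):
        subj_effect = rng.normal(0, subj_sd, n_roi)
        for sess in (1, 2):
            noise = rng.normal(0, sess_sd, n_roi)
            for r in range(n_roi):
                rows.append(
                    {
                        "subject": f"s{s}",
                        "session": sess,
                        "roi_id": f"roi{r}",
                        "value": roi_effect[r] + subj_effect[r] + noise[r],
                    }
                )
    return pd.DataFrame(rows)


class TestRepeatability:
    def test_duplicated_sessions_are_perfectly_repeatable(self):
        t = _cohort(sess_sd=0.0)
        rep = repeatability(t)
        np.testing.assert_allclose(rep.intra, 0.0, atol=1e-12)
        assert rep.intra_corr == pytest.approx(1.0, abs=1e-12)

    def test_subject_offsets_make_intra_exceed_inter_correlation(self):
        rep = repeatability(_cohort(subj_sd=1.0, sess_sd=0.05, seed=1))
        assert rep.intra_corr > rep.inter_corr
        assert rep.intra.mean() < rep.inter.mean()

    def test_independent_tables_have_null_inter_correlation(self):
        rng = np.random.default_rng(6)
        rows = []
        for s in range(12):
            for sess in (1, 2):
                for r in range(40):
                    rows.append(
                        {"subject": f"s{s}", "session": sess, "roi_id": f"r{r}",
                         "value": rng.normal()}
                    )
        rep = repeatability(pd.DataFrame(rows))
        assert abs(rep.inter_corr) < 0.12

    def test_missing_session_rejected(self):
        t = _cohort(n_subj=3)
        t = t[~((t.subject == "s1") & (t.session == 2))]
        with pytest.raises(ValueError):
            repeatability(t)

    def test_wilcoxon_detects_shifted_differences(self):
        rng = np.random.default_rng(7)
        a = np.abs(rng.normal(0, 1, 100))
        b = a + 0.5
        _, p = compare_difference_distributions(a, b)
        assert p < 1e-6


class TestRoiCorrelation:
    def _table(self, values):
        return pd.DataFrame({"roi_id": [f"r{i}" for i in range(len(values))], "value": values})

    def test_affine_relation_gives_unit_correlation(self):
        a = np.linspace(0, 1, 10)
        r, p, paired = correlate_roi_maps(self._table(a), self._table(2 * a + 1))
        assert r == pytest.approx(1.0, abs=1e-12)
        assert len(paired) == 10

    def test_negation_gives_anticorrelation(self):
        a = np.linspace(0, 1, 10)
        r, _, _ = correlate_roi_maps(self._table(a), self._table(-a))
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_permuted_values_are_uncorrelated(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=200)
        r, p, _ = correlate_roi_maps(self._table(a), self._table(rng.permutation(a)))
        assert abs(r) < 0.2

    def test_subject_averaging(self):
        a = pd.DataFrame(
            {"roi_id": ["r0", "r0", "r1", "r1", "r2", "r2"],
             "subject": ["s1", "s2"] * 3,
             "value": [1.0, 3.0, 2.0, 4.0, 3.0, 5.0]}
        )
        b = self._table([2.0, 3.0, 4.0])
        r, _, paired = correlate_roi_maps(a, b)
        np.testing.assert_allclose(paired["a"], [2.0, 3.0, 4.0])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_too_few_shared_rois_rejected(self):
        with pytest.raises(ValueError):
            correlate_roi_maps(self._table([1, 2]), self._table([3, 4]))


class TestRoiTable:
    def test_mean_and_robust_aggregation(self):
        pm = np.zeros((2, 2, 1))
        pm[0, 0, 0], pm[1, 0, 0] = 1.0, 3.0
        pm[0, 1, 0], pm[1, 1, 0] = 5.0, np.nan
        lab = np.array([[[1], [2]], [[1], [2]]])
        t = roi_table(pm, lab)
        assert t.loc[t.roi_id == "1", "value"].item() == pytest.approx(2.0)
        assert t.loc[t.roi_id == "2", "value"].item() == pytest.approx(5.0)
        assert t.loc[t.roi_id == "2", "n_voxels"].item() == 1
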