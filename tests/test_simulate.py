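"""Seeded generators and the synthetic RR cohort model."""

import numpy as np
import pytest
from scipy import stats

from epsigraph import (
    CohortSpec,
    degree_distribution_summary,
    gen_brownian,
    gen_normal_series,
    gen_rr_cohort,
)


class TestTheoreticalSeries:
    def test_normal_series_reproducible_and_calibrated(self):
        a = gen_normal_series(10_000, seed=1)
        b = gen_normal_series(10_000, seed=1)
        assert np.array_equal(a.values, b.values)
        assert abs(a.values.mean()) < 0.05
        assert 0.95 < a.values.std() < 1.05

    def test_single_sample(self):
        assert np.isfinite(gen_normal_series(1, seed=0).values[0])

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            gen_normal_series(0, seed=0)
        with pytest.raises(ValueError):
            gen_brownian(0, seed=0)

    def test_brownian_increments_are_standard_normal(self):
        b = gen_brownian(10_000, seed=2)
        inc = np.diff(np.concatenate([[0.0], b.values]))  # includes the first step
        assert abs(inc.mean()) < 0.05
        assert 0.95 < inc.std() < 1.05
        assert stats.normaltest(inc).pvalue > 1e-4

    def test_brownian_variance_scales_linearly(self):
        # Var(B(n) / sqrt(n)) ~ 1 over 200 replicates
        n = 1_000
        finals = np.array([gen_brownian(n, seed=s).values[-1] for s in range(200)])
        v = np.var(finals / np.sqrt(n))
        assert 0.7 < v < 1.3


class TestDegreeDistributionShapes:
    """Reduced quantitative statistics behind the qualitative shape claims."""

    def test_normal_series_distribution_peaks_high_with_left_tail(self):
        d = degree_distribution_summary(gen_normal_series(10_000, seed=0), epsilon=1.0)
        assert d.skewness < -0.5  # unimodal, long left tail
        assert d.hist.argmax() > len(d.hist) // 2  # mode in the upper half

    def test_brownian_distribution_relatively_broader(self):
        xn = gen_normal_series(10_000, seed=0)
        xb = gen_brownian(10_000, seed=0)
        dn = degree_distribution_summary(xn, epsilon=1.0)
        db = degree_distribution_summary(xb, epsilon=1.0)
        # Brownian occupation spreads degrees over a wider range relative
        # to its mean, and is closer to symmetric than the normal case
        assert db.support_width / db.mean > dn.support_width / dn.mean
        assert abs(db.skewness) < abs(dn.skewness)

    def test_constant_series_is_a_point_mass_at_one(self):
        d = degree_distribution_summary(np.full(50, 0.8), epsilon=0.01)
        assert d.mean == 1.0 and d.sd == 0.0 and d.support_width == 0.0


class TestCohortGenerator:
    def test_seed_determinism(self):
        spec = CohortSpec(n_pairs=3, length=200, change_index=80, seed=9)
        a, b = gen_rr_cohort(spec), gen_rr_cohort(spec)
        for ra, rb in zip(a, b):
            assert ra.subject_id == rb.subject_id and ra.group == rb.group
            assert np.array_equal(ra.rr.values, rb.rr.values)

    def test_null_change_is_indistinguishable(self):
        spec = CohortSpec(
            n_pairs=20, length=500, change_index=200,
            change_sd_scale=1.0, change_mean_shift=0.0, post_sd_scale=1.0, seed=3,
        )
        records = gen_rr_cohort(spec)
        vt = np.concatenate([r.rr.values for r in records if r.group == "VT"])
        cr = np.concatenate([r.rr.values for r in records if r.group == "CR"])
        assert abs(vt.mean() - cr.mean()) < 3 * 0.03 * np.sqrt(2 / vt.size)
        assert abs(vt.std() - cr.std()) / cr.std() < 0.05

    def test_burst_inflates_vt_variance_locally(self):
        spec = CohortSpec(
            n_pairs=30, length=500, change_index=200, change_sd_scale=3.0,
            change_duration=60, post_sd_scale=0.5, seed=4,
        )
        records = gen_rr_cohort(spec)
        vt = np.stack([r.rr.values for r in records if r.group == "VT"])
        cr = np.stack([r.rr.values for r in records if r.group == "CR"])
        burst = slice(199, 259)
        post = slice(300, 500)
        assert vt[:, burst].std() > 2 * cr[:, burst].std()
        assert vt[:, post].std() < 0.75 * cr[:, post].std()
        assert np.allclose(vt[:, :150].std(), cr[:, :150].std(), rtol=0.1)

    def test_all_outputs_positive_and_finite(self):
        spec = CohortSpec(
            n_pairs=5, length=300, baseline_mean=0.35, baseline_sd=0.08,
            change_index=100, change_sd_scale=3.0, n_healthy=2, healthy_length=400, seed=5,
        )
        for r in gen_rr_cohort(spec):
            assert np.all(np.isfinite(r.rr.values))
            assert np.all(r.rr.values > 0.2)

    def test_healthy_records_created_with_requested_length(self):
        spec = CohortSpec(n_pairs=2, length=200, n_healthy=3, healthy_length=260, seed=0)
        hs = [r for r in gen_rr_cohort(spec) if r.group == "HS"]
        assert len(hs) == 3 and all(len(r.rr) == 260 for r in hs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_pairs": 0},
            {"baseline_sd": 0.0},
            {"ar_coeff": 1.0},
            {"change_index": 0},
            {"change_index": 1000, "length": 500},
            {"change_duration": 0},
            {"healthy_length": 100, "length": 200},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortSpec(**kwargs)
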