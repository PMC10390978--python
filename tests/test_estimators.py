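"""The five indirect estimators and the combination wiring."""

import numpy as np
import pytest
from scipy.special import inv_boxcox, ndtri
from scipy.stats import norm

import refinterval as ri
from refinterval.estimators import (
    BhattacharyaRI,
    HoffmannRI,
    KosmicRI,
    NonparametricRI,
    ParametricRI,
    bhattacharya_from_counts,
    run_combo,
    run_matrix,
)
from refinterval.transforms import BoxCoxTransform, LogTransform


class TestParametric:
    def test_standardized_sample_gives_plus_minus_1_96(self, rng):
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std(ddof=1)
        est = ParametricRI().fit(x)
        assert est.lower_ == pytest.approx(-1.96, abs=1e-12)
        assert est.upper_ == pytest.approx(1.96, abs=1e-12)

    def test_log_model_back_transforms_exponentially(self, rng):
        y = rng.normal(2.0, 0.25, 1000)
        est = ParametricRI(transform=LogTransform()).fit(y)
        m, s = y.mean(), y.std(ddof=1)
        assert est.lower_ == pytest.approx(np.exp(m - 1.96 * s))
        assert est.upper_ == pytest.approx(np.exp(m + 1.96 * s))

    def test_full_pipeline_on_truncated_gaussian(self, rng):
        # N(100, 5^2): fitted lambda ~ 1, interval ~ (90.2, 109.8)
        x = rng.normal(100.0, 5.0, 100_000)
        x = x[x > 0]
        tr = ri.fit_boxcox(x)
        est = ParametricRI(transform=tr).fit(tr.transform(x))
        assert est.lower_ == pytest.approx(90.2, abs=0.3)
        assert est.upper_ == pytest.approx(109.8, abs=0.3)

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError, match="standard deviation"):
            ParametricRI().fit(np.full(30, 2.0))


class TestNonparametric:
    def test_rank_formula_small_samples(self):
        est = NonparametricRI(min_n=0).fit(np.arange(1.0, 40.0))
        assert est.lower_ == pytest.approx(1.0)   # rank 0.025*40 = 1
        assert est.upper_ == pytest.approx(39.0)
        est = NonparametricRI(min_n=0).fit(np.arange(1.0, 201.0))
        assert est.lower_ == pytest.approx(5.025)
        assert est.upper_ == pytest.approx(195.975)

    def test_minimum_sample_size_enforced(self, rng):
        with pytest.raises(ValueError, match="120"):
            NonparametricRI().fit(rng.standard_normal(100))

    def test_matches_sort_and_rank_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(120, 1001))
            x = rng.lognormal(1.0, 0.5, n)
            est = NonparametricRI().fit(x)
            s = sorted(x)
            for r, got in ((0.025 * (n + 1), est.lower_), (0.975 * (n + 1), est.upper_)):
                r = min(max(r, 1.0), n)
                i, frac = int(r), r - int(r)
                want = s[i - 1] + frac * (s[i] - s[i - 1]) if i < n else s[-1]
                assert got == pytest.approx(want, rel=1e-12)

    def test_agrees_with_parametric_in_gaussian_limit(self, rng):
        x = rng.normal(50.0, 4.0, 100_000)
        p = ParametricRI().fit(x)
        np_ = NonparametricRI().fit(x)
        # 3 order-statistic SEs at the 2.5th/97.5th percentile of N(50,16)
        se = np.sqrt(0.025 * 0.975 / x.size) / norm.pdf(norm.ppf(0.025)) * 4.0
        assert abs(p.lower_ - np_.lower_) < 3 * se
        assert abs(p.upper_ - np_.upper_) < 3 * se


class TestHoffmann:
    def test_points_on_the_line_recovered_exactly(self):
        n = 1000
        x = ndtri((np.arange(1, n + 1) - 0.5) / n)
        est = HoffmannRI().fit(x)
        assert est.lower_ == pytest.approx(-1.96, abs=0.01)
        assert est.upper_ == pytest.approx(1.96, abs=0.01)

    def test_gaussian_sample_recovers_analytic_limits(self, rng):
        x = rng.normal(50.0, 4.0, 100_000)
        est = HoffmannRI().fit(x)
        assert est.lower_ == pytest.approx(50 - 1.96 * 4, abs=0.2)
        assert est.upper_ == pytest.approx(50 + 1.96 * 4, abs=0.2)

    def test_degenerate_window_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            HoffmannRI(window=(0.5, 0.5)).fit(rng.standard_normal(100))

    def test_decreasing_data_cannot_fit(self):
        with pytest.raises(ValueError):
            HoffmannRI().fit(np.full(50, 1.0))


class TestBhattacharya:
    @pytest.mark.parametrize("mu,sigma", [(0.0, 1.0), (10.0, 2.0)])
    def test_exact_density_counts_recover_parameters(self, mu, sigma):
        """Counts proportional to the Gaussian density at bin midpoints make the
        log-difference plot exactly linear; (mu, sigma) recovered to 1e-6."""
        h = 0.5
        mids = np.arange(mu - 3 * sigma, mu + 3 * sigma + h / 2, h)
        counts = 1e6 * norm.pdf(mids, mu, sigma)
        got_mu, got_sigma, diag = bhattacharya_from_counts(mids, counts, h)
        assert diag["slope"] == pytest.approx(-h / sigma**2, abs=1e-9)
        assert got_mu == pytest.approx(mu, abs=1e-6)
        assert got_sigma == pytest.approx(sigma, abs=1e-6)

    def test_flat_histogram_has_no_negative_slope(self):
        mids = np.arange(0.0, 5.0, 0.5)
        with pytest.raises(ValueError, match="slope"):
            bhattacharya_from_counts(mids, np.full(mids.size, 100.0), 0.5)

    def test_manual_segment_must_cover_three_points(self):
        mids = np.arange(0.0, 5.0, 0.5)
        counts = 1e4 * norm.pdf(mids, 2.5, 1.0)
        with pytest.raises(ValueError, match="at least 3 points"):
            bhattacharya_from_counts(mids, counts, 0.5, segment=(2, 4))

    def test_sampled_gaussian_recovery(self, rng):
        x = rng.normal(50.0, 4.0, 100_000)
        est = BhattacharyaRI().fit(x)
        assert est.mu_ == pytest.approx(50.0, abs=0.3)
        assert est.sigma_ == pytest.approx(4.0, rel=0.05)
        assert est.slope_ < 0


class TestKosmic:
    def test_pure_power_normal_recovery(self):
        """Parameter recovery at n = 50,000: typically (median over seeds)
        within 1% relative of the true limits, always within 2%."""
        lo, hi = inv_boxcox(12 - 1.96, 0.5), inv_boxcox(12 + 1.96, 0.5)
        errors = []
        for seed in range(5):
            z = np.random.default_rng(seed).normal(12.0, 1.0, 50_000)
            est = KosmicRI().fit(inv_boxcox(z, 0.5))
            errors.append(max(abs(est.lower_ - lo) / lo, abs(est.upper_ - hi) / hi))
            assert 0 <= est.ks_distance_ <= 1
        assert np.median(errors) < 0.01
        assert max(errors) < 0.02

    def test_agrees_with_parametric_when_uncontaminated(self, rng):
        z = rng.normal(12.0, 1.0, 50_000)
        x = inv_boxcox(z, 0.5)
        k = KosmicRI().fit(x)
        tr = ri.fit_boxcox(x)
        p = ParametricRI(transform=tr).fit(tr.transform(x))
        assert abs(k.lower_ - p.lower_) / p.lower_ < 0.02
        assert abs(k.upper_ - p.upper_) / p.upper_ < 0.02

    def test_small_sample_warns(self, rng):
        x = np.abs(rng.normal(10, 2, 500)) + 0.1
        with pytest.warns(UserWarning, match="recommended minimum"):
            KosmicRI().fit(x)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            KosmicRI().fit(np.linspace(-1, 1, 2000))
        with pytest.raises(ValueError, match="constant"):
            KosmicRI().fit(np.full(2000, 5.0))


class TestComboWiring:
    @pytest.fixture(scope="class")
    def values(self):
        spec = ri.make_preset("WBC", "male", n=4000, seed=21)
        return ri.simulate_dataset(spec)["value"].to_numpy()

    def test_nonparametric_consumes_retained_original_values(self, values):
        combo = run_combo(values, "log", "tukey", "nonparametric")
        tr = LogTransform().fit(values)
        mask = ri.TukeyFences().fit(tr.transform(values)).outlier_mask_
        direct = NonparametricRI().fit(values[~mask])
        assert combo.interval.lower == pytest.approx(direct.lower_)
        assert combo.interval.upper == pytest.approx(direct.upper_)
        assert combo.n_used == int((~mask).sum())

    def test_nonparametric_sees_transform_only_through_flags(self, values):
        a = run_combo(values, "log", "tukey", "nonparametric")
        b = run_combo(values, "boxcox", "tukey", "nonparametric")
        # any difference must come from differing flag sets alone
        if a.n_used == b.n_used and a.elimination_rate == b.elimination_rate:
            assert a.interval.as_tuple() == pytest.approx(b.interval.as_tuple())

    def test_reed_dixon_removes_nothing_at_scale(self, values):
        combo = run_combo(values, "boxcox", "reed_dixon", "parametric")
        assert combo.n_used == values.size
        assert combo.elimination_rate == 0.0

    def test_unknown_estimator_rejected(self, values):
        with pytest.raises(ValueError, match="unknown estimator"):
            run_combo(values, "log", "tukey", "magic")


class TestRunMatrix:
    @pytest.fixture(scope="class")
    def stratum(self):
        spec = ri.make_preset("PLT", "female", n=4000, seed=31)
        vals = ri.simulate_dataset(spec)["value"].to_numpy()
        return vals, ri.true_reference_limits(spec)

    def test_emits_exactly_30_rows(self, stratum):
        vals, ref = stratum
        m = run_matrix(vals, analyte="PLT", sex="female", reference=ref)
        assert len(m) == 30
        assert set(m["transform"]) == {"log", "boxcox"}
        from refinterval.estimators import ESTIMATOR_NAMES

        assert set(m["estimator"]) == set(ESTIMATOR_NAMES)
        assert (m["status"] == "ok").all()
        assert {"BR_LL", "BR_UL", "d_pct_LL", "qualified_UL"} <= set(m.columns)

    def test_failing_cell_is_isolated(self, stratum):
        vals, _ = stratum
        m = run_matrix(vals, estimator_kwargs={"nonparametric": {"min_n": 10**6}})
        failed = m[m["status"] != "ok"]
        assert set(failed["estimator"]) == {"nonparametric"}
        assert len(failed) == 6
        assert (m.loc[m["estimator"] != "nonparametric", "status"] == "ok").all()

    def test_rerun_is_identical(self, stratum):
        vals, ref = stratum
        m1 = run_matrix(vals, reference=ref)
        m2 = run_matrix(vals, reference=ref)
        assert m1.equals(m2)
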