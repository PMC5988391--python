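"""Circular-shift GLM machinery, FCR correction, contrasts and lags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oscnet import stats as ost


def _subject(rng, n=120, beta=0.0):
    x = rng.normal(size=n)
    y = beta * x + rng.normal(size=n)
    cov = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    return y, x, cov


class TestSubjectGlm:
    def test_identity_regressor_gives_unit_beta(self, rng):
        x = rng.normal(size=60)
        assert ost.subject_glm(x, x) == pytest.approx(1.0, abs=1e-10)

    def test_independent_regressor_near_zero(self, rng):
        y, x, cov = _subject(rng, n=500)
        assert abs(ost.subject_glm(y, x, cov)) < 0.1

    def test_no_covariate_equals_spearman(self, rng):
        for _ in range(20):
            y, x, _ = _subject(rng, n=50, beta=0.4)
            rho = sps.spearmanr(y, x).statistic
            assert ost.subject_glm(y, x) == pytest.approx(rho, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        y, x, cov = _subject(rng, beta=0.3)
        b1 = ost.subject_glm(y, x, cov)
        b2 = ost.subject_glm(np.exp(y), x**3, cov)
        assert b1 == pytest.approx(b2, abs=1e-12)

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            ost.subject_glm(np.arange(5.0), np.arange(5.0))

    def test_collinear_covariates_named(self, rng):
        x = rng.normal(size=50)
        cov = pd.DataFrame({"c1": x})
        with pytest.raises(ValueError, match="x~c1"):
            ost.subject_glm(rng.normal(size=50), x, cov)


class TestCircularNull:
    def test_matches_explicit_shift_refits(self, rng):
        """The vectorized null equals refitting subject GLMs on explicitly
        rolled behavioral series."""
        subs = [_subject(rng, n=40) for _ in range(3)]
        _, _, null = ost.glm_with_null(
            [s[0] for s in subs], [s[1] for s in subs], [s[2] for s in subs],
            n_shifts=10,
        )
        for k in (1, 5, 10):
            betas = [
                ost.subject_glm(np.roll(y, -k), x, cov) for y, x, cov in subs
            ]
            assert null[k - 1] == pytest.approx(np.mean(betas), abs=1e-10)

    def test_shift_count_limited_by_trials(self, rng):
        y, x, cov = _subject(rng, n=30)
        with pytest.raises(ValueError):
            ost.glm_with_null([y], [x], [cov], n_shifts=30)

    def test_circular_shift_preserves_acf(self, rng):
        """Circularly shifted series keep the circular autocorrelation
        function of the original (FFT-based check)."""
        y = np.convolve(rng.normal(size=128), np.ones(4) / 4, mode="same")
        def cacf(v):
            v = v - v.mean()
            f = np.fft.rfft(v)
            return np.fft.irfft(f * np.conj(f))
        assert np.allclose(cacf(np.roll(y, 17)), cacf(y), atol=1e-9)

    def test_full_rotation_is_identity(self, rng):
        y = rng.normal(size=64)
        assert np.array_equal(np.roll(y, 64), y)
        assert sorted(np.roll(y, 7)) == sorted(y)


class TestSignificance:
    def test_median_not_significant(self, rng):
        null = rng.normal(size=350)
        flag, (lo, hi) = ost.significance(float(np.median(null)), null)
        assert not flag and lo < hi

    def test_extreme_value_significant(self, rng):
        null = rng.normal(size=350)
        flag, _ = ost.significance(null.max() + 1.0, null)
        assert flag

    def test_type_one_rate_calibrated(self, rng):
        """Under exchangeability the two-sided percentile test flags ~5%."""
        hits = 0
        reps = 1000
        for _ in range(reps):
            draws = rng.normal(size=101)
            flag, _ = ost.significance(draws[0], draws[1:])
            hits += flag
        assert 0.03 <= hits / reps <= 0.07


class TestFcrCorrect:
    def test_adjusted_level_formula(self, rng):
        """Fs=2 of Ft=14 at q=0.05 gives level 1 - 0.1/14 ~ 0.99286."""
        nulls = rng.normal(size=(14, 350))
        obs = np.zeros(14)
        obs[:2] = 10.0  # far outside both passes
        table = ost.fcr_correct(obs, nulls, q=0.05, Ft=14)
        assert table["selected"].sum() == 2
        assert table["fcr_level"].iloc[0] == pytest.approx(1 - 0.1 / 14)
        assert table["significant"].sum() == 2

    def test_all_selected_means_no_inflation(self, rng):
        nulls = rng.normal(size=(5, 350))
        table = ost.fcr_correct(np.full(5, 10.0), nulls, q=0.05)
        assert table["fcr_level"].iloc[0] == pytest.approx(0.95)
        assert np.allclose(table["null_lo_fcr"], table["null_lo"])

    def test_adjusted_ci_contains_unadjusted(self, rng):
        nulls = rng.normal(size=(10, 350))
        obs = rng.normal(size=10)
        obs[3] = 5.0
        table = ost.fcr_correct(obs, nulls, q=0.05)
        assert np.all(table["null_lo_fcr"] <= table["null_lo"] + 1e-12)
        assert np.all(table["null_hi_fcr"] >= table["null_hi"] - 1e-12)

    def test_no_selection_skips_second_pass(self, rng):
        nulls = rng.normal(size=(6, 350))
        table = ost.fcr_correct(np.zeros(6), nulls)
        assert not table["selected"].any()
        assert not table["significant"].any()

    def test_ft_smaller_than_results_rejected(self, rng):
        with pytest.raises(ValueError):
            ost.fcr_correct(np.zeros(5), rng.normal(size=(5, 100)), Ft=3)


class TestTaskContrast:
    def test_identical_tasks_give_zero(self, rng):
        betas = rng.normal(size=8)
        null = rng.normal(scale=0.1, size=350)
        diff, flag, _ = ost.task_contrast(betas, betas, null, null)
        assert diff == 0.0 and not flag

    def test_sign_flipped_effects_double(self, rng):
        betas = np.full(6, 0.4) + 0.01 * rng.normal(size=6)
        null = rng.normal(scale=0.05, size=350)
        diff, flag, _ = ost.task_contrast(betas, -betas, null, -null)
        assert diff == pytest.approx(2 * betas.mean())
        assert flag

    def test_unpaired_rejected(self, rng):
        with pytest.raises(ValueError):
            ost.task_contrast(np.zeros(4), np.zeros(5), np.zeros(10), np.zeros(10))

    def test_regional_variant_uses_fcr(self, rng):
        nulls = rng.normal(scale=0.1, size=(2, 7, 350))
        ba = rng.normal(scale=0.05, size=(6, 7))
        bb = ba.copy()
        bb[:, 2] -= 1.0  # one region with a strong task difference
        table = ost.task_contrast(ba, bb, nulls[0], nulls[1], Ft=7)
        assert isinstance(table, pd.DataFrame)
        assert table["significant"].iloc[2]


class TestCrossCorrLag:
    def test_constructed_shift_peaks_at_plus_three(self, rng):
        b = rng.normal(size=200)
        m = np.roll(b, 3)  # metric trails behavior by 3 trials
        table = ost.crosscorr_lag(b, m, max_lag=5)
        peak = table.loc[table["r"].idxmax(), "lag"]
        assert peak == 3

    def test_independent_series_flat(self, rng):
        table = ost.crosscorr_lag(
            rng.normal(size=400), rng.normal(size=400), max_lag=4
        )
        assert np.all(np.abs(table["r"]) < 0.15)

    def test_lag_zero_equals_subject_glm(self, rng):
        y, x, _ = _subject(rng, n=80, beta=0.5)
        table = ost.crosscorr_lag(y, x, max_lag=2)
        r0 = table.loc[table["lag"] == 0, "r"].iloc[0]
        assert r0 == pytest.approx(ost.subject_glm(y, x), abs=1e-10)


def test_permutation_one_sample_exact_small_n():
    vals = np.array([0.5, 0.6, 0.4, 0.55, 0.45])
    mean, p = ost.permutation_one_sample(vals)
    assert mean == pytest.approx(0.5)
    assert p == pytest.approx(2 / 32)
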