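"""Ground-truth simulator: epochs, behavior, and coupling recovery."""

import numpy as np
import pytest

from oscnet import connectivity as conn
from oscnet import spectral, synthmeg
from oscnet.synthmeg import CouplingModel


BETA_BIN = 2.0**4.25  # grid bin closest to the 20-Hz default carrier


def _couplings(model, trials, seed, freq=BETA_BIN):
    epochs = synthmeg.simulate_epochs(model, trials, seed=seed)
    grid = spectral.FrequencyGrid(np.array([freq]))
    tfr = spectral.wavelet_transform(
        epochs.data, epochs.sample_rate, epochs.epoch_window[0], grid=grid
    )
    return conn.envelope_correlations(tfr, freq).corr.mean(axis=0)


class TestSimulateEpochs:
    def test_shape_window_and_finiteness(self):
        model = CouplingModel(n_sources=5)
        epochs = synthmeg.simulate_epochs(model, 7, seed=0)
        assert epochs.data.shape == (7, 5, 1500)
        assert epochs.sample_rate == 500.0
        assert epochs.times[0] == pytest.approx(-1.0)
        assert np.all(np.isfinite(epochs.data))

    def test_seed_determinism(self):
        model = CouplingModel(n_sources=4)
        a = synthmeg.simulate_epochs(model, 3, seed=11)
        b = synthmeg.simulate_epochs(model, 3, seed=11)
        assert np.array_equal(a.data, b.data)

    def test_identity_coupling_gives_null_couplings(self):
        model = CouplingModel(n_sources=6)
        mean_r = _couplings(model, 150, seed=1)
        iu = np.triu_indices(6, 1)
        assert np.all(np.abs(mean_r[iu]) < 0.1)

    def test_zero_snr_is_pure_noise(self):
        model = CouplingModel(
            n_sources=4,
            snr=0.0,
            envelope_corr=synthmeg.uniform_correlation(4, 0.9),
        )
        mean_r = _couplings(model, 150, seed=2)
        iu = np.triu_indices(4, 1)
        assert np.all(np.abs(mean_r[iu]) < 0.1)

    def test_non_psd_matrix_projected_with_warning(self, caplog):
        bad = np.array(
            [[1.0, 0.95, -0.95], [0.95, 1.0, 0.95], [-0.95, 0.95, 1.0]]
        )
        bad4 = np.eye(4)
        bad4[:3, :3] = bad
        with caplog.at_level("WARNING", logger="oscnet.synthmeg"):
            model = CouplingModel(n_sources=4, envelope_corr=bad4)
        assert "PSD" in caplog.text
        w = np.linalg.eigvalsh(model.envelope_corr)
        assert w.min() >= -1e-10

    def test_envelope_recovery_monotone(self):
        """Estimated couplings increase strictly with the planted pair
        correlation across {0, 0.3, 0.6, 0.9}."""
        estimates = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            R = np.eye(4)
            R[0, 1] = R[1, 0] = rho
            model = CouplingModel(n_sources=4, envelope_corr=R)
            mean_r = _couplings(model, 500, seed=5)
            estimates.append(mean_r[0, 1])
        assert np.all(np.diff(estimates) > 0)


class TestSimulateBehavior:
    def test_accuracy_calibrated(self):
        model = CouplingModel(n_sources=4)
        rng = np.random.default_rng(0)
        stat = rng.uniform(0, 1, 384)
        acc = np.array(
            [
                synthmeg.simulate_behavior(model, stat, seed=s)["correct"].mean()
                for s in range(10)
            ]
        )
        # binomial oracle: sd of one 384-trial accuracy is ~0.023
        sd = np.sqrt(0.7 * 0.3 / 384)
        assert abs(acc.mean() - 0.70) < 2 * sd
        assert np.all(np.abs(acc - 0.70) < 3.5 * sd)

    def test_zero_slope_gives_null_correlation(self):
        model = CouplingModel(n_sources=4, behavior_slope=0.0)
        stat = np.random.default_rng(1).uniform(0, 1, 2000)
        table = synthmeg.simulate_behavior(model, stat, seed=3)
        ok = np.isfinite(table["speed"])
        r = np.corrcoef(table.loc[ok, "speed"], stat[ok])[0, 1]
        assert abs(r) < 0.06

    def test_affine_slope_matches_closed_form(self):
        """slope 0.3 with unit noise gives population correlation
        0.3 / sqrt(0.09 + 1) ~ 0.287."""
        model = CouplingModel(
            n_sources=4, behavior_slope=0.3, behavior_noise_sd=1.0
        )
        stat = np.random.default_rng(2).normal(size=4000)
        table = synthmeg.simulate_behavior(
            model, stat, seed=4, no_response_rate=0.0
        )
        r = np.corrcoef(table["speed"], stat)[0, 1]
        assert r == pytest.approx(0.3 / np.sqrt(1.09), abs=0.03)

    def test_response_times_positive_and_missing_rate(self):
        model = CouplingModel(n_sources=4, no_response_rate=0.05)
        stat = np.random.default_rng(3).normal(size=2000)
        table = synthmeg.simulate_behavior(model, stat, seed=5)
        rt = table["response_time"]
        assert np.all(rt[np.isfinite(rt)] > 0)
        assert 0.02 < rt.isna().mean() < 0.09

    def test_bad_target_accuracy_rejected(self):
        model = CouplingModel(n_sources=4)
        with pytest.raises(ValueError):
            synthmeg.simulate_behavior(model, np.zeros(10), seed=0,
                                       target_accuracy=0.4)

    def test_nonfinite_stat_rejected(self):
        model = CouplingModel(n_sources=4)
        with pytest.raises(ValueError):
            synthmeg.simulate_behavior(model, np.array([1.0, np.nan]), seed=0)


def test_model_validation():
    with pytest.raises(ValueError):
        CouplingModel(n_sources=2)
    with pytest.raises(ValueError):
        CouplingModel(n_sources=4, snr=-1.0)
    with pytest.raises(ValueError):
        CouplingModel(n_sources=4, envelope_corr=np.eye(3))


def test_target_matrices_are_valid_correlations():
    for mat in (
        synthmeg.modular_correlation(16, 4, 0.8, 0.1),
        synthmeg.uniform_correlation(16, 0.1),
    ):
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.linalg.eigvalsh(mat).min() >= -1e-10
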