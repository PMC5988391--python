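"""Synthetic source-space oscillations with a planted coupling network.

This module provides ground truth for the whole analysis chain: it emits
epoched "source-projected" signals directly (no sensors, no inverse
model).  Each source carries a band-limited oscillation at a carrier
frequency (default 20 Hz) whose amplitude is a slowly varying log-normal
envelope; the log envelopes are low-pass-filtered Gaussian processes
(cutoff 0.3 Hz, mirroring the slow dynamics of beta-band power
envelopes) that are correlated across sources according to a target
correlation matrix.  Carrier phases are independent across sources, so
the planted coupling lives purely in the power envelopes -- exactly what
orthogonalized envelope correlation is meant to recover.  Pink (1/f)
background noise is added at a configurable signal-to-noise ratio.

Behavior is generated from a per-trial latent network statistic:
decision speed is an affine function of the z-scored statistic plus
Gaussian noise, response time its reciprocal, and correctness a Bernoulli
draw calibrated to a target accuracy (~70 %, as an adaptive staircase
would produce).  An optional instantaneous linear mixing matrix emulates
field spread for leakage tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EPOCH_WINDOW = (-1.0, 2.0)
SAMPLE_RATE = 500.0


def nearest_psd(corr: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the nearest PSD correlation matrix."""
    sym = 0.5 * (corr + corr.T)
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, 0.0, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def modular_correlation(
    n_sources: int, n_modules: int, r_within: float, r_between: float
) -> np.ndarray:
    """Block-structured correlation matrix: dense modules, sparse between."""
    labels = np.arange(n_sources) % n_modules
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, r_within, r_between)
    np.fill_diagonal(corr, 1.0)
    return nearest_psd(corr)


def uniform_correlation(n_sources: int, r: float) -> np.ndarray:
    """Exchangeable correlation matrix with constant off-diagonal ``r``."""
    corr = np.full((n_sources, n_sources), r)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class CouplingModel:
    """Ground-truth generative model for one simulated subject.

    Attributes
    ----------
    n_sources : int
        Number of source locations (>= 4).  Default 64, a desk-scale
        stand-in for a dense cortical grid.
    carrier_freq : float
        Oscillation carrier in Hz.
    envelope_corr : ndarray (N, N), optional
        Target correlation matrix of the log envelopes; identity if
        omitted.  Non-PSD inputs are projected to the nearest PSD
        correlation matrix with a warning.
    behavior_slope : float
        Effect size of the planted statistic on decision speed
        (speed units per SD of the statistic).
    behavior_noise_sd : float
        SD of the Gaussian noise added to decision speed.
    snr : float
        Ratio of oscillation power to pink-noise power.
    env_cutoff_hz : float
        Low-pass cutoff of the slow log-envelope component.
    env_fast_frac : float
        Fraction of log-envelope variance carried by a faster,
        band-limited component (cutoff ``env_fast_cutoff_hz``).  Power
        envelopes measured through a wavelet fluctuate within the
        wavelet's own spectral bandwidth, not only below the slow
        coupling timescale; without this component a 2-s analysis window
        would contain ~1.5 independent envelope samples and per-trial
        correlation estimates would be statistically degenerate.
    env_fast_cutoff_hz : float, optional
        Cutoff of the fast component; defaults to ``carrier_freq / 6``,
        the spectral half-bandwidth of a 6-cycle wavelet at the carrier.
    log_env_sd : float
        SD of the total log envelope (depth of power fluctuations).
    baseline_speed : float
        Mean decision speed in 1/s (~1.8 for this kind of task).
    no_response_rate : float
        Fraction of trials without a response.
    mixing : ndarray (N, N), optional
        Instantaneous linear mixing applied to the emitted signals
        (leakage-test toggle).
    """

    n_sources: int = 64
    carrier_freq: float = 20.0
    envelope_corr: np.ndarray | None = None
    network_stat_name: str = "mean_fc"
    behavior_slope: float = 0.0
    behavior_noise_sd: float = 1.0
    snr: float = 1.0
    env_cutoff_hz: float = 0.3
    env_fast_frac: float = 0.5
    env_fast_cutoff_hz: float | None = None
    log_env_sd: float = 0.5
    baseline_speed: float = 1.8
    no_response_rate: float = 0.01
    mixing: np.ndarray | None = None

    def __post_init__(self):
        if self.n_sources < 4:
            raise ValueError("n_sources must be >= 4")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if not (0 <= self.env_fast_frac <= 1):
            raise ValueError("env_fast_frac must be in [0, 1]")
        if self.env_fast_cutoff_hz is None:
            self.env_fast_cutoff_hz = self.carrier_freq / 6.0
        if self.envelope_corr is not None:
            self.envelope_corr = _validated_corr(
                np.asarray(self.envelope_corr, dtype=float), self.n_sources
            )


def _validated_corr(corr: np.ndarray, n: int) -> np.ndarray:
    if corr.shape != (n, n):
        raise ValueError("envelope_corr must be (n_sources, n_sources)")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("envelope_corr must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("envelope_corr must have a unit diagonal")
    w = np.linalg.eigvalsh(0.5 * (corr + corr.T))
    if w.min() < -1e-10:
        logger.warning("envelope_corr is not PSD; projecting to the nearest PSD matrix")
        corr = nearest_psd(corr)
    return corr


@dataclass
class EpochSet:
    """Per-trial source-space signals with sampling metadata."""

    data: np.ndarray  # (trials, sources, samples)
    sample_rate: float = SAMPLE_RATE
    epoch_window: tuple = EPOCH_WINDOW
    trial_table: pd.DataFrame | None = None

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, sources, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sources(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.epoch_window[0] + np.arange(n) / self.sample_rate

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("data", data=self.data)
            h5.attrs["sample_rate"] = self.sample_rate
            h5.attrs["epoch_window"] = self.epoch_window
            if self.trial_table is not None:
                h5.create_dataset(
                    "trial_ids", data=self.trial_table["trial"].to_numpy()
                )

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as h5:
            return cls(
                data=h5["data"][()],
                sample_rate=float(h5.attrs["sample_rate"]),
                epoch_window=tuple(h5.attrs["epoch_window"]),
            )


def _white_spectrum(shape, rng: np.random.Generator) -> np.ndarray:
    """rfft-domain white Gaussian spectrum (drawn directly, no forward FFT)."""
    n = shape[-1]
    n_bins = n // 2 + 1
    spec = np.empty(shape[:-1] + (n_bins,), dtype=np.complex128)
    spec.real = rng.standard_normal(spec.shape)
    spec.imag = rng.standard_normal(spec.shape)
    spec *= np.sqrt(n / 2.0)
    spec[..., 0] = 0.0  # zero-mean processes throughout
    if n % 2 == 0:
        spec[..., -1] = spec[..., -1].real * np.sqrt(2.0)
    return spec


def _pink_noise(shape, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise along the last axis."""
    n = shape[-1]
    spec = _white_spectrum(shape, rng)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    spec[..., 0] = 0.0
    pink = np.fft.irfft(spec, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    return pink / np.where(sd > 0, sd, 1.0)


def _lowpass_gain(n, cutoff_hz, sample_rate, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth magnitude response on the rfft grid.

    Filtering happens in the frequency domain; time-domain IIR filtering
    is numerically unstable at cutoffs this far below the sampling rate.
    The DC gain is zero: a retained offset would be inflated without
    bound by per-series standardization.
    """
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    gain = 1.0 / np.sqrt(1.0 + (f / cutoff_hz) ** (2 * order))
    gain[0] = 0.0
    return gain


def _unit_gain(n, cutoff_hz, sample_rate, order: int = 4) -> np.ndarray:
    """Low-pass gain scaled so the filtered process has unit variance."""
    g = _lowpass_gain(n, cutoff_hz, sample_rate, order)
    # Parseval on the rfft grid: interior bins count twice
    w = np.full(len(g), 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    var = float((w * g**2).sum()) / n
    return g / np.sqrt(var)


def _slow_processes(shape, cutoff_hz, sample_rate, rng, order: int = 4) -> np.ndarray:
    """Unit-variance low-pass Gaussian processes along the last axis."""
    n = shape[-1]
    spec = _white_spectrum(shape, rng)
    spec *= _lowpass_gain(n, cutoff_hz, sample_rate, order)
    slow = np.fft.irfft(spec, n=n, axis=-1)
    sd = slow.std(axis=-1, keepdims=True)
    return slow / np.where(sd > 0, sd, 1.0)


def simulate_epochs(
    model: CouplingModel,
    n_trials: int,
    seed,
    envelope_corr_per_trial: np.ndarray | None = None,
    sample_rate: float = SAMPLE_RATE,
    epoch_window: tuple = EPOCH_WINDOW,
    trial_table: pd.DataFrame | None = None,
) -> EpochSet:
    """Simulate epoched source signals with the planted envelope coupling.

    Per trial and source the signal is ``A(t) * cos(2 pi f t + phi)``
    plus pink noise, where ``log A`` is a slow Gaussian process correlated
    across sources per the model's (or per-trial) target matrix and
    ``phi`` is an independent uniform phase per source and trial.

    Parameters
    ----------
    model : CouplingModel
    n_trials : int
    seed : int or numpy.random.Generator
    envelope_corr_per_trial : ndarray (trials, N, N), optional
        Per-trial target matrices overriding ``model.envelope_corr``
        (used to plant a trial-varying network state).

    Returns
    -------
    EpochSet
        Deterministic for fixed inputs and seed.
    """
    rng = np.random.default_rng(seed)
    N = model.n_sources
    n_samp = int(round((epoch_window[1] - epoch_window[0]) * sample_rate))
    t = epoch_window[0] + np.arange(n_samp) / sample_rate

    shape = (n_trials, N, n_samp)
    if model.env_fast_frac > 0:
        # both timescales drawn in the spectral domain and combined before
        # a single inverse FFT (the components are independent processes)
        spec = _white_spectrum(shape, rng) * (
            np.sqrt(1.0 - model.env_fast_frac)
            * _unit_gain(n_samp, model.env_cutoff_hz, sample_rate)
        )
        spec += _white_spectrum(shape, rng) * (
            np.sqrt(model.env_fast_frac)
            * _unit_gain(n_samp, model.env_fast_cutoff_hz, sample_rate)
        )
        slow = np.fft.irfft(spec, n=n_samp, axis=-1)
        sd = slow.std(axis=-1, keepdims=True)
        slow /= np.where(sd > 0, sd, 1.0)
    else:
        slow = _slow_processes(shape, model.env_cutoff_hz, sample_rate, rng)

    if envelope_corr_per_trial is not None:
        mats = np.asarray(envelope_corr_per_trial, dtype=float)
        if mats.shape != (n_trials, N, N):
            raise ValueError("envelope_corr_per_trial must be (trials, N, N)")
        chols = np.empty_like(mats)
        for k in range(n_trials):
            chols[k] = np.linalg.cholesky(
                _validated_corr(mats[k], N) + 1e-10 * np.eye(N)
            )
        mixed = np.einsum("kij,kjt->kit", chols, slow)
    elif model.envelope_corr is not None:
        chol = np.linalg.cholesky(model.envelope_corr + 1e-10 * np.eye(N))
        mixed = np.einsum("ij,kjt->kit", chol, slow)
    else:
        mixed = slow

    log_env = model.log_env_sd * mixed
    envelope = np.exp(log_env)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_trials, N, 1))
    osc = envelope * np.cos(2.0 * np.pi * model.carrier_freq * t + phases)
    # unit average oscillation power: E[A^2]/2 with A log-normal
    osc /= np.sqrt(np.exp(2.0 * model.log_env_sd**2) / 2.0)

    noise = _pink_noise((n_trials, N, n_samp), rng)
    data = np.sqrt(model.snr) * osc + noise

    if model.mixing is not None:
        M = np.asarray(model.mixing, dtype=float)
        if M.shape != (N, N):
            raise ValueError("mixing must be (n_sources, n_sources)")
        data = np.einsum("ij,kjt->kit", M, data)

    return EpochSet(
        data=data,
        sample_rate=sample_rate,
        epoch_window=epoch_window,
        trial_table=trial_table,
    )


def simulate_behavior(
    model: CouplingModel,
    per_trial_stat,
    seed,
    target_accuracy: float = 0.70,
    no_response_rate: float | None = None,
    speed_floor: float = 0.05,
) -> pd.DataFrame:
    """Simulate trial-by-trial behavior coupled to a planted statistic.

    Decision speed is ``baseline + slope * z(stat) + noise`` (floored at a
    small positive value so response times stay positive), response time
    its reciprocal, and correctness Bernoulli with probability equal to
    the target accuracy.  A configurable fraction of trials has no
    response (missing response time).

    Parameters
    ----------
    model : CouplingModel
        Supplies ``behavior_slope``, ``behavior_noise_sd``,
        ``baseline_speed`` and the default no-response rate.
    per_trial_stat : array-like
        Planted network statistic per trial; must be finite.
    target_accuracy : float
        Mean accuracy the Bernoulli draws are calibrated to; must lie in
        (0.5, 1) -- above chance, below ceiling.

    Returns
    -------
    pandas.DataFrame
        Columns ``correct`` (0/1), ``response_time`` (s, NaN when no
        response), ``speed`` (1/s), ``planted_stat``.
    """
    stat = np.asarray(per_trial_stat, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("per_trial_stat must be finite")
    if not (0.5 < target_accuracy < 1.0):
        raise ValueError("target_accuracy must lie in (0.5, 1)")
    if no_response_rate is None:
        no_response_rate = model.no_response_rate
    rng = np.random.default_rng(seed)
    n = len(stat)
    sd = stat.std()
    z = (stat - stat.mean()) / sd if sd > 0 else np.zeros(n)
    speed = (
        model.baseline_speed
        + model.behavior_slope * z
        + model.behavior_noise_sd * rng.standard_normal(n)
    )
    speed = np.maximum(speed, speed_floor)
    rt = 1.0 / speed
    missing = rng.random(n) < no_response_rate
    rt[missing] = np.nan
    correct = (rng.random(n) < target_accuracy).astype(int)
    return pd.DataFrame(
        {
            "correct": correct,
            "response_time": rt,
            "speed": np.where(missing, np.nan, speed),
            "planted_stat": stat,
        }
    )


def leakage_mixing(n_sources: int, strength: float = 0.4) -> np.ndarray:
    """Mixing matrix leaking a fraction of source 1 into source 0 and back."""
    M = np.eye(n_sources)
    M[0, 1] = M[1, 0] = strength
    return M
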