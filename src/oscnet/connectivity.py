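"""Orthogonalized power-envelope correlations, all-to-all and per trial.

MEG source estimates of nearby locations share instantaneous signal
through field spread, which inflates naive envelope correlations.  Before
correlating, the coefficient series of one source is therefore
orthogonalized with respect to the other: only the component of ``y``
orthogonal to ``x`` at each time point contributes,

    P_orth(y|x)(t) = Im( y(t) * conj(x(t)) / |x(t)| )**2.

For every ordered source pair (i, j) the Pearson correlation between the
log power of i and the log orthogonalized power of j-given-i is computed
over the analysis time points of one trial; the two directions are then
averaged, yielding a symmetric source-by-source coupling matrix per trial
and frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral import TFRSet

logger = logging.getLogger(__name__)

EPS_REL = 1e-30


@dataclass
class ConnectivityStack:
    """Per-trial symmetric envelope-correlation matrices at one frequency."""

    corr: np.ndarray  # (trials, N, N), diagonal zero
    frequency: float
    n_timepoints_used: int

    @property
    def n_trials(self) -> int:
        return self.corr.shape[0]

    @property
    def n_sources(self) -> int:
        return self.corr.shape[1]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("corr", data=self.corr)
            h5.attrs["frequency"] = self.frequency
            h5.attrs["n_timepoints_used"] = self.n_timepoints_used

    @classmethod
    def from_hdf5(cls, path) -> "ConnectivityStack":
        import h5py

        with h5py.File(path, "r") as h5:
            return cls(
                corr=h5["corr"][()],
                frequency=float(h5.attrs["frequency"]),
                n_timepoints_used=int(h5.attrs["n_timepoints_used"]),
            )


def orthogonalize(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Power envelope of the component of ``y`` orthogonal to ``x``.

    Parameters
    ----------
    x, y : complex ndarray of equal length
        Spectral coefficient series at one frequency.

    Returns
    -------
    ndarray
        ``Im(y * conj(x) / |x|)**2`` per time point; NaN where ``|x| = 0``
        (those points are excluded from downstream correlations).
    """
    x = np.asarray(x, dtype=complex)
    y = np.asarray(y, dtype=complex)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mag = np.abs(x)
    out = np.full(x.shape, np.nan)
    ok = mag > 0
    out[ok] = np.imag(y[ok] * np.conj(x[ok]) / mag[ok]) ** 2
    return out


def _zscore_last(a: np.ndarray, warn: bool = False) -> np.ndarray:
    """Z-score along the last axis; constant series become all zeros."""
    mean = a.mean(axis=-1, keepdims=True)
    sd = a.std(axis=-1, keepdims=True)
    flat = sd == 0
    if warn and np.any(flat):
        logger.warning("constant envelope encountered; correlation recorded as 0")
    sd = np.where(flat, 1.0, sd)
    return (a - mean) / sd


def _envelope_corr_block(coeffs: np.ndarray, eps: float) -> np.ndarray:
    """Envelope correlations for a block of trials.

    coeffs: (trials, N, T) complex -> (trials, N, N) symmetric.
    Internally single precision: ample for correlation estimates and twice
    as fast on this all-pairs hot path.
    """
    coeffs = np.asarray(coeffs, dtype=np.complex64)
    mag = np.abs(coeffs)
    safe_mag = np.where(mag > 0, mag, 1.0)
    unit = coeffs / safe_mag
    log_pow = np.log(np.maximum(mag**2, eps))
    # orth[b, i, j, t]: imaginary part of y_j relative to the phase of x_i
    orth = np.imag(np.conj(unit)[:, :, None, :] * coeffs[:, None, :, :]) ** 2
    log_orth = np.log(np.maximum(orth, eps))
    zx = _zscore_last(log_pow, warn=True)
    # the diagonal of log_orth is constant by construction (a source is
    # fully collinear with itself); only off-diagonal constants are odd
    off = ~np.eye(coeffs.shape[1], dtype=bool)
    if np.any(log_orth.std(axis=-1)[:, off] == 0):
        logger.warning("constant orthogonalized envelope; correlation recorded as 0")
    zo = _zscore_last(log_orth)
    r = np.einsum("bit,bijt->bij", zx, zo).astype(np.float64) / coeffs.shape[-1]
    r = 0.5 * (r + np.transpose(r, (0, 2, 1)))
    for b in range(r.shape[0]):
        np.fill_diagonal(r[b], 0.0)
    return np.clip(r, -1.0, 1.0)


def envelope_corr_trial(
    coeffs: np.ndarray, frequency: float = np.nan, eps_rel: float = EPS_REL
) -> np.ndarray:
    """Symmetric envelope-correlation matrix for one trial.

    Parameters
    ----------
    coeffs : complex ndarray, shape (sources, times)
        Wavelet coefficients of all sources at one frequency, one trial.
    frequency : float
        Informational only.
    eps_rel : float
        Relative floor applied before taking logs.

    Returns
    -------
    ndarray, shape (N, N)
        Values in [-1, 1]; diagonal zero.  With N sources the matrix holds
        N(N-1)/2 unique couplings.
    """
    coeffs = np.asarray(coeffs, dtype=complex)
    if coeffs.ndim != 2:
        raise ValueError("coeffs must have shape (sources, times)")
    if coeffs.shape[1] < 10:
        raise ValueError("at least 10 time points are required")
    pmax = (np.abs(coeffs) ** 2).max()
    eps = eps_rel * pmax if pmax > 0 else eps_rel
    return _envelope_corr_block(coeffs[None], eps)[0]


def envelope_correlations(
    tfr: TFRSet,
    frequency: float,
    trials=None,
    eps_rel: float = EPS_REL,
    block_size: int = 16,
) -> ConnectivityStack:
    """All-to-all orthogonalized envelope correlations for every trial.

    Parameters
    ----------
    tfr : TFRSet
    frequency : float
        One of the grid frequencies.
    trials : sequence of int, optional
        Subset of trials; defaults to all.
    block_size : int
        Trials processed per vectorized block (memory/speed trade-off).

    Returns
    -------
    ConnectivityStack
    """
    fi = tfr.freq_index(frequency)
    coeffs = tfr.coeffs[:, :, fi, :]
    if trials is not None:
        coeffs = coeffs[np.asarray(trials)]
    n_trials, n_sources, n_t = coeffs.shape
    if n_t < 10:
        raise ValueError("at least 10 time points are required")
    pmax = (np.abs(coeffs) ** 2).max()
    eps = eps_rel * pmax if pmax > 0 else eps_rel
    out = np.empty((n_trials, n_sources, n_sources))
    for start in range(0, n_trials, block_size):
        blk = coeffs[start : start + block_size]
        out[start : start + len(blk)] = _envelope_corr_block(blk, eps)
    return ConnectivityStack(out, float(tfr.freqs[fi]), n_t)


def naive_envelope_corr_trial(coeffs: np.ndarray, eps_rel: float = EPS_REL) -> np.ndarray:
    """Plain (non-orthogonalized) log-power correlation matrix for one trial.

    Retained for leakage comparisons: under instantaneous linear mixing of
    independent sources this estimator is inflated, whereas the
    orthogonalized one is not.
    """
    coeffs = np.asarray(coeffs, dtype=complex)
    power = np.abs(coeffs) ** 2
    pmax = power.max()
    eps = eps_rel * pmax if pmax > 0 else eps_rel
    z = _zscore_last(np.log(np.maximum(power, eps)))
    r = (z @ z.T) / coeffs.shape[-1]
    np.fill_diagonal(r, 0.0)
    return np.clip(r, -1.0, 1.0)
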