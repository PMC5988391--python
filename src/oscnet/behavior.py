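"""Behavioral time series and the behavior-versus-acoustics regression.

Raw per-trial responses (binary correctness, response times) are turned
into two trial-resolved series: a moving-average accuracy (rectangular
window of four trials) and decision speed, defined as the reciprocal of
response time.  Trials without a response are flagged invalid and excluded
downstream.

Because response-time distributions are positively skewed, all regressions
here operate on rank-transformed, z-scored variables; with a single
predictor the resulting OLS weight is exactly Spearman's rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class BehaviorSeries:
    """Trial-resolved behavioral series for one subject and task."""

    accuracy_series: np.ndarray
    speed_series: np.ndarray  # NaN on trials without a response
    valid_mask: np.ndarray


def moving_accuracy(correct, window: int = 4, center: bool = True) -> np.ndarray:
    """Moving average of binary correctness with a unit-height rectangular window.

    Edges use a shrinking (partial) window so the output has the same
    length as the input.

    Parameters
    ----------
    correct : array-like of {0, 1}
    window : int
        Window length in trials; must satisfy ``1 <= window <= len(correct)``.
    center : bool
        Centered alignment (default); set False for a trailing window.
    """
    x = pd.Series(np.asarray(correct, dtype=float))
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(x):
        raise ValueError(
            f"window ({window}) exceeds series length ({len(x)})"
        )
    return x.rolling(window, center=center, min_periods=1).mean().to_numpy()


def decision_speed(rt) -> np.ndarray:
    """Decision speed, ``1 / response_time``, with NaN for missing responses.

    Parameters
    ----------
    rt : array-like of seconds
        Response times; NaN marks trials without a response.

    Raises
    ------
    ValueError
        If any recorded response time is non-positive.
    """
    rt = np.asarray(rt, dtype=float)
    finite = np.isfinite(rt)
    if np.any(rt[finite] <= 0):
        raise ValueError("response times must be positive")
    speed = np.full_like(rt, np.nan)
    speed[finite] = 1.0 / rt[finite]
    return speed


def valid_mask(rt) -> np.ndarray:
    """Boolean mask of trials on which a response was given."""
    return np.isfinite(np.asarray(rt, dtype=float))


def rank_z(x) -> np.ndarray:
    """Rank-transform then z-score a series.

    Ties receive average ranks; z-scoring uses the population (n)
    denominator.  Non-finite entries are ignored for ranking and returned
    as NaN.  A constant input yields all zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    if mask.sum() < 3:
        raise ValueError("rank_z requires at least 3 finite values")
    ranks = sps.rankdata(x[mask])
    sd = ranks.std()
    if sd == 0:
        warnings.warn("constant input to rank_z; returning zeros")
        out[mask] = 0.0
    else:
        out[mask] = (ranks - ranks.mean()) / sd
    return out


def _design_matrix(features: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = list(features.columns)
    cols = [rank_z(features[c].to_numpy()) for c in names]
    X = np.column_stack([np.ones(len(features))] + cols)
    return X, names


def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    bad = []
    cc = np.corrcoef(X[:, 1:], rowvar=False)
    cc = np.atleast_2d(cc)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(cc[i, j]) > 1 - 1e-12:
                bad.append(f"{names[i]}~{names[j]}")
    raise ValueError(
        "rank-deficient design matrix; collinear columns: "
        + (", ".join(bad) if bad else "unidentified")
    )


def behavior_vs_acoustics(y, features: pd.DataFrame) -> pd.Series:
    """Per-subject regression of behavior on acoustic features.

    The dependent variable and each feature (typically the stimulus
    spectral center and coherence) are rank-transformed and z-scored, then
    fit by ordinary least squares with an intercept.  With a single
    predictor the returned weight equals Spearman's rho.

    Parameters
    ----------
    y : array-like
        Behavioral series (accuracy moving average or decision speed).
        NaN entries (e.g., no-response trials) are dropped together with
        the matching feature rows.
    features : pandas.DataFrame
        One column per acoustic feature, aligned with ``y``.

    Returns
    -------
    pandas.Series
        Standardized weight per feature (intercept omitted).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(features):
        raise ValueError("y and features must be aligned")
    keep = np.isfinite(y)
    feats = features.loc[keep].reset_index(drop=True)
    X, names = _design_matrix(feats)
    _check_collinear(X, names)
    yz = rank_z(y[keep])
    beta, *_ = np.linalg.lstsq(X, yz, rcond=None)
    return pd.Series(beta[1:], index=names, name="weight")


def group_behavior_vs_acoustics(
    per_subject: list[pd.Series], n_perm: int = 10000, seed=0
) -> pd.DataFrame:
    """Group-level mean weights with one-sample permutation (sign-flip) p values."""
    from . import stats as oscstats

    table = pd.DataFrame(per_subject)
    rows = []
    for name in table.columns:
        vals = table[name].to_numpy()
        mean, p = oscstats.permutation_one_sample(vals, n_perm=n_perm, seed=seed)
        rows.append({"feature": name, "mean_weight": mean, "p": p})
    return pd.DataFrame(rows)
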