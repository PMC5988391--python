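"""Two-level neurobehavioral GLM with a circular-shift permutation null.

Per subject, a behavioral series (decision speed or moving-average
accuracy) is regressed on one neural regressor -- oscillatory power or a
network metric -- controlling for the acoustic features of the stimuli.
All variables are rank-transformed and z-scored first, so the whole layer
is invariant to strictly monotone transforms of the inputs and, with a
single predictor, the subject-level weight equals Spearman's rho.

Group inference never uses parametric statistics: the observed group-mean
weight is compared with a null distribution built by circularly shifting
each subject's behavioral series by k = 1..n_shifts trials (wrap-around)
and refitting.  Circular shifting preserves the series' autocorrelation.
Significance is a two-sided percentile test (outside the 2.5th-97.5th
percentiles at alpha = 0.05).  Across frequency bins (or source
locations) the selection is corrected with the false coverage-statement
rate (FCR): confidence intervals of first-pass selections are rebuilt at
level ``1 - Fs * q / Ft`` and only selections still excluded survive.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .behavior import rank_z

DEFAULT_N_SHIFTS = 350
DEFAULT_ALPHA = 0.05
DEFAULT_Q = 0.05


def _design(x, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(x)), rank_z(x)]
    names = ["x"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            cols.append(rank_z(cov[c].to_numpy()))
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        cc = np.atleast_2d(np.corrcoef(X[:, 1:], rowvar=False))
        bad = [
            f"{names[i]}~{names[j]}"
            for i in range(cc.shape[0])
            for j in range(i + 1, cc.shape[0])
            if abs(cc[i, j]) > 1 - 1e-12
        ]
        raise ValueError(
            "rank-deficient design; collinear columns: "
            + (", ".join(bad) if bad else "unidentified")
        )
    return X, names


def _valid_rows(y, x, covariates):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates).loc[keep].reset_index(drop=True)
    return y[keep], x[keep], cov


def subject_glm(y, x, covariates=None) -> float:
    """Standardized weight of ``x`` in a rank-z GLM of ``y`` for one subject.

    Parameters
    ----------
    y : array-like
        Behavioral series; NaN entries (no-response trials) are dropped
        together with the matching rows of ``x`` and the covariates.
    x : array-like
        Neural regressor (power or a network-metric series).
    covariates : DataFrame / dict of array-like, optional
        Acoustic features controlled for (spectral center, coherence).

    Returns
    -------
    float
        OLS weight of ``x`` after rank-z transforming every variable;
        equals Spearman's rho when no covariates are given.
    """
    yv, xv, cov = _valid_rows(y, x, covariates)
    if len(yv) < 10:
        raise ValueError("at least 10 aligned valid trials are required")
    X, _ = _design(xv, cov)
    beta, *_ = np.linalg.lstsq(X, rank_z(yv), rcond=None)
    return float(beta[1])


def glm_with_null(
    y_per_subject,
    x_per_subject,
    covariates_per_subject=None,
    n_shifts: int = DEFAULT_N_SHIFTS,
):
    """Group-mean weight and its circular-shift null distribution.

    For shift k = 1..n_shifts the same offset k is applied to every
    subject's behavioral series with wrap-around, the subject GLMs are
    refit and the group mean recomputed.  Subjects' valid-trial series
    are truncated to the common minimum length so one offset is
    meaningful for every subject.  Rank transformation commutes with
    circular shifting, so shifts are applied to the rank-z series.

    Parameters
    ----------
    y_per_subject, x_per_subject : list of array-like
    covariates_per_subject : list of DataFrame-like, optional
    n_shifts : int
        Must not exceed the common valid-trial count minus one.

    Returns
    -------
    (group_beta, subject_betas, null)
        ``group_beta`` float, ``subject_betas`` shape (S,), ``null``
        shape (n_shifts,) of null group means.
    """
    n_subj = len(y_per_subject)
    if covariates_per_subject is None:
        covariates_per_subject = [None] * n_subj
    valid = [
        _valid_rows(y, x, c)
        for y, x, c in zip(y_per_subject, x_per_subject, covariates_per_subject)
    ]
    L = min(len(v[0]) for v in valid)
    if n_shifts > L - 1:
        raise ValueError(
            f"n_shifts ({n_shifts}) exceeds the common trial count minus one ({L - 1})"
        )
    shifts = np.arange(1, n_shifts + 1)
    roll_idx = (np.arange(L)[None, :] + shifts[:, None]) % L
    betas = np.empty(n_subj)
    null = np.zeros(n_shifts)
    for s, (yv, xv, cov) in enumerate(valid):
        yv = yv[:L]
        cov = None if cov is None else cov.iloc[:L]
        X, _ = _design(xv[:L], cov)
        p_row = np.linalg.pinv(X)[1]  # row extracting the weight of x
        yz = rank_z(yv)
        betas[s] = float(p_row @ yz)
        null += yz[roll_idx] @ p_row
    null /= n_subj
    return float(betas.mean()), betas, null


def circular_null(
    y_per_subject,
    x_per_subject,
    covariates_per_subject=None,
    n_shifts: int = DEFAULT_N_SHIFTS,
) -> np.ndarray:
    """Null distribution of the group-mean weight under circular shifting.

    Convenience wrapper around :func:`glm_with_null` returning only the
    ``n_shifts`` null group means.
    """
    return glm_with_null(
        y_per_subject, x_per_subject, covariates_per_subject, n_shifts
    )[2]


def significance(
    observed: float, null: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> tuple[bool, tuple[float, float]]:
    """Two-sided percentile test of an observed value against its null.

    Returns
    -------
    (significant, (lower, upper))
        ``significant`` is True iff the observed value lies above the
        ``1 - alpha/2`` or below the ``alpha/2`` percentile of the null.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return bool(observed > hi or observed < lo), (float(lo), float(hi))


def fcr_correct(
    observed: np.ndarray,
    nulls: np.ndarray,
    q: float = DEFAULT_Q,
    Ft: int | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """False coverage-statement rate correction across tested parameters.

    Pass 1 selects parameters whose ``1 - alpha`` null confidence interval
    excludes the observed value.  Pass 2 rebuilds the intervals of the
    ``Fs`` selected parameters at level ``1 - Fs * q / Ft`` and keeps only
    those still excluded.

    Parameters
    ----------
    observed : ndarray (F,)
        Observed group-mean weights, one per frequency bin (or source).
    nulls : ndarray (F, n_shifts)
        Matching null distributions.
    q : float
        Tolerated false coverage-statement rate.
    Ft : int, optional
        Total number of parameters tested; defaults to ``len(observed)``
        and must be at least that.

    Returns
    -------
    pandas.DataFrame
        Columns ``observed, null_lo, null_hi, selected, fcr_level,
        null_lo_fcr, null_hi_fcr, significant``.
    """
    observed = np.asarray(observed, dtype=float)
    nulls = np.asarray(nulls, dtype=float)
    if nulls.shape[0] != len(observed):
        raise ValueError("nulls must have one row per observed value")
    if Ft is None:
        Ft = len(observed)
    if Ft < len(observed):
        raise ValueError("Ft must be at least the number of results")
    lo = np.percentile(nulls, 100 * alpha / 2, axis=1)
    hi = np.percentile(nulls, 100 * (1 - alpha / 2), axis=1)
    selected = (observed > hi) | (observed < lo)
    fs = int(selected.sum())
    if fs == 0:
        level = 1.0 - alpha
        lo_f, hi_f = lo.copy(), hi.copy()
        significant = selected.copy()
    else:
        adj_alpha = fs * q / Ft
        level = 1.0 - adj_alpha
        lo_f = np.percentile(nulls, 100 * adj_alpha / 2, axis=1)
        hi_f = np.percentile(nulls, 100 * (1 - adj_alpha / 2), axis=1)
        significant = selected & ((observed > hi_f) | (observed < lo_f))
    return pd.DataFrame(
        {
            "observed": observed,
            "null_lo": lo,
            "null_hi": hi,
            "selected": selected,
            "fcr_level": level,
            "null_lo_fcr": lo_f,
            "null_hi_fcr": hi_f,
            "significant": significant,
        }
    )


def task_contrast(
    betas_a: np.ndarray,
    betas_b: np.ndarray,
    null_a: np.ndarray,
    null_b: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    q: float = DEFAULT_Q,
    Ft: int | None = None,
):
    """Paired task contrast ``mean(beta_a - beta_b)`` against a shift null.

    The null of differences pairs the two tasks' circular-shift null
    distributions shift-by-shift (the same offset is applied to both).

    Parameters
    ----------
    betas_a, betas_b : ndarray (S,) or (S, R)
        Per-subject weights for the two tasks (paired); an optional
        trailing axis indexes regions/sources.
    null_a, null_b : ndarray (n_shifts,) or (R, n_shifts)
        Null distributions of the two tasks' group means.
    Ft : int, optional
        For the regional variant, the total number of locations used by
        the FCR correction.

    Returns
    -------
    For scalar inputs ``(mean_diff, significant, (lo, hi))``; for the
    regional variant a :class:`pandas.DataFrame` from :func:`fcr_correct`.
    """
    betas_a = np.asarray(betas_a, dtype=float)
    betas_b = np.asarray(betas_b, dtype=float)
    if betas_a.shape != betas_b.shape:
        raise ValueError("task weights must be paired (equal shapes)")
    diff = (betas_a - betas_b).mean(axis=0)
    null_diff = np.asarray(null_a, dtype=float) - np.asarray(null_b, dtype=float)
    if np.ndim(diff) == 0:
        flag, ci = significance(float(diff), null_diff, alpha=alpha)
        return float(diff), flag, ci
    return fcr_correct(diff, null_diff, q=q, Ft=Ft, alpha=alpha)


def crosscorr_lag(behavior, metric, max_lag: int) -> pd.DataFrame:
    """Rank-based cross-correlation of two trial series at integer lags.

    The value at lag ``l`` is the Spearman correlation between
    ``behavior[t]`` and ``metric[t + l]`` over the overlapping trials:
    a peak at positive lag means the metric series trails behavior.  At
    lag 0 the value equals the single-predictor :func:`subject_glm`
    weight.

    Returns
    -------
    pandas.DataFrame with columns ``lag`` and ``r``.
    """
    b = np.asarray(behavior, dtype=float)
    m = np.asarray(metric, dtype=float)
    if len(b) != len(m):
        raise ValueError("series must be aligned")
    rows = []
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            bb, mm = b[: len(b) - lag], m[lag:]
        else:
            bb, mm = b[-lag:], m[: len(m) + lag]
        keep = np.isfinite(bb) & np.isfinite(mm)
        r = float(np.mean(rank_z(bb[keep]) * rank_z(mm[keep])))
        rows.append({"lag": lag, "r": r})
    return pd.DataFrame(rows)


def permutation_one_sample(
    values: np.ndarray, n_perm: int = 10000, seed=0
) -> tuple[float, float]:
    """One-sample permutation (sign-flip) test of a mean against zero.

    Enumerates all ``2**n`` sign patterns when feasible (exact test),
    otherwise draws ``n_perm`` random patterns.

    Returns
    -------
    (mean, p) : two-sided p value of the observed mean.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    obs = values.mean()
    if 2**n <= n_perm:
        signs = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm_means = signs @ values / n
    p = float(np.mean(np.abs(perm_means) >= abs(obs) - 1e-15))
    return float(obs), p
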