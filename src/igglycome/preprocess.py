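"""Variance stabilization and batch correction of abundance/trait tables.

Relative glycan abundances are right-skewed, so tables are natural-log
transformed before modelling.  Plate (batch) effects are removed with a
parametric empirical-Bayes location/scale correction: each feature is
standardized against a model that protects biological covariates, batch
locations and scales are estimated per feature, shrunk across features
via a normal prior on locations and an inverse-gamma prior on scales
(solved by the standard iterative fixed point), and the data are
adjusted and back-transformed.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["log_transform", "combat_adjust", "batch_f_pvalues"]


def log_transform(tab: pd.DataFrame, zero_policy: str = "half-minimum") -> pd.DataFrame:
    """Element-wise natural log.

    Zeros are handled by the half-minimum offset: within each column,
    exact zeros are replaced by half the smallest positive value before
    taking logs.  Negative values are rejected.
    """
    values = tab.to_numpy(dtype=float).copy()
    if (values < 0).any():
        bad = tab.columns[(values < 0).any(axis=0)]
        raise ValueError(f"negative values cannot be log-transformed: {list(bad)}")
    if zero_policy not in ("half-minimum", "error"):
        raise ValueError("zero_policy must be 'half-minimum' or 'error'")
    if (values == 0).any():
        if zero_policy == "error":
            raise ValueError("zeros present and zero_policy='error'")
        for j in range(values.shape[1]):
            col = values[:, j]
            zero = col == 0
            if zero.any():
                positive = col[col > 0]
                if positive.size == 0:
                    raise ValueError(
                        f"column {tab.columns[j]!r} is all zeros; cannot offset")
                col[zero] = positive.min() / 2.0
    return pd.DataFrame(np.log(values), index=tab.index, columns=tab.columns)


def _design_matrix(batch: pd.Series, covariates: pd.DataFrame | None) -> np.ndarray:
    batches = pd.Categorical(batch)
    design = pd.get_dummies(batches, dtype=float).to_numpy()
    if covariates is not None:
        cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
        design = np.hstack([design, cov.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "batch/covariate design is rank deficient (a covariate is "
            "confounded with batch)")
    return design


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def combat_adjust(tab: pd.DataFrame, batch: pd.Series,
                  covariates: pd.DataFrame | None = None,
                  parametric: bool = True,
                  conv: float = 1e-6, max_iter: int = 200) -> pd.DataFrame:
    """Parametric empirical-Bayes batch correction of a samples x features
    table (log scale in, log scale out).

    ``covariates`` are protected: their effects enter the standardization
    model and are restored after adjustment.  Batches with a single sample
    cannot support a scale estimate; they fall back to location-only
    correction with a warning.
    """
    if not parametric:
        raise NotImplementedError("only the parametric variant is implemented")
    batch = batch.reindex(tab.index)
    if batch.isna().any():
        missing = tab.index[batch.isna()]
        raise ValueError(f"samples without a batch label: {list(missing[:5])}")
    if covariates is not None:
        covariates = covariates.reindex(tab.index)

    dat = tab.to_numpy(dtype=float).T      # features x samples
    n_features, n_array = dat.shape
    levels = pd.Categorical(batch).categories
    batch_idx = [np.flatnonzero((batch == lv).to_numpy()) for lv in levels]
    n_batches = np.array([len(ix) for ix in batch_idx])
    if (n_batches == 0).any():
        raise ValueError("empty batch level")
    singleton = n_batches < 2
    if singleton.any():
        warnings.warn(
            f"batch(es) {[levels[i] for i in np.flatnonzero(singleton)]} have a "
            "single sample; falling back to location-only correction there")

    design = _design_matrix(batch, covariates)
    n_batch = len(levels)

    # feature-wise OLS on the full design; grand mean is the sample-size
    # weighted combination of batch intercepts
    b_hat, *_ = np.linalg.lstsq(design, dat.T, rcond=None)
    grand_mean = (n_batches / n_array) @ b_hat[:n_batch]
    resid = dat - (design @ b_hat).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, np.finfo(float).tiny, var_pooled)

    stand_mean = np.outer(grand_mean, np.ones(n_array))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + (design[:, n_batch:] @ b_hat[n_batch:]).T
    s_data = (dat - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.column_stack([s_data[:, ix].mean(axis=1) for ix in batch_idx])
    delta_hat = np.column_stack([
        s_data[:, ix].var(axis=1, ddof=1) if len(ix) > 1 else np.ones(n_features)
        for ix in batch_idx])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i in range(n_batch):
        g_hat = gamma_hat[:, i]
        d_hat = delta_hat[:, i]
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1) if n_features > 1 else 1.0
        m = d_hat.mean()
        s2 = d_hat.var(ddof=1) if n_features > 1 else 1.0
        if s2 <= 0:
            s2 = np.finfo(float).tiny
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        n_i = n_batches[i]
        g_new, d_new = g_hat.copy(), d_hat.copy()
        for _ in range(max_iter):
            g_next = _postmean(g_hat, g_bar, n_i, d_new, t2)
            sum2 = ((s_data[:, batch_idx[i]] - g_next[:, None]) ** 2).sum(axis=1)
            d_next = _postvar(sum2, n_i, a_prior, b_prior)
            change = max(np.max(np.abs(g_next - g_new) / np.maximum(np.abs(g_new), 1e-12)),
                         np.max(np.abs(d_next - d_new) / np.maximum(np.abs(d_new), 1e-12)))
            g_new, d_new = g_next, d_next
            if change < conv:
                break
        gamma_star[:, i] = g_new
        delta_star[:, i] = np.ones(n_features) if singleton[i] else d_new

    bayes = s_data.copy()
    for i, ix in enumerate(batch_idx):
        bayes[:, ix] = (bayes[:, ix] - gamma_star[:, [i]]) \
            / np.sqrt(delta_star[:, [i]])
    corrected = bayes * np.sqrt(var_pooled)[:, None] + stand_mean
    return pd.DataFrame(corrected.T, index=tab.index, columns=tab.columns)


def batch_f_pvalues(tab: pd.DataFrame, batch: pd.Series) -> pd.Series:
    """Per-feature one-way ANOVA p-value for between-batch mean differences."""
    from scipy import stats
    batch = batch.reindex(tab.index)
    groups = [tab[batch == lv] for lv in pd.Categorical(batch).categories]
    out = {}
    for col in tab.columns:
        out[col] = stats.f_oneway(*[g[col].to_numpy() for g in groups]).pvalue
    return pd.Series(out)
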