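"""Connectome Predictive Modelling (CPM) comparator.

CPM is a deliberately simple mass-univariate predictor: in the training
sample, edges whose Pearson correlation with the outcome reaches
p < 0.05 (two-sided, uncorrected — the screen is internal to the model)
are selected; the outcome is then regressed on the per-observation
*mean* of the selected edge values; the same edge set and line predict
the held-out sample, scored by PRESS.

Positively and negatively correlated edges are pooled into one mean by
default.  The classical variant that builds separate positive- and
negative-network sums is available via ``split_sign=True``.  Covariates
are not used: the comparison against the PCA-regression model is run on
the connectivity data alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ssm_core import PressResult, press

__all__ = ["CpmModel", "screen_edges", "cpm_fit", "cpm_predict", "cpm_predict_press"]

logger = logging.getLogger(__name__)


def _edge_corr_pvalues(edges: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of every edge (row) against y, vectorized."""
    n = y.size
    ym = y - y.mean()
    em = edges - edges.mean(axis=1, keepdims=True)
    denom = np.sqrt((em**2).sum(axis=1) * (ym**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (em @ ym) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = np.nan
    p[np.isinf(t)] = 0.0
    return r, p


def screen_edges(train: np.ndarray, y: np.ndarray, p_threshold: float = 0.05) -> np.ndarray:
    """Mass-univariate screen: indices of edges correlating with y at p < threshold.

    Parameters
    ----------
    train : (edges, observations) array
    y : (observations,) outcome, no missing values
    """
    train = np.asarray(train, dtype=float)
    y = np.asarray(y, dtype=float)
    if train.ndim != 2 or train.shape[1] != y.size:
        raise ValueError("train must be (edges, observations) aligned with y")
    if y.size < 4:
        raise ValueError("screening requires at least 4 observations")
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    _, p = _edge_corr_pvalues(train, y)
    dead = ~np.isfinite(p)
    if dead.any():
        logger.warning("excluding %d zero-variance edge(s) from the screen", dead.sum())
    return np.flatnonzero(np.isfinite(p) & (p < p_threshold))


@dataclass
class CpmModel:
    """Fitted CPM: selected edge set plus a simple regression line.

    When the screen selects nothing the model falls back to predicting
    the training-sample mean outcome (slope 0).
    """

    selected_edges: np.ndarray
    slope: float
    intercept: float
    p_threshold: float = 0.05
    # split-sign variant: separate coefficients for the positive- and
    # negative-edge means; None for the pooled default
    split_beta: np.ndarray | None = field(default=None, repr=False)
    positive_edges: np.ndarray | None = field(default=None, repr=False)
    negative_edges: np.ndarray | None = field(default=None, repr=False)

    @property
    def is_fallback(self) -> bool:
        return self.selected_edges.size == 0


def _mean_feature(edges: np.ndarray, selected: np.ndarray) -> np.ndarray:
    return edges[selected].mean(axis=0)


def cpm_fit(
    train: np.ndarray,
    y: np.ndarray,
    selected: np.ndarray,
    p_threshold: float = 0.05,
    split_sign: bool = False,
) -> CpmModel:
    """Regress the outcome on the mean of the selected edge values."""
    train = np.asarray(train, dtype=float)
    y = np.asarray(y, dtype=float)
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        logger.warning("empty edge selection; falling back to the mean-outcome model")
        return CpmModel(selected_edges=selected, slope=0.0,
                        intercept=float(y.mean()), p_threshold=p_threshold)
    if split_sign:
        r, _ = _edge_corr_pvalues(train[selected], y)
        pos = selected[r >= 0]
        neg = selected[r < 0]
        cols = [np.ones_like(y)]
        for idx in (pos, neg):
            if idx.size:
                cols.append(_mean_feature(train, idx))
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return CpmModel(selected_edges=selected, slope=float("nan"),
                        intercept=float(beta[0]), p_threshold=p_threshold,
                        split_beta=beta, positive_edges=pos, negative_edges=neg)
    x = _mean_feature(train, selected)
    res = stats.linregress(x, y)
    return CpmModel(selected_edges=selected, slope=float(res.slope),
                    intercept=float(res.intercept), p_threshold=p_threshold)


def cpm_predict(test: np.ndarray, model: CpmModel) -> np.ndarray:
    """Apply the fitted line to held-out observations."""
    test = np.asarray(test, dtype=float)
    if model.is_fallback:
        return np.full(test.shape[1], model.intercept)
    if model.split_beta is not None:
        cols = [np.ones(test.shape[1])]
        for idx in (model.positive_edges, model.negative_edges):
            if idx is not None and idx.size:
                cols.append(_mean_feature(test, idx))
        return np.column_stack(cols) @ model.split_beta
    return model.intercept + model.slope * _mean_feature(test, model.selected_edges)


def cpm_predict_press(test: np.ndarray, y2: np.ndarray, model: CpmModel) -> PressResult:
    """Predict the held-out outcomes and score with PRESS."""
    return press(cpm_predict(test, model), y2)
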