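"""Scaled Subprofile Modelling: PCA regression for brain-behavior prediction.

The recipe, applied identically to every modality:

1. Principal components ``V`` are extracted from the *training* data
   array (variables x observations) without removing the grand mean.
2. The cognitive outcome is regressed on the leading ``N`` component
   scores plus the demographic covariates (age, education, sex) and an
   intercept: ``Y1 = [DATA1' V(:,1:N)  COV1  1] beta``.
3. ``N`` is chosen by minimizing AIC over the contiguous candidate sets
   ``1:N`` on the training sample only.
4. Held-out observations are projected onto the same training basis and
   predicted; performance is the mean squared prediction error (PRESS,
   ``<(pY2 - Y2)^2>``).
5. The variable-space predictive pattern is ``V(:,1:N) beta(1:N)``.

``N = 0`` degenerates to the covariates-only Reference model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import ObservationArray

__all__ = [
    "PcBasis",
    "SsmModel",
    "PressResult",
    "VarianceSpectrum",
    "fit_pca",
    "expression_scores",
    "fit_ssm",
    "select_n_aic",
    "predict",
    "press",
    "derive_pattern",
    "variance_spectrum",
]

DEFAULT_N_MAX = 50


def _values(data) -> np.ndarray:
    if isinstance(data, ObservationArray):
        return np.asarray(data.values, dtype=float)
    return np.asarray(data, dtype=float)


@dataclass
class PcBasis:
    """Orthonormal principal-component basis of a training array.

    ``V`` holds one variables-space component per column; eigenvalues are
    the squared singular values divided by the number of observations,
    sorted descending.  ``mean_removed`` records whether the grand mean
    pattern was subtracted before the decomposition (off by default: the
    mean pattern is left in and typically dominates the first component).
    """

    V: np.ndarray
    eigenvalues: np.ndarray
    mean_removed: bool = False
    mean_: np.ndarray | None = field(default=None, repr=False)

    @property
    def rank(self) -> int:
        return self.V.shape[1]


def fit_pca(data, remove_mean: bool = False) -> PcBasis:
    """Principal components of a variables x observations array via SVD."""
    X = _values(data)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("PCA requires a 2-D array with at least 2 observations")
    if not np.any(X):
        raise ValueError("PCA of an all-zero array is undefined")
    mean = None
    if remove_mean:
        mean = X.mean(axis=1, keepdims=True)
        X = X - mean
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else slice(0)
    U, s = U[:, keep], s[keep]
    eig = s**2 / X.shape[1]
    return PcBasis(V=U, eigenvalues=eig, mean_removed=remove_mean,
                   mean_=None if mean is None else mean.ravel())


def expression_scores(data, basis: PcBasis, n: int) -> np.ndarray:
    """Project observations onto the first ``n`` components: ``DATA' V(:,1:n)``.

    Works identically for training data and held-out data; the basis is
    never refit.  ``n = 0`` returns an empty score matrix (Reference
    model path).
    """
    X = _values(data)
    if X.shape[0] != basis.V.shape[0]:
        raise ValueError(
            f"variable space mismatch: data has {X.shape[0]} variables, "
            f"basis has {basis.V.shape[0]}"
        )
    if n > basis.rank:
        raise ValueError(f"n={n} exceeds basis rank {basis.rank}")
    if basis.mean_removed and basis.mean_ is not None:
        X = X - basis.mean_[:, None]
    return X.T @ basis.V[:, :n]


@dataclass
class SsmModel:
    """A fitted SSM prediction model.

    ``beta`` is ordered [N component slopes, covariates in the order
    given at fit time, intercept]; ``n_components = 0`` is the
    covariates-only Reference model.
    """

    basis: PcBasis
    n_components: int
    beta: np.ndarray
    n_covariates: int = 3

    def __post_init__(self):
        expected = self.n_components + self.n_covariates + 1
        if self.beta.size != expected:
            raise ValueError(
                f"beta length {self.beta.size} != N + covariates + 1 = {expected}"
            )


def _design(scores: np.ndarray, cov: np.ndarray | None, n_obs: int) -> np.ndarray:
    parts = [scores]
    if cov is not None:
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n_obs:
            raise ValueError("covariate rows must match observations")
        parts.append(cov)
    parts.append(np.ones((n_obs, 1)))
    return np.hstack(parts)


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # identify which columns are linearly dependent on the preceding ones
        bad = []
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                bad.append(j - 1)
        raise np.linalg.LinAlgError(
            f"rank-deficient design matrix; collinear columns {bad}"
        )
    return beta


def fit_ssm(train, y, cov, n: int, basis: PcBasis | None = None,
            remove_mean: bool = False) -> SsmModel:
    """Fit the SSM regression with a fixed number of components ``n``.

    The PCA uses *all* training observations; rows with a missing
    outcome are excluded from the regression only.  Pass a precomputed
    ``basis`` to avoid refitting the PCA when scanning over ``n``.
    """
    if basis is None:
        basis = fit_pca(train, remove_mean=remove_mean)
    scores = expression_scores(train, basis, n)
    y = np.asarray(y, dtype=float)
    X = _design(scores, cov, y.size)
    valid = np.isfinite(y)
    if valid.sum() <= X.shape[1]:
        raise ValueError("too few observations with outcomes for the design size")
    beta = _ols(X[valid], y[valid])
    n_cov = X.shape[1] - n - 1
    return SsmModel(basis=basis, n_components=n, beta=beta, n_covariates=n_cov)


def _aic(rss: float, n_obs: int, k: int) -> float:
    rss = max(rss, np.finfo(float).tiny)
    return n_obs * np.log(rss / n_obs) + 2 * k


def select_n_aic(train, y, cov, n_max: int = DEFAULT_N_MAX,
                 basis: PcBasis | None = None,
                 remove_mean: bool = False,
                 return_aic: bool = False):
    """Choose the component count ``N`` minimizing AIC on the training set.

    Candidate sets are the contiguous leading sets ``1:N`` for
    ``N in 1..n_max``; ``AIC = n ln(RSS/n) + 2k`` with
    ``k = N + covariates + intercept + error variance``.  Ties break
    toward smaller ``N``.
    """
    if basis is None:
        basis = fit_pca(train, remove_mean=remove_mean)
    y = np.asarray(y, dtype=float)
    valid = np.isfinite(y)
    n_obs = int(valid.sum())
    n_max = int(min(n_max, basis.rank, n_obs - 5))
    if n_max < 1:
        raise ValueError("not enough observations or rank to select any component")
    scores = expression_scores(train, basis, n_max)
    yv = y[valid]
    aics = np.empty(n_max)
    for n in range(1, n_max + 1):
        X = _design(scores[:, :n], None if cov is None else np.asarray(cov), y.size)
        Xv = X[valid]
        beta, _, rank, _ = np.linalg.lstsq(Xv, yv, rcond=None)
        rss = float(np.sum((yv - Xv @ beta) ** 2))
        k = X.shape[1] + 1  # slopes + covariates + intercept, plus error variance
        aics[n - 1] = _aic(rss, n_obs, k)
    best = int(np.argmin(aics)) + 1  # argmin returns the first (smallest N) minimum
    if return_aic:
        return best, aics
    return best


def predict(test, cov2, model: SsmModel) -> np.ndarray:
    """Out-of-sample prediction ``pY2 = [DATA2' V(:,1:N)  COV2  1] beta``."""
    scores = expression_scores(test, model.basis, model.n_components)
    X = _design(scores, cov2, scores.shape[0])
    if X.shape[1] != model.beta.size:
        raise ValueError("covariate count differs from the fitted model")
    return X @ model.beta


@dataclass
class PressResult:
    """Mean squared out-of-sample prediction error and its ingredients."""

    press: float
    predictions: np.ndarray
    n_test: int


def press(predictions, y2) -> PressResult:
    """PRESS statistic ``<(pY2 - Y2)^2>`` — the *mean* squared error.

    Observations with a missing outcome are excluded from the mean but
    their predictions are kept in the result.
    """
    predictions = np.asarray(predictions, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if predictions.shape != y2.shape:
        raise ValueError("predictions and outcomes must align")
    valid = np.isfinite(y2)
    if not valid.any():
        raise ValueError("no test observations with a recorded outcome")
    value = float(np.mean((predictions[valid] - y2[valid]) ** 2))
    return PressResult(press=value, predictions=predictions, n_test=int(valid.sum()))


def derive_pattern(model: SsmModel) -> np.ndarray:
    """Variable-space predictive pattern ``V(:,1:N) beta(1:N)``.

    Covariate and intercept coefficients are excluded; the Reference
    model (N = 0) has no pattern.
    """
    if model.n_components < 1:
        raise ValueError("the covariates-only model has no brain pattern")
    n = model.n_components
    return model.basis.V[:, :n] @ model.beta[:n]


@dataclass
class VarianceSpectrum:
    """Normalized eigenvalue spectrum of an observation array."""

    eigenvalues: np.ndarray     # normalized, sum over full rank = 1
    cumulative: np.ndarray      # running sum of the reported components

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def variance_spectrum(data, k: int = 300, remove_mean: bool = False) -> VarianceSpectrum:
    """Normalized eigenvalues and cumulative variance of the first ``k`` PCs.

    By default the grand mean pattern stays in the data (uncentered
    PCA), so the first component typically absorbs the mean.  When the
    array is large, only the top ``k`` singular values are computed with
    a randomized solver; normalization uses the exact total variance
    (squared Frobenius norm), so cumulative fractions are exact.
    """
    X = _values(data)
    total = float(np.sum(X.astype(float) ** 2))
    if total == 0:
        raise ValueError("variance spectrum of an all-zero array is undefined")
    if remove_mean:
        X = X - X.mean(axis=1, keepdims=True)
        total = float(np.sum(X**2))
    rank_bound = min(X.shape)
    if k > rank_bound:
        warnings.warn(
            f"requested {k} components but rank is at most {rank_bound}; truncating"
        )
        k = rank_bound
    if rank_bound <= 1200 or k >= 0.5 * rank_bound:
        s = np.linalg.svd(X, compute_uv=False)[:k]
    else:
        from sklearn.utils.extmath import randomized_svd

        _, s, _ = randomized_svd(X, n_components=k, n_iter=7, random_state=0)
    eig = s**2 / total
    return VarianceSpectrum(eigenvalues=eig, cumulative=np.cumsum(eig))
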