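"""Monte-Carlo cross-validated comparison of brain-behavior predictors.

Subjects are repeatedly split 80/20 into training and test sets (Monte
Carlo 5-fold cross-validation: random redraws, not a fixed disjoint
partition).  The *same* split plan is applied verbatim to every
modality, so PRESS distributions are comparable apples-to-apples across
activation (ACT), functional connectivity (FC), brain structure
(STRUCT), their prediction average (Vote), and the demographics-only
Reference model.  Per iteration the component count N is re-selected by
AIC on that training sample alone; subjects with missing outcomes enter
the PCA but never the regression or the test score.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ssm_core
from .cpm import cpm_fit, cpm_predict, screen_edges
from .data_model import ObservationArray
from .ssm_core import press

__all__ = [
    "SplitPlan",
    "ModalityResult",
    "BenchResult",
    "make_splits",
    "run_modality",
    "reference_model",
    "vote",
    "summarize",
    "run_benchmark",
    "cpm_compare",
]

logger = logging.getLogger(__name__)

N_ITERATIONS_SSM = 1_000
N_ITERATIONS_CPM = 200
TRAIN_FRACTION = 0.8


@dataclass
class SplitPlan:
    """Per-iteration disjoint train/test subject index sets, shared across modalities."""

    iterations: list            # list of (train_idx, test_idx) integer arrays
    n_subjects: int
    train_fraction: float
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.iterations)

    def checksum(self) -> str:
        """Digest of the full assignment table, for asserting plan identity."""
        h = hashlib.sha256()
        for train, test in self.iterations:
            h.update(np.ascontiguousarray(train, dtype=np.int64).tobytes())
            h.update(np.ascontiguousarray(test, dtype=np.int64).tobytes())
        return h.hexdigest()


def make_splits(
    subject_ids,
    n_iterations: int = N_ITERATIONS_SSM,
    train_fraction: float = TRAIN_FRACTION,
    seed: int | None = None,
) -> SplitPlan:
    """Draw subject-level random 80/20 splits, reproducibly.

    Every iteration partitions all subjects: train and test are disjoint
    and cover the cohort, with ``|train| = round(train_fraction * n)``.
    """
    subject_ids = np.asarray(subject_ids)
    n = subject_ids.size
    if n < 10:
        raise ValueError("need at least 10 subjects to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = round(train_fraction * n)
    if n_train in (0, n):
        raise ValueError("train_fraction leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    iters = []
    for _ in range(n_iterations):
        perm = rng.permutation(n)
        iters.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return SplitPlan(iterations=iters, n_subjects=n,
                     train_fraction=train_fraction, seed=seed)


@dataclass
class ModalityResult:
    """Per-iteration outputs of one modality under one split plan."""

    press: np.ndarray                    # (iterations,)
    selected_n: np.ndarray               # (iterations,) AIC-chosen N
    patterns: np.ndarray | None          # (iterations, variables) or None for Reference
    predictions: np.ndarray              # (iterations, n_test)
    test_subjects: np.ndarray            # (iterations, n_test) subject indices
    plan_checksum: str = ""


def _run_plan(
    values: np.ndarray,
    y: np.ndarray,
    cov: np.ndarray | None,
    plan: SplitPlan,
    n_components: int | None,
    n_max: int,
    remove_mean: bool,
    keep_patterns: bool,
) -> ModalityResult:
    n_test = plan.n_subjects - round(plan.train_fraction * plan.n_subjects)
    press_vals = np.empty(len(plan))
    ns = np.zeros(len(plan), dtype=int)
    preds = np.empty((len(plan), n_test))
    tests = np.empty((len(plan), n_test), dtype=int)
    pats = np.empty((len(plan), values.shape[0])) if keep_patterns else None

    for i, (train_idx, test_idx) in enumerate(plan.iterations):
        train = values[:, train_idx]
        test = values[:, test_idx]
        y1, y2 = y[train_idx], y[test_idx]
        cov1 = None if cov is None else cov[train_idx]
        cov2 = None if cov is None else cov[test_idx]

        if n_components is None:
            basis = ssm_core.fit_pca(train, remove_mean=remove_mean)
            n = ssm_core.select_n_aic(train, y1, cov1, n_max=n_max, basis=basis)
        elif n_components == 0:
            basis, n = ssm_core.PcBasis(V=np.zeros((values.shape[0], 0)),
                                        eigenvalues=np.zeros(0)), 0
        else:
            basis = ssm_core.fit_pca(train, remove_mean=remove_mean)
            n = n_components

        model = ssm_core.fit_ssm(train, y1, cov1, n, basis=basis)
        p = ssm_core.predict(test, cov2, model)
        press_vals[i] = press(p, y2).press
        ns[i] = n
        preds[i] = p
        tests[i] = test_idx
        if keep_patterns:
            pats[i] = ssm_core.derive_pattern(model) if n >= 1 else 0.0
    return ModalityResult(press=press_vals, selected_n=ns, patterns=pats,
                          predictions=preds, test_subjects=tests,
                          plan_checksum=plan.checksum())


def run_modality(
    arr: ObservationArray | np.ndarray,
    y: np.ndarray,
    cov: np.ndarray | None,
    plan: SplitPlan,
    n_max: int = ssm_core.DEFAULT_N_MAX,
    remove_mean: bool = False,
    keep_patterns: bool = True,
) -> ModalityResult:
    """Run the SSM recipe for one modality over every split of the plan.

    ``arr`` must be subject-level (one column per subject) and aligned
    with the plan's subject indexing; ``y`` may contain NaN for missing
    outcomes (the affected subjects contribute to the PCA only).
    """
    values = arr.values if isinstance(arr, ObservationArray) else np.asarray(arr)
    values = values.astype(float, copy=False)
    y = np.asarray(y, dtype=float)
    if values.shape[1] != plan.n_subjects or y.size != plan.n_subjects:
        raise ValueError("array, outcomes, and split plan disagree on subject count")
    return _run_plan(values, y, cov, plan, None, n_max, remove_mean, keep_patterns)


def reference_model(cov: np.ndarray, y: np.ndarray, plan: SplitPlan) -> ModalityResult:
    """Covariates-only benchmark: the SSM path with N forced to 0."""
    cov = np.asarray(cov, dtype=float)
    y = np.asarray(y, dtype=float)
    dummy = np.zeros((1, plan.n_subjects))  # empty variable space
    return _run_plan(dummy, y, cov, plan, 0, 0, False, keep_patterns=False)


def vote(*prediction_sets) -> np.ndarray:
    """Elementwise mean of aligned prediction vectors/matrices."""
    if not prediction_sets:
        raise ValueError("vote needs at least one prediction set")
    arrs = [np.asarray(p, dtype=float) for p in prediction_sets]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("prediction sets must align elementwise")
    return np.mean(arrs, axis=0)


def _vote_result(results: list, y: np.ndarray, plan: SplitPlan) -> ModalityResult:
    ref = results[0]
    for r in results[1:]:
        if r.plan_checksum != ref.plan_checksum:
            raise ValueError("Vote requires modalities run on the identical split plan")
    preds = vote(*[r.predictions for r in results])
    press_vals = np.array([
        press(preds[i], y[plan.iterations[i][1]]).press for i in range(len(plan))
    ])
    return ModalityResult(press=press_vals, selected_n=np.zeros(len(plan), dtype=int),
                          patterns=None, predictions=preds,
                          test_subjects=ref.test_subjects,
                          plan_checksum=ref.plan_checksum)


@dataclass
class BenchResult:
    """Raw per-iteration PRESS for every model and domain, plus patterns."""

    press: pd.DataFrame                       # columns: iteration, model, domain, press, selected_n
    patterns: dict = field(default_factory=dict)   # (model, domain) -> (iters, vars)
    plan: SplitPlan | None = None


def summarize(bench: BenchResult | pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of PRESS per model and domain."""
    df = bench.press if isinstance(bench, BenchResult) else bench
    if len(df) == 0:
        raise ValueError("nothing to summarize")
    out = (
        df.groupby(["model", "domain"], sort=False)["press"]
        .agg(median="median",
             q25=lambda s: s.quantile(0.25),
             q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    out["iqr"] = out["q75"] - out["q25"]
    return out


def run_benchmark(
    cohort,
    modalities=("act", "fc", "struct"),
    domains=None,
    n_iterations: int = N_ITERATIONS_SSM,
    seed: int | None = None,
    n_max: int = ssm_core.DEFAULT_N_MAX,
    include_vote: bool = True,
    include_reference: bool = True,
    keep_patterns: bool = True,
) -> BenchResult:
    """Full comparison run on a cohort: per-modality SSM, Vote, Reference.

    One split plan is drawn from ``seed`` and shared verbatim by every
    model and domain.
    """
    domains = list(cohort.domain_names if domains is None else domains)
    plan = make_splits(np.arange(cohort.config.n_subjects),
                       n_iterations=n_iterations, seed=seed)
    cov = cohort.covariates()
    rows, patterns = [], {}

    def _record(name, domain, result):
        for i in range(len(plan)):
            rows.append((i, name, domain, result.press[i], result.selected_n[i]))
        if result.patterns is not None:
            patterns[(name, domain)] = result.patterns

    for domain in domains:
        logger.info("benchmark domain %s", domain)
        per_modality = []
        y_dom = None
        for m in modalities:
            arr, y = cohort.domain_data(m, domain)
            y_dom = y
            res = run_modality(arr, y, cov, plan, n_max=n_max,
                               keep_patterns=keep_patterns)
            per_modality.append(res)
            _record(m.upper(), domain, res)
        if include_vote and len(per_modality) > 1:
            _record("Vote", domain, _vote_result(per_modality, y_dom, plan))
        if include_reference:
            _record("Reference", domain, reference_model(cov, y_dom, plan))

    df = pd.DataFrame(rows, columns=["iteration", "model", "domain", "press", "selected_n"])
    return BenchResult(press=df, patterns=patterns, plan=plan)


def cpm_compare(
    cohort,
    domains=None,
    n_iterations: int = N_ITERATIONS_CPM,
    seed: int | None = None,
    p_threshold: float = 0.05,
    n_max: int = ssm_core.DEFAULT_N_MAX,
) -> pd.DataFrame:
    """Head-to-head CPM vs SSM-PCA on connectivity, shared splits, no covariates.

    Returns per-iteration PRESS for both techniques and their
    difference (CPM - SSM; positive favours the PCA model).
    """
    domains = list(cohort.domain_names if domains is None else domains)
    plan = make_splits(np.arange(cohort.config.n_subjects),
                       n_iterations=n_iterations, seed=seed)
    rows = []
    for domain in domains:
        arr, y = cohort.domain_data("fc", domain)
        values = arr.values.astype(float, copy=False)
        ssm_res = run_modality(arr, y, None, plan, n_max=n_max, keep_patterns=False)
        for i, (train_idx, test_idx) in enumerate(plan.iterations):
            tr_valid = train_idx[np.isfinite(y[train_idx])]
            sel = screen_edges(values[:, tr_valid], y[tr_valid], p_threshold)
            model = cpm_fit(values[:, tr_valid], y[tr_valid], sel, p_threshold)
            p = cpm_predict(values[:, test_idx], model)
            cpm_press = press(p, y[test_idx]).press
            rows.append((i, domain, cpm_press, ssm_res.press[i],
                         cpm_press - ssm_res.press[i], sel.size))
    return pd.DataFrame(rows, columns=["iteration", "domain", "press_cpm",
                                       "press_ssm", "press_diff", "n_edges_selected"])
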