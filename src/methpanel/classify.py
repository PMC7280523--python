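"""Marker panels and their cross-validated diagnostic performance.

Implements the evaluation stack used on the binary MSRE-PCR call matrix:
per-group methylation frequencies and their deltas, marker independence
grouping (Manhattan/ward.D2 clustering plus PCA), maximum-likelihood
logistic regression with Wald inference, repeated stratified k-fold
cross-validation with per-repeat pooled out-of-fold AUC, a tie-corrected
ROC with the Youden-index operating point, and exhaustive small-subset
search over marker combinations.

Conventions: the responder class (PR) is coded 1 and anchors sensitivity
(configurable); the default classification cut-off is 0.5; cross-validation
is stratified and fully reproducible from its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .simulate import INVALID, METHYLATED, SampleAnnotation

logger = logging.getLogger(__name__)

Z_95 = 1.96  # conventional two-sided 95% normal quantile, as used in the field


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge; carries the last iterate."""

    def __init__(self, message: str, fit: "LogisticFit"):
        super().__init__(message)
        self.fit = fit


def wald_or_ci(beta: float, se: float, z: float = Z_95) -> tuple[float, float, float]:
    """Odds ratio exp(beta) and its Wald confidence interval
    (exp(beta - z*se), exp(beta + z*se))."""
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


@dataclass
class LogisticFit:
    """A fitted logistic model with Wald inference per term."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    separation_warning: bool
    n_iter: int
    loglik: float

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        """(lower, upper) odds-ratio bounds per term, shape (p, 2)."""
        return np.column_stack(
            [np.exp(self.beta - Z_95 * self.se), np.exp(self.beta + Z_95 * self.se)]
        )

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        eta = self.beta[0] + x @ self.beta[1:]
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "odds_ratio": self.or_,
                "ci95_low": ci[:, 0],
                "ci95_high": ci[:, 1],
            },
            index=self.terms,
        )


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray | Sequence[int],
    terms: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    beta_bound: float = 15.0,
    raise_on_failure: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton-Raphson.

    ``x`` holds the predictors (no intercept column; one is prepended),
    ``y`` the 0/1 outcome. Iterations stop when the gradient max-norm falls
    below ``tol``. Step-halving guards against overshooting. Quasi-complete
    separation is flagged when any predictor coefficient magnitude exceeds
    ``beta_bound``; the fit is then returned as-is with
    ``separation_warning`` set rather than raised, since the diverging MLE
    still ranks observations correctly. Wald standard errors come from the
    inverse observed information.
    """
    if isinstance(x, pd.DataFrame):
        terms = terms or list(x.columns)
        x = x.to_numpy(float)
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1 and x.shape[1] > 1 and len(np.asarray(y)) == x.shape[1]:
        x = x.T
    y = np.asarray(y, float)
    n, p = x.shape
    if n != len(y):
        raise ValueError("x and y sizes disagree")
    design = np.column_stack([np.ones(n), x])
    names = ["(Intercept)"] + (terms or [f"x{i + 1}" for i in range(p)])

    beta = np.zeros(p + 1)
    ll = _loglik(y, design @ beta)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = design.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        hess = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(hess) @ grad
        # step-halving if the log-likelihood does not improve
        for _ in range(30):
            cand = beta + step
            ll_new = _loglik(y, design @ cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        ll = _loglik(y, design @ beta)
        if np.max(np.abs(beta[1:])) > beta_bound if p else False:
            separation = True
            break

    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    hess = design.T @ (design * w[:, None])
    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    fit = LogisticFit(
        terms=names, beta=beta, se=se, converged=converged,
        separation_warning=separation, n_iter=it, loglik=ll,
    )
    if not converged and not separation and raise_on_failure:
        raise ConvergenceError(f"no convergence after {max_iter} Newton iterations", fit)
    return fit


@dataclass
class RocResult:
    """A full ROC with its AUC and the Youden-index operating point."""

    auc: float
    thresholds: np.ndarray
    sensitivity_curve: np.ndarray
    specificity_curve: np.ndarray
    youden_threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    j: float
    n_pos: int
    n_neg: int


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-corrected probability that a random positive outscores a
    random negative: P(s+ > s-) + 0.5 P(s+ = s-), via midranks."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_youden(scores: Iterable[float], labels: Iterable[int]) -> RocResult:
    """ROC over the observed thresholds plus the Youden operating point.

    Predictions are positive when score >= threshold; candidate thresholds
    are the distinct scores (plus one above the maximum, giving the all-
    negative corner). Ties in J = sens + spec - 1 break toward higher
    specificity, then toward the higher threshold.
    """
    scores = np.asarray(list(scores), float)
    labels = np.asarray(list(labels), bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc = auc_mann_whitney(scores, labels)
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[uniq[0] + 1.0], uniq])
    sens = np.array([(scores[labels] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~labels] < t).mean() for t in thresholds])
    js = sens + spec - 1.0
    best = max(range(len(thresholds)), key=lambda i: (js[i], spec[i], thresholds[i]))
    t = float(thresholds[best])
    acc = float(((scores >= t) == labels).mean())
    return RocResult(
        auc=auc,
        thresholds=thresholds,
        sensitivity_curve=sens,
        specificity_curve=spec,
        youden_threshold=t,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        accuracy=acc,
        j=float(js[best]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


@dataclass
class CvReport:
    """Repeated stratified cross-validation result for one marker combination."""

    combo: tuple[str, ...]
    repeats: int
    folds: int
    seed: int
    auc_per_repeat: np.ndarray
    mean_auc: float
    roc: RocResult
    youden_threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    accuracy_cut05: float
    n_used: int
    n_dropped: int

    def to_dict(self) -> dict:
        return {
            "combo": list(self.combo),
            "repeats": self.repeats,
            "folds": self.folds,
            "seed": self.seed,
            "mean_auc": self.mean_auc,
            "youden_threshold": self.youden_threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "accuracy_cut05": self.accuracy_cut05,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
        }


def _design_from_calls(
    calls: pd.DataFrame,
    ann: list[SampleAnnotation],
    combo: Sequence[str],
    positive: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Complete-case design matrix (samples with any invalid call in the
    combo dropped) and 0/1 outcome."""
    missing = [m for m in combo if m not in calls.index]
    if missing:
        raise KeyError(f"markers not in call matrix: {missing}")
    resp = {a.sample_id: a.response for a in ann}
    cols = [s for s in calls.columns if s in resp]
    sub = calls.loc[list(combo), cols]
    valid = (sub != INVALID).all(axis=0)
    dropped = int((~valid).sum())
    if dropped:
        logger.info("dropping %d sample(s) with invalid calls for combo %s", dropped, combo)
    sub = sub.loc[:, valid]
    x = (sub.to_numpy().T == METHYLATED).astype(float)
    y = np.array([resp[s] == positive for s in sub.columns], float)
    return x, y, dropped


def repeated_cv(
    calls: pd.DataFrame,
    ann: list[SampleAnnotation],
    combo: Sequence[str],
    repeats: int = 100,
    folds: int = 5,
    seed: int = 0,
    positive: str = "PR",
) -> CvReport:
    """Repeated stratified k-fold cross-validation of a logistic classifier.

    Per repeat: a fresh stratified partition into ``folds`` folds; the model
    is fitted on the training folds and out-of-fold probabilities are pooled
    within the repeat; that pool's AUC is the repeat's AUC and the reported
    AUC is the mean over repeats. The pooled probabilities of all repeats
    feed the ROC/Youden operating point. Each class must supply at least
    ``folds`` samples so every training split contains both classes.
    """
    x, y, dropped = _design_from_calls(calls, ann, combo, positive)
    n = len(y)
    n_pos, n_neg = int(y.sum()), int(n - y.sum())
    if min(n_pos, n_neg) < folds:
        raise ValueError(
            f"each class needs >= {folds} samples for {folds}-fold stratified CV "
            f"(have {n_pos} positive / {n_neg} negative)"
        )
    rep_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    aucs = np.empty(repeats)
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rep_seeds[r]))
        oof = np.empty(n)
        for train, test in skf.split(x, y):
            fit = fit_logistic(x[train], y[train], raise_on_failure=False)
            oof[test] = fit.predict_proba(x[test])
        aucs[r] = auc_mann_whitney(oof, y.astype(bool))
        pooled_scores.append(oof)
        pooled_labels.append(y)
    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels).astype(bool)
    roc = roc_youden(all_scores, all_labels)
    acc05 = float(((all_scores >= 0.5) == all_labels).mean())
    return CvReport(
        combo=tuple(combo),
        repeats=repeats,
        folds=folds,
        seed=seed,
        auc_per_repeat=aucs,
        mean_auc=float(aucs.mean()),
        roc=roc,
        youden_threshold=roc.youden_threshold,
        sensitivity=roc.sensitivity,
        specificity=roc.specificity,
        accuracy=roc.accuracy,
        accuracy_cut05=acc05,
        n_used=n,
        n_dropped=dropped,
    )


def marker_stats(
    calls: pd.DataFrame,
    ann: list[SampleAnnotation],
    cv_params: dict | None = None,
    positive: str = "PR",
) -> pd.DataFrame:
    """Per-marker group methylation frequencies, deltas and (optionally)
    single-marker cross-validated metrics.

    Frequencies are computed over valid (non-invalid) cells only; a marker
    with zero valid cells in a group gets a missing frequency and is flagged.
    ``delta`` is freq(PR) - freq(SD). ``cv_params`` (repeats/folds/seed)
    switches on single-marker repeated CV.
    """
    resp = {a.sample_id: a.response for a in ann}
    pr_cols = [s for s in calls.columns if resp.get(s) == "PR"]
    sd_cols = [s for s in calls.columns if resp.get(s) == "SD"]
    rows = []
    for locus in calls.index:
        row = {"locus": locus}
        for key, cols in (("pr", pr_cols), ("sd", sd_cols)):
            vals = calls.loc[locus, cols]
            valid = vals[vals != INVALID]
            row[f"n_valid_{key}"] = len(valid)
            row[f"freq_{key}"] = (
                float((valid == METHYLATED).mean()) if len(valid) else float("nan")
            )
        row["delta"] = row["freq_pr"] - row["freq_sd"]
        row["flagged"] = row["n_valid_pr"] == 0 or row["n_valid_sd"] == 0
        if cv_params is not None and not row["flagged"]:
            rep = repeated_cv(calls, ann, (locus,), positive=positive, **cv_params)
            row["cv_auc"] = rep.mean_auc
            row["cv_sens"] = rep.sensitivity
            row["cv_spec"] = rep.specificity
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus")


def independence_groups(
    calls: pd.DataFrame, k: int = 2
) -> tuple[pd.Series, pd.DataFrame, np.ndarray]:
    """Group markers by redundancy: Manhattan/ward.D2 clustering of the
    marker call vectors cut at ``k`` groups, plus marker scores on the first
    two principal components for concordance inspection. Invalid calls are
    median-imputed per marker."""
    if len(calls) < 2:
        raise ValueError("need at least 2 markers")
    x = calls.to_numpy(float)
    x[x == INVALID] = np.nan
    med = np.nanmedian(x, axis=1)
    idx = np.where(np.isnan(x))
    x[idx] = med[idx[0]]
    z = linkage(pdist(x, metric="cityblock"), method="ward")
    labels = pd.Series(
        fcluster(z, t=k, criterion="maxclust"), index=calls.index, name="group"
    )
    n_comp = min(2, min(x.shape) if min(x.shape) > 1 else 1, len(calls) - 1) or 1
    scores = PCA(n_components=n_comp, random_state=0).fit_transform(x)
    if scores.shape[1] < 2:
        scores = np.column_stack([scores, np.zeros(len(scores))])
    pca = pd.DataFrame(scores[:, :2], index=calls.index, columns=["pc1", "pc2"])
    return labels, pca, z


def combo_search(
    calls: pd.DataFrame,
    ann: list[SampleAnnotation],
    candidates: Sequence[str],
    max_size: int = 3,
    repeats: int = 100,
    folds: int = 5,
    seed: int = 0,
    positive: str = "PR",
    groups: pd.Series | None = None,
    cross_group_only: bool = False,
) -> list[CvReport]:
    """Evaluate every marker subset up to ``max_size`` by repeated CV.

    Ranked by mean AUC, ties broken toward fewer markers (simpler panels
    preferred). With ``cross_group_only`` and independence-group labels,
    multi-marker combos must draw each marker from a distinct group.
    """
    reports = []
    for size in range(1, max_size + 1):
        for combo in combinations(candidates, size):
            if cross_group_only and groups is not None and size > 1:
                labs = [groups[m] for m in combo]
                if len(set(labs)) < len(labs):
                    continue
            reports.append(
                repeated_cv(calls, ann, combo, repeats=repeats, folds=folds,
                            seed=seed, positive=positive)
            )
    reports.sort(key=lambda r: (-r.mean_auc, len(r.combo), r.combo))
    return reports


def cohort_summary(ann: list[SampleAnnotation]) -> pd.DataFrame:
    """Response-group bookkeeping: counts and percentages (2 dp)."""
    total = len(ann)
    rows = []
    for label, name in (("PR", "Partial response"), ("SD", "Stable disease")):
        n = sum(a.response == label for a in ann)
        rows.append({"response": name, "n": n, "percent": round(100.0 * n / total, 2)})
    return pd.DataFrame(rows)
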