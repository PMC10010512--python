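"""Per-feature and per-contrast association screen with FDR and CV classifiers.

For each target (a feature or a pairwise contrast) the screen fits an
age/gender-adjusted logistic regression

    logit P(case) = b0 + b1·age + b2·gender + b3·target,   case = 1, control = 0,

reports the Wald p-value and sign of ``b3`` (positive: cases higher after
adjustment), adjusts p-values across the family by the Benjamini–Yekutieli
step-up procedure (valid under arbitrary dependence), and optionally evaluates
each target as a classifier: an L2-penalized logistic regression on
(age, gender, target) with the penalty chosen by 5-fold cross-validated
deviance, out-of-sample predictions from 10 repeats of 5-fold CV averaged per
participant, AUROC on the averaged scores, and confusion-matrix metrics at the
F1-maximizing threshold with specificity ≥ 0.85.

``FeatureScreen`` is the model object; ``FeatureScreen.fit()`` returns
``ScreenResults`` carrying the per-target table sorted by ascending p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold

from . import metrics as _metrics
from .solvers import binomial_deviance, lambda_path, logistic_path

logger = logging.getLogger(__name__)

#: |coefficient| beyond which a logistic fit is treated as (quasi-)separated
SEPARATION_COEF_BOUND = 30.0


@dataclass
class AssociationResult:
    beta: float
    p_value: float
    effect_direction: str  # "+" or "-"
    separation: bool = False


def adjusted_association(y, x, age, gender) -> AssociationResult:
    """Age/gender-adjusted logistic association of one target with case status.

    Rows with missing ``x`` are dropped (imputed values are never screened).
    Complete or quasi-complete separation is flagged rather than silently
    reported: the Wald p-value is then unreliable.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    age = np.asarray(age, dtype=float)
    gender = np.asarray(gender, dtype=float)
    keep = ~np.isnan(x)
    if not keep.all():
        logger.debug("dropping %d rows with missing target values", (~keep).sum())
    y, x, age, gender = y[keep], x[keep], age[keep], gender[keep]
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 participants per class")
    X = np.column_stack([np.ones_like(x), age, gender, x])
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            beta = float(res.params[-1])
            p = float(res.pvalues[-1])
            if (not np.isfinite(p)) or np.abs(res.params).max() > SEPARATION_COEF_BOUND:
                separated = True
        except Exception:  # pragma: no cover - pathological designs
            beta, p, separated = np.nan, np.nan, True
    direction = "+" if beta >= 0 else "-"
    return AssociationResult(beta, p, direction, separated)


def by_fdr(p_values) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted values.

    adj_(i) = min_{j ≥ i} p_(j) · m · c(m) / j with c(m) = Σ_{k=1..m} 1/k,
    capped at 1. The family is exactly the vector passed in.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _resolve_folds(y: np.ndarray, folds: int) -> int:
    smallest = int(min((y == 1).sum(), (y == 0).sum()))
    if smallest < folds:
        new_folds = max(3, smallest)
        warnings.warn(
            f"class with {smallest} members: reducing CV folds {folds} -> {new_folds}"
        )
        return new_folds
    return folds


def _cv_ridge_lambda(X, y, folds, seed, n_lambda=40, min_ratio=1e-4) -> float:
    """L2 penalty minimizing 5-fold cross-validated binomial deviance."""
    lambdas = lambda_path(X, y, alpha=0.0, n_lambda=n_lambda, min_ratio=min_ratio)
    folds = _resolve_folds(y, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros(len(lambdas))
    for tr, te in skf.split(X, y):
        fits = logistic_path(X[tr], y[tr], lambdas, alpha=0.0)
        for k, fit in enumerate(fits):
            dev[k] += binomial_deviance(y[te], fit.decision(X[te]))
    return float(lambdas[int(np.argmin(dev))])


def cross_validated_scores(
    X: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    alpha: float = 0.0,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    penalty_factor: np.ndarray | None = None,
) -> np.ndarray:
    """Per-participant out-of-sample log-odds, averaged over CV repeats.

    Every participant's score comes from models whose training folds excluded
    that participant (asserted via fold bookkeeping).
    """
    folds = _resolve_folds(y, folds)
    scores = np.zeros(len(y))
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        seen = np.zeros(len(y), dtype=bool)
        for tr, te in skf.split(X, y):
            assert not np.intersect1d(tr, te).size
            fit = logistic_path(X[tr], y[tr], np.array([lambda_]), alpha,
                                penalty_factor)[0]
            scores[te] += fit.decision(X[te])
            seen[te] = True
        assert seen.all()
    return scores / repeats


def single_feature_classifier(
    y, x, age, gender, seed: int = 0, folds: int = 5, repeats: int = 10
) -> tuple[float, np.ndarray]:
    """AUROC of one target used with age and gender in an L2 logistic classifier."""
    cols = [np.asarray(age, float), np.asarray(gender, float)]
    if x is not None:
        cols.append(np.asarray(x, float))
    X = np.column_stack(cols)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(X).any(axis=1)
    X, y = X[keep], y[keep]
    lam = _cv_ridge_lambda(X, y, folds, seed)
    scores = cross_validated_scores(X, y, lam, alpha=0.0, folds=folds,
                                    repeats=repeats, seed=seed)
    return _metrics.auroc(scores, y), scores


class ScreenResults:
    """Results of a feature/contrast screen; one row per target, sorted by p."""

    def __init__(self, frame: pd.DataFrame, family: str, cohort_pair: str):
        self.frame = frame
        self.family = family
        self.cohort_pair = cohort_pair

    def top(self, n: int = 20) -> pd.DataFrame:
        return self.frame.head(n)

    def summary(self, n: int = 20) -> str:
        cols = [c for c in ("target", "p_value", "fdr", "auroc", "effect_direction")
                if c in self.frame.columns]
        lines = [
            f"Screen of {len(self.frame)} {self.family} "
            f"({self.cohort_pair}), sorted by p-value",
            self.frame[cols].head(n).to_string(index=False,
                                               float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


class FeatureScreen:
    """Age/gender-adjusted screen of many targets against a binary cohort pair.

    Parameters
    ----------
    targets : DataFrame
        Participants × targets (features or contrasts); NaN rows are dropped
        per target.
    y : array of {0,1}
        Case (1) / control (0) labels aligned with ``targets`` rows.
    age, gender : arrays
        Adjustment covariates (gender coded female=0, male=1).
    family : str
        Label for the FDR family ("features" or "contrasts"); the BY adjustment
        runs within exactly the targets passed in.
    """

    def __init__(self, targets: pd.DataFrame, y, age, gender,
                 family: str = "features", cohort_pair: str = "aMCI-vs-HC"):
        self.targets = targets
        self.y = np.asarray(y, dtype=float)
        self.age = np.asarray(age, dtype=float)
        self.gender = np.asarray(gender, dtype=float)
        if len(self.targets) != len(self.y):
            raise ValueError("targets and labels are misaligned")
        self.family = family
        self.cohort_pair = cohort_pair

    def fit(self, compute_classifiers: bool = True, seed: int = 0,
            folds: int = 5, repeats: int = 10,
            min_specificity: float = 0.85) -> ScreenResults:
        rows = []
        for name in self.targets.columns:
            x = self.targets[name].to_numpy(dtype=float)
            assoc = adjusted_association(self.y, x, self.age, self.gender)
            row = {
                "target": name,
                "beta": assoc.beta,
                "p_value": assoc.p_value,
                "effect_direction": assoc.effect_direction,
                "separation": assoc.separation,
            }
            if compute_classifiers:
                auc, scores = single_feature_classifier(
                    self.y, x, self.age, self.gender, seed=seed,
                    folds=folds, repeats=repeats,
                )
                keep = ~np.isnan(x)
                thr, rep = _metrics.select_threshold(scores, self.y[keep],
                                                     min_specificity)
                row.update(
                    auroc=auc, threshold=thr, sensitivity=rep.sensitivity,
                    specificity=rep.specificity, precision=rep.precision,
                    accuracy=rep.accuracy, f1=rep.f1,
                )
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame["fdr"] = by_fdr(frame["p_value"].fillna(1.0).to_numpy())
        frame = frame.sort_values("p_value", kind="mergesort").reset_index(drop=True)
        return ScreenResults(frame, self.family, self.cohort_pair)


def screen_all(targets: pd.DataFrame, y, age, gender, family: str = "features",
               cohort_pair: str = "aMCI-vs-HC", **fit_kwargs) -> ScreenResults:
    """Functional wrapper: screen every column of ``targets``; see FeatureScreen."""
    return FeatureScreen(targets, y, age, gender, family, cohort_pair).fit(**fit_kwargs)
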