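"""Combined picture-description risk scores.

Two constructions are provided, both on the log-odds scale:

* ``PDRiskModel`` — elastic-net logistic regression per cohort pair
  (aMCI-vs-HC, naMCI-vs-HC, MCI-vs-HC) over all registry features plus
  unpenalized age and gender. The mixing parameter alpha and penalty scale
  lambda are chosen on a grid by 5-fold cross-validated binomial deviance, with
  the six tremor features imputed separately on each side of every train/test
  split. The final model is refit on all data at the chosen penalties; each
  participant's risk score is the mean out-of-sample prediction over 10 further
  replications of 5-fold CV.

* ``MultinomialRiskModel`` — a penalized multinomial model over the three
  diagnoses fitted once; differences of cross-validated class liabilities
  estimate the pairwise log-odds and serve as risk scores for the three
  pairwise tasks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import metrics as _metrics
from .prep import impute_split
from .solvers import (
    binomial_deviance,
    lambda_path,
    logistic_path,
    multinomial_deviance,
    multinomial_path,
)
from .tables import FeatureTable

TASKS = ("aMCI-vs-HC", "naMCI-vs-HC", "MCI-vs-HC")

_TASK_CASES = {
    "aMCI-vs-HC": ("aMCI",),
    "naMCI-vs-HC": ("naMCI",),
    "MCI-vs-HC": ("aMCI", "naMCI"),
}


@dataclass
class RiskConfig:
    """Tuning grid and CV settings for the penalized risk-score models."""

    alphas: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
    n_lambda: int = 30
    lambda_min_ratio: float = 1e-3
    folds: int = 5
    repeats: int = 10
    impute_max_rank: int = 5
    impute_tol: float = 1e-4
    impute_max_iters: int = 200


def _task_frame(table: FeatureTable, participants: pd.DataFrame, task: str):
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    cases = _TASK_CASES[task]
    keep = participants["diagnosis"].isin(cases + ("HC",))
    part = participants.loc[keep]
    if part["diagnosis"].isin(cases).sum() == 0 or (part["diagnosis"] == "HC").sum() == 0:
        raise ValueError(f"task {task}: one class is empty")
    sub = FeatureTable(table.data.loc[part.index], table.registry, table.normalized)
    y = part["diagnosis"].isin(cases).to_numpy(dtype=float)
    return sub, part, y


def _design(table: FeatureTable, part: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [table.data.to_numpy(dtype=float),
         part["age"].to_numpy(dtype=float),
         part["gender"].to_numpy(dtype=float)]
    )


def _impute_pair(table: FeatureTable, tr: np.ndarray, te: np.ndarray, cfg: RiskConfig):
    train = FeatureTable(table.data.iloc[tr], table.registry, table.normalized)
    test = FeatureTable(table.data.iloc[te], table.registry, table.normalized)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return impute_split(train, test, max_rank=cfg.impute_max_rank,
                            tol=cfg.impute_tol, max_iters=cfg.impute_max_iters)


@dataclass
class PDRiskResults:
    """Fitted PD risk score: weights, penalties, out-of-sample scores, AUROC."""

    task: str
    alpha: float
    lambda_: float
    intercept: float
    weights: dict[str, float]  # nonzero feature weights only
    covariate_weights: dict[str, float]  # age, gender (never penalized away)
    scores: pd.Series  # per-participant out-of-sample log-odds
    auroc: float
    y: np.ndarray
    seed: int
    cv_deviance: float

    @property
    def support(self) -> list[str]:
        return sorted(self.weights)

    def threshold_metrics(self, min_specificity: float = 0.85):
        return _metrics.select_threshold(self.scores.to_numpy(), self.y,
                                         min_specificity)[1]

    def summary(self) -> str:
        lines = [
            f"PD risk score — {self.task}",
            f"  alpha={self.alpha:.2f}  lambda={self.lambda_:.4g}  "
            f"cv deviance={self.cv_deviance:.3f}",
            f"  selected features: {len(self.weights)} of {self._n_features}",
            f"  AUROC (10×5-fold CV averaged scores): {self.auroc:.3f}",
            "  covariates: "
            + ", ".join(f"{k}={v:+.4f}" for k, v in self.covariate_weights.items()),
        ]
        if self.weights:
            top = sorted(self.weights.items(), key=lambda kv: -abs(kv[1]))[:10]
            lines.append("  largest weights:")
            lines += [f"    {name}: {w:+.4f}" for name, w in top]
        return "\n".join(lines)

    _n_features: int = 0

    def to_json(self, path) -> None:
        payload = {
            "task": self.task, "alpha": self.alpha, "lambda": self.lambda_,
            "intercept": self.intercept, "weights": self.weights,
            "covariate_weights": self.covariate_weights, "auroc": self.auroc,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class PDRiskModel:
    """Elastic-net logistic risk score for one cohort pair.

    Parameters
    ----------
    table : FeatureTable
        Quantile-normalized features for all participants; missing values only
        in the tremor features.
    participants : DataFrame
        Indexed by participant id with ``diagnosis``, ``age``, ``gender``
        (gender coded female=0, male=1).
    task : str
        One of ``aMCI-vs-HC``, ``naMCI-vs-HC``, ``MCI-vs-HC``.
    """

    def __init__(self, table: FeatureTable, participants: pd.DataFrame,
                 task: str = "aMCI-vs-HC", config: RiskConfig | None = None):
        if not table.normalized:
            raise ValueError("risk models require a quantile-normalized table")
        self.table, self.participants, self.y = _task_frame(table, participants, task)
        self.task = task
        self.config = config or RiskConfig()
        p = len(self.table.registry)
        self.penalty_factor = np.concatenate([np.ones(p), np.zeros(2)])

    # -- penalty selection ---------------------------------------------------

    def _cv_penalties(self, seed: int) -> tuple[float, float, float]:
        cfg = self.config
        full_train, _ = _impute_pair(self.table, np.arange(len(self.y)),
                                     np.arange(0), cfg)
        X_full = _design(full_train, self.participants)
        grids = {
            a: lambda_path(X_full, self.y, a, self.penalty_factor,
                           cfg.n_lambda, cfg.lambda_min_ratio)
            for a in cfg.alphas
        }
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=seed)
        dev = {a: np.zeros(cfg.n_lambda) for a in cfg.alphas}
        for tr, te in skf.split(X_full, self.y):
            tr_tab, te_tab = _impute_pair(self.table, tr, te, cfg)
            X_tr = _design(tr_tab, self.participants.iloc[tr])
            X_te = _design(te_tab, self.participants.iloc[te])
            for a in cfg.alphas:
                fits = logistic_path(X_tr, self.y[tr], grids[a], a,
                                     self.penalty_factor)
                for k, fit in enumerate(fits):
                    dev[a][k] += binomial_deviance(self.y[te], fit.decision(X_te))
        best = min(
            ((a, k) for a in cfg.alphas for k in range(cfg.n_lambda)),
            key=lambda ak: (dev[ak[0]][ak[1]], ak[0], ak[1]),
        )
        a, k = best
        return float(a), float(grids[a][k]), float(dev[a][k] / cfg.folds)

    # -- fitting ---------------------------------------------------------------

    def fit(self, seed: int = 0) -> PDRiskResults:
        cfg = self.config
        alpha, lam, cv_dev = self._cv_penalties(seed)

        # final model refit on all data at the chosen penalties
        full_train, _ = _impute_pair(self.table, np.arange(len(self.y)),
                                     np.arange(0), cfg)
        X_full = _design(full_train, self.participants)
        final = logistic_path(X_full, self.y, np.array([lam]), alpha,
                              self.penalty_factor)[0]

        # out-of-sample scores: 10 further replications of 5-fold CV
        scores = np.zeros(len(self.y))
        for rep in range(cfg.repeats):
            skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                                  random_state=seed + 1000 + rep)
            for tr, te in skf.split(X_full, self.y):
                assert not np.intersect1d(tr, te).size
                tr_tab, te_tab = _impute_pair(self.table, tr, te, cfg)
                X_tr = _design(tr_tab, self.participants.iloc[tr])
                X_te = _design(te_tab, self.participants.iloc[te])
                fit = logistic_path(X_tr, self.y[tr], np.array([lam]), alpha,
                                    self.penalty_factor)[0]
                scores[te] += fit.decision(X_te)
        scores /= cfg.repeats

        names = self.table.registry.names
        weights = {
            names[j]: float(final.coef[j])
            for j in range(len(names))
            if final.coef[j] != 0.0
        }
        res = PDRiskResults(
            task=self.task, alpha=alpha, lambda_=lam,
            intercept=float(final.intercept), weights=weights,
            covariate_weights={"age": float(final.coef[-2]),
                               "gender": float(final.coef[-1])},
            scores=pd.Series(scores, index=self.participants.index, name="risk_score"),
            auroc=_metrics.auroc(scores, self.y), y=self.y.copy(), seed=seed,
            cv_deviance=cv_dev,
        )
        res._n_features = len(names)
        return res


def fit_pd_risk_score(table: FeatureTable, participants: pd.DataFrame, task: str,
                      config: RiskConfig | None = None, seed: int = 0
                      ) -> PDRiskResults:
    """Functional wrapper over :class:`PDRiskModel`."""
    return PDRiskModel(table, participants, task, config).fit(seed)


# ---------------------------------------------------------------------------
# multinomial liabilities


@dataclass
class LiabilitySet:
    """Per-participant class liabilities and pairwise liability differences."""

    liabilities: pd.DataFrame  # columns HC, aMCI, naMCI

    def difference(self, a: str, b: str) -> pd.Series:
        return self.liabilities[a] - self.liabilities[b]


@dataclass
class MultinomialRiskResults:
    alpha: float
    lambda_: float
    weights: pd.DataFrame  # features × classes
    liability_set: LiabilitySet
    aurocs: dict[str, float]  # the three pairwise tasks
    diagnosis: pd.Series
    seed: int

    def summary(self) -> str:
        lines = [
            "Multinomial PD risk scores (liability differences)",
            f"  alpha={self.alpha:.2f}  lambda={self.lambda_:.4g}",
        ]
        lines += [f"  AUROC {task}: {auc:.3f}" for task, auc in self.aurocs.items()]
        return "\n".join(lines)


class MultinomialRiskModel:
    """Penalized multinomial (HC / aMCI / naMCI) risk-score model."""

    CLASSES = ("HC", "aMCI", "naMCI")

    def __init__(self, table: FeatureTable, participants: pd.DataFrame,
                 config: RiskConfig | None = None):
        if not table.normalized:
            raise ValueError("risk models require a quantile-normalized table")
        self.table = FeatureTable(table.data.loc[participants.index],
                                  table.registry, table.normalized)
        self.participants = participants
        counts = participants["diagnosis"].value_counts()
        small = [g for g in self.CLASSES if counts.get(g, 0) < 3]
        if small:
            raise ValueError(
                f"group(s) {small} have fewer than 3 members; "
                "use the two-class PDRiskModel instead"
            )
        self.config = config or RiskConfig()
        p = len(self.table.registry)
        self.penalty_factor = np.concatenate([np.ones(p), np.zeros(2)])
        self.y = participants["diagnosis"].to_numpy()

    def _indicator(self) -> np.ndarray:
        Y = np.zeros((len(self.y), 3))
        for k, g in enumerate(self.CLASSES):
            Y[self.y == g, k] = 1.0
        return Y

    def fit(self, seed: int = 0) -> MultinomialRiskResults:
        cfg = self.config
        y_idx = np.array([self.CLASSES.index(g) for g in self.y])

        full_train, _ = _impute_pair(self.table, np.arange(len(self.y)),
                                     np.arange(0), cfg)
        X_full = _design(full_train, self.participants)
        grids = {
            a: lambda_path(X_full, self._indicator(), a, self.penalty_factor,
                           cfg.n_lambda, cfg.lambda_min_ratio)
            for a in cfg.alphas
        }
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=seed)
        dev = {a: np.zeros(cfg.n_lambda) for a in cfg.alphas}
        for tr, te in skf.split(X_full, self.y):
            tr_tab, te_tab = _impute_pair(self.table, tr, te, cfg)
            X_tr = _design(tr_tab, self.participants.iloc[tr])
            X_te = _design(te_tab, self.participants.iloc[te])
            for a in cfg.alphas:
                fits = multinomial_path(X_tr, y_idx[tr], grids[a], a,
                                        self.penalty_factor, tol=1e-6)
                for k, fit in enumerate(fits):
                    eta = fit.liabilities(X_te)
                    # align fit classes (subset possible in a fold) to full set
                    full_eta = np.full((len(te), 3), -35.0)
                    for ci, cls in enumerate(fit.classes):
                        full_eta[:, int(cls)] = eta[:, ci]
                    dev[a][k] += multinomial_deviance(y_idx[te], full_eta)
        best = min(
            ((a, k) for a in cfg.alphas for k in range(cfg.n_lambda)),
            key=lambda ak: (dev[ak[0]][ak[1]], ak[0], ak[1]),
        )
        alpha, k = best
        lam = float(grids[alpha][k])

        final = multinomial_path(X_full, y_idx, np.array([lam]), alpha,
                                 self.penalty_factor, tol=1e-7)[0]

        # liabilities from 10 further rounds of 5-fold CV, averaged
        liab = np.zeros((len(self.y), 3))
        for rep in range(cfg.repeats):
            skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                                  random_state=seed + 1000 + rep)
            for tr, te in skf.split(X_full, self.y):
                tr_tab, te_tab = _impute_pair(self.table, tr, te, cfg)
                X_tr = _design(tr_tab, self.participants.iloc[tr])
                X_te = _design(te_tab, self.participants.iloc[te])
                fit = multinomial_path(X_tr, y_idx[tr], np.array([lam]), alpha,
                                       self.penalty_factor, tol=1e-7)[0]
                eta = fit.liabilities(X_te)
                for ci, cls in enumerate(fit.classes):
                    liab[te, int(cls)] += eta[:, ci]
        liab /= cfg.repeats
        liab_df = pd.DataFrame(liab, index=self.participants.index,
                               columns=list(self.CLASSES))
        lset = LiabilitySet(liab_df)

        aurocs = {}
        for task, case, ctrl in (("aMCI-vs-HC", "aMCI", "HC"),
                                 ("naMCI-vs-HC", "naMCI", "HC"),
                                 ("aMCI-vs-naMCI", "aMCI", "naMCI")):
            mask = np.isin(self.y, (case, ctrl))
            diff = lset.difference(case, ctrl).to_numpy()[mask]
            labels = (self.y[mask] == case).astype(int)
            aurocs[task] = _metrics.auroc(diff, labels)

        names = self.table.registry.names + ["age", "gender"]
        weights = pd.DataFrame(final.coef, index=names, columns=list(self.CLASSES))
        return MultinomialRiskResults(
            alpha=float(alpha), lambda_=lam, weights=weights,
            liability_set=lset, aurocs=aurocs,
            diagnosis=self.participants["diagnosis"], seed=seed,
        )


def fit_multinomial_risk_scores(table: FeatureTable, participants: pd.DataFrame,
                                config: RiskConfig | None = None, seed: int = 0
                                ) -> MultinomialRiskResults:
    """Functional wrapper over :class:`MultinomialRiskModel`."""
    return MultinomialRiskModel(table, participants, config).fit(seed)


# ---------------------------------------------------------------------------
# report bundle


def report_tables(feature_screen, contrast_screen, risk_results, outdir,
                  table: FeatureTable | None = None,
                  participants: pd.DataFrame | None = None) -> dict:
    """Write CSV renditions of the screen and risk-score tables.

    Produces the per-feature screen table (sorted by ascending p), the contrast
    screen table with the pair split into feature-A / feature-B columns, the
    risk-score AUROC table (one row per task), and, when the feature table and
    participants are given, a long-format violin-plot-ready CSV of feature
    values by cohort.
    """
    from pathlib import Path

    from .tables import ContrastTable

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    if feature_screen is not None:
        path = outdir / "feature_screen.csv"
        feature_screen.to_csv(path)
        written["feature_screen"] = str(path)

    if contrast_screen is not None:
        frame = contrast_screen.frame.copy()
        if len(frame):
            ab = frame["target"].str.split(ContrastTable.SEP, regex=False)
            frame.insert(0, "feature_a", ab.str[0])
            frame.insert(1, "feature_b", ab.str[1])
            frame = frame.drop(columns=["target"])
        else:
            frame.insert(0, "feature_a", pd.Series(dtype=str))
            frame.insert(1, "feature_b", pd.Series(dtype=str))
        path = outdir / "contrast_screen.csv"
        frame.to_csv(path, index=False)
        written["contrast_screen"] = str(path)

    if risk_results:
        rows = [{"task": r.task, "auroc": r.auroc, "alpha": r.alpha,
                 "lambda": r.lambda_, "n_selected_features": len(r.weights)}
                for r in risk_results]
        path = outdir / "risk_scores.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written["risk_scores"] = str(path)
        for r in risk_results:
            spath = outdir / f"risk_scores_{r.task}.csv"
            r.scores.to_frame().to_csv(spath)
            written[f"scores_{r.task}"] = str(spath)

    if table is not None and participants is not None:
        long = table.data.copy()
        long["cohort"] = participants.loc[long.index, "diagnosis"]
        long = long.melt(id_vars="cohort", var_name="feature", value_name="value",
                         ignore_index=False)
        path = outdir / "violin_long.csv"
        long.to_csv(path)
        written["violin_long"] = str(path)
    return written
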