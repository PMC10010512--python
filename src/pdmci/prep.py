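"""Feature preparation: quantile normalization, split-aware imputation, contrasts.

* ``quantile_normalize`` maps each feature column onto standard-normal quantiles
  of its ranks, so every feature shares one distribution and contrasts are in
  standard-deviation units.
* ``SoftImpute`` / ``impute_split`` complete the six vocal-tremor columns by
  low-rank matrix completion (iterative soft-thresholded SVD), fitted separately
  on the train and test sides of a split so no information leaks across.
* ``build_contrasts`` forms all within-modality pairwise differences A − B of
  normalized features. Rows with a missing (hence imputed) value in either
  feature are excluded from that contrast: imputed values never enter contrasts
  or single-feature screens.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .registry import FeatureRegistry
from .tables import ContrastTable, FeatureTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize_column(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform Φ⁻¹(rank/(n+1)); ties get mean ranks.

    NaNs are preserved; ranks run over non-missing entries only.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("all-missing column cannot be normalized")
    ranks = rankdata(values[mask], method="average")
    out[mask] = norm.ppf(ranks / (n + 1.0))
    return out


def quantile_normalize(table: FeatureTable) -> FeatureTable:
    """Quantile normalize every column of a feature table (missing stays missing)."""
    if table.normalized:
        raise ValueError("table is already normalized")
    df = table.data.copy()
    for col in df.columns:
        if df[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing")
        df[col] = quantile_normalize_column(df[col].to_numpy())
    return FeatureTable(df, table.registry, normalized=True)


# ---------------------------------------------------------------------------
# SoftImpute matrix completion


class SoftImpute:
    """Low-rank matrix completion by iterative soft-thresholded SVD.

    Repeatedly fills missing entries with the current low-rank reconstruction,
    takes an SVD, soft-thresholds the singular values and truncates to
    ``max_rank``, until the reconstruction changes by less than ``tol``
    (relative Frobenius norm) or ``max_iters`` is reached. The shrinkage is
    annealed along a geometric path from half the leading singular value down
    to the target (``shrinkage_fraction`` of the leading singular value by
    default), warm-starting each level — the standard continuation scheme that
    avoids the poor fixed points of a single small shrinkage.
    """

    def __init__(self, max_rank: int = 5, shrinkage: float | None = None,
                 shrinkage_fraction: float = 0.01, tol: float = 1e-4,
                 max_iters: int = 200, n_shrinkage_levels: int = 8):
        self.max_rank = max_rank
        self.shrinkage = shrinkage
        self.shrinkage_fraction = shrinkage_fraction
        self.tol = tol
        self.max_iters = max_iters
        self.n_shrinkage_levels = n_shrinkage_levels

    def complete(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        missing = np.isnan(X)
        if not missing.any():
            return X.copy()
        # column-mean start (0 for all-missing columns, e.g. after normalization)
        col_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        filled = np.where(missing, col_means[None, :], X)
        s0 = float(np.linalg.svd(filled, compute_uv=False)[0])
        target = self.shrinkage if self.shrinkage is not None else (
            self.shrinkage_fraction * s0)
        start = 0.5 * s0
        if target > 0 and target < start:
            levels = np.geomspace(start, target, self.n_shrinkage_levels)
        elif target <= 0:
            levels = np.append(np.geomspace(start, 1e-3 * s0,
                                            self.n_shrinkage_levels - 1), 0.0)
        else:
            levels = np.array([target])
        prev = filled.copy()
        for shrink in levels:
            for _ in range(self.max_iters):
                U, s, Vt = np.linalg.svd(filled, full_matrices=False)
                s = np.maximum(s - shrink, 0.0)
                rank = min(self.max_rank, int((s > 0).sum()))
                Z = (U[:, :rank] * s[:rank]) @ Vt[:rank]
                filled = np.where(missing, Z, X)
                denom = np.linalg.norm(prev) or 1.0
                delta = np.linalg.norm(filled - prev) / denom
                prev = filled.copy()
                if delta < self.tol:
                    break
        return filled


def _complete_table(table: FeatureTable, imputer: SoftImpute) -> FeatureTable:
    df = table.data
    if not df.isna().any().any():
        return table.copy()
    # columns entirely missing in this split fall back to 0 (the column median
    # on the normalized scale), logged, before the low-rank completion
    df = df.copy()
    for col in df.columns:
        if df[col].isna().all():
            logger.warning("column %r entirely missing in split; filled with 0", col)
            df[col] = 0.0
    completed = imputer.complete(df.to_numpy())
    out = pd.DataFrame(completed, index=df.index, columns=df.columns)
    return FeatureTable(out, table.registry, table.normalized)


def impute_split(
    train: FeatureTable, test: FeatureTable | None = None,
    max_rank: int = 5, shrinkage: float | None = None,
    tol: float = 1e-4, max_iters: int = 200,
) -> tuple[FeatureTable, FeatureTable | None]:
    """Impute missing entries separately on each side of a train/test split.

    The completion fitted on the training rows never sees the test rows and
    vice versa, so imputed values cannot leak across the split.
    """
    imputer = SoftImpute(max_rank=max_rank, shrinkage=shrinkage,
                         tol=tol, max_iters=max_iters)
    train_out = _complete_table(train, imputer)
    test_out = _complete_table(test, imputer) if test is not None else None
    return train_out, test_out


# ---------------------------------------------------------------------------
# pairwise contrasts


def contrast_pairs(registry: FeatureRegistry) -> list[tuple[str, str]]:
    """All unordered same-modality pairs, A before B in registry order."""
    pairs = list(combinations(registry.language, 2))
    pairs += list(combinations(registry.acoustic, 2))
    return pairs


def build_contrasts(table: FeatureTable, registry: FeatureRegistry | None = None
                    ) -> ContrastTable:
    """Differences A − B of normalized features for all within-modality pairs.

    Requires a normalized table. Entries where either feature is missing are
    left missing (imputed values are not used for contrasts).
    """
    if not table.normalized:
        raise ValueError("contrasts require a quantile-normalized table")
    registry = registry if registry is not None else table.registry
    pairs = contrast_pairs(registry)
    values = {
        ContrastTable.key(a, b): table.data[a] - table.data[b] for a, b in pairs
    }
    df = pd.DataFrame(values, index=table.data.index)
    return ContrastTable(df, pairs)
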