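"""Quantile normalization, SoftImpute completion, and pairwise contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from pdmci.prep import (
    SoftImpute,
    build_contrasts,
    contrast_pairs,
    impute_split,
    quantile_normalize,
    quantile_normalize_column,
)
from pdmci.registry import FeatureRegistry
from pdmci.tables import ContrastTable, FeatureTable


def small_registry(n_ac=2, n_lang=3, missing=()):
    return FeatureRegistry.from_names(
        acoustic=[f"A{i}" for i in range(n_ac)],
        language=[f"L{i}" for i in range(n_lang)],
        may_be_missing=missing,
    )


def table_from(values: dict, registry, normalized=False):
    return FeatureTable(pd.DataFrame(values), registry, normalized)


class TestQuantileNormalize:
    def test_three_values_closed_form(self):
        out = quantile_normalize_column(np.array([3.2, 1.1, 5.0]))
        expected = np.array([0.0, norm.ppf(0.25), norm.ppf(0.75)])
        assert np.allclose(out, expected, atol=1e-4)
        assert round(float(out[2]), 4) == 0.6745

    def test_idempotent_on_grid(self):
        grid = norm.ppf(np.arange(1, 8) / 8.0)
        out = quantile_normalize_column(grid)
        assert np.allclose(out, grid, atol=1e-12)

    def test_constant_column_maps_to_zero(self):
        out = quantile_normalize_column(np.full(9, 3.7))
        assert np.allclose(out, 0.0)

    def test_missing_preserved(self):
        out = quantile_normalize_column(np.array([1.0, np.nan, 2.0, 3.0]))
        assert np.isnan(out[1])
        assert np.allclose(sorted(out[~np.isnan(out)]),
                           norm.ppf(np.array([1, 2, 3]) / 4.0))

    def test_all_missing_column_errors(self):
        reg = small_registry(missing=("A0",))
        tab = table_from({"A0": [np.nan, np.nan], "A1": [1.0, 2.0],
                          "L0": [1, 2], "L1": [3, 4], "L2": [5, 6]}, reg)
        with pytest.raises(ValueError, match="A0"):
            quantile_normalize(tab)

    def test_double_normalization_rejected(self):
        reg = small_registry()
        tab = table_from({"A0": [1.0, 2], "A1": [1.0, 2], "L0": [1, 2],
                          "L1": [3, 4], "L2": [5, 6]}, reg)
        out = quantile_normalize(tab)
        assert out.normalized
        with pytest.raises(ValueError, match="already"):
            quantile_normalize(out)

    @given(st.lists(st.integers(-5000, 5000), min_size=3, max_size=40, unique=True))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_to_monotone_transform(self, values):
        x = np.array(values, dtype=float) / 100.0
        base = quantile_normalize_column(x)
        transformed = quantile_normalize_column(np.exp(x / 25.0) + 3 * x)
        assert np.allclose(base, transformed, atol=1e-12)


class TestSoftImpute:
    def test_complete_data_identity(self):
        reg = small_registry()
        tab = table_from({"A0": [1.0, 2], "A1": [0.5, 1], "L0": [1, 2],
                          "L1": [3, 4], "L2": [5, 6]}, reg)
        out, _ = impute_split(tab)
        pd.testing.assert_frame_equal(out.data, tab.data)

    def test_rank1_recovery(self):
        rng = np.random.default_rng(12)
        u = rng.normal(size=200)
        v = rng.normal(size=30)
        X = np.outer(u, v)
        mask = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        completed = SoftImpute(max_rank=5, tol=1e-6, max_iters=300).complete(Xm)
        rmse = np.sqrt(np.mean((completed[mask] - X[mask]) ** 2))
        assert rmse < 0.1

    def test_no_leakage_across_split(self):
        reg = small_registry(missing=("A0",))

        def mk(seed):
            r = np.random.default_rng(seed)
            df = pd.DataFrame({
                "A0": r.normal(size=20), "A1": r.normal(size=20),
                "L0": r.normal(size=20), "L1": r.normal(size=20),
                "L2": r.normal(size=20)})
            df.loc[df.index[:3], "A0"] = np.nan
            return FeatureTable(df, reg)
        train = mk(1)
        tr_a, te_a = impute_split(train, mk(2))
        tr_b, te_b = impute_split(train, mk(3))  # different test rows
        pd.testing.assert_frame_equal(tr_a.data, tr_b.data)
        assert not te_a.data.equals(te_b.data)

    def test_entirely_missing_column_falls_back_to_zero(self):
        reg = small_registry(missing=("A0",))
        df = pd.DataFrame({"A0": [np.nan] * 5, "A1": np.arange(5.0),
                           "L0": np.arange(5.0), "L1": np.arange(5.0),
                           "L2": np.arange(5.0)})
        out, _ = impute_split(FeatureTable(df, reg))
        assert not out.data.isna().any().any()


class TestContrasts:
    def test_default_registry_counts(self, registry, normalized_cohort):
        _, norm_table, _ = normalized_cohort
        contrasts = build_contrasts(norm_table, registry)
        lang = [p for p in contrasts.pairs
                if registry.modality_of(p[0]) == "language"]
        ac = [p for p in contrasts.pairs
              if registry.modality_of(p[0]) == "acoustic"]
        assert len(lang) == 1081
        assert len(ac) == 946
        assert contrasts.n_contrasts == 2027
        # zero cross-modality pairs
        assert all(registry.modality_of(a) == registry.modality_of(b)
                   for a, b in contrasts.pairs)

    def test_worked_words_sentences_example(self):
        """Participant at +1 SD words and +2 SD sentences has a words−sentences
        contrast of −1; the reverse participant has +1."""
        reg = FeatureRegistry.from_names(
            acoustic=["A0", "A1"], language=["Count of words", "Count of sentences"])
        df = pd.DataFrame({"Count of words": [1.0, 2.0],
                           "Count of sentences": [2.0, 1.0],
                           "A0": [0.0, 0.0], "A1": [0.0, 0.0]})
        tab = FeatureTable(df, reg, normalized=True)
        contrasts = build_contrasts(tab, reg)
        col = contrasts.data[ContrastTable.key("Count of words", "Count of sentences")]
        assert col.tolist() == [-1.0, 1.0]

    def test_requires_normalized(self, default_cohort):
        _, table, _, _ = default_cohort
        with pytest.raises(ValueError, match="normalized"):
            build_contrasts(table)

    def test_antisymmetry_and_no_self_pairs(self, normalized_cohort):
        _, norm_table, _ = normalized_cohort
        contrasts = build_contrasts(norm_table)
        a, b = contrasts.pairs[0]
        assert a != b
        flipped = norm_table.data[b] - norm_table.data[a]
        assert np.allclose(-flipped.dropna(),
                           contrasts.data[ContrastTable.key(a, b)].dropna())

    def test_contrast_linearity(self, normalized_cohort):
        _, norm_table, _ = normalized_cohort
        contrasts = build_contrasts(norm_table)
        la, lb, lc = norm_table.registry.language[:3]
        ab = contrasts.data[ContrastTable.key(la, lb)]
        bc = contrasts.data[ContrastTable.key(lb, lc)]
        ac = contrasts.data[ContrastTable.key(la, lc)]
        assert np.allclose(ab + bc, ac)

    @given(st.integers(2, 12), st.integers(2, 12))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_pair_count_conservation(self, n_lang, n_ac):
        reg = small_registry(n_ac=n_ac, n_lang=n_lang)
        pairs = contrast_pairs(reg)
        expected = n_lang * (n_lang - 1) // 2 + n_ac * (n_ac - 1) // 2
        assert len(pairs) == expected

    def test_missing_rows_stay_missing(self, normalized_cohort):
        """Contrasts involving a missing tremor value are missing, never imputed."""
        _, norm_table, _ = normalized_cohort
        tremor = norm_table.registry.may_be_missing[0]
        other = norm_table.registry.acoustic[0]
        contrasts = build_contrasts(norm_table)
        key = ContrastTable.key(other, tremor)
        na_rows = norm_table.data[tremor].isna()
        assert contrasts.data.loc[na_rows, key].isna().all()
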