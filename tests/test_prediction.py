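"""Marker filters, KNN imputation, RR-BLUP prediction and cross-validation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gbskit.prediction import (
    RidgeBLUP,
    count_shared_polymorphic,
    cross_validate,
    knn_impute,
    locus_maf,
    maf_filter,
    mean_impute,
    missing_rate_filter,
    missing_threshold_sweep,
)
from gbskit.synthetic import PanelSpec, TraitSpec, simulate_genotype_panel, simulate_trait


def _structured_panel(n=60, L=120, seed=0):
    """Panel with relatedness structure: two founder haplotype groups."""
    rng = np.random.default_rng(seed)
    founders = rng.integers(0, 3, size=(2, L)).astype(float)
    rows = []
    for i in range(n):
        base = founders[i % 2].copy()
        flip = rng.random(L) < 0.1
        base[flip] = rng.integers(0, 3, size=int(flip.sum()))
        rows.append(base)
    return pd.DataFrame(
        rows, index=[f"G{i}" for i in range(n)], columns=[f"L{j}" for j in range(L)]
    )


class TestMafFilter:
    def test_single_het_carrier_removed(self):
        # 40 genotypes, one heterozygote: MAF = 1/80 = 1.25% < 2.5%
        col = np.zeros(40)
        col[0] = 1
        m = pd.DataFrame({"L1": col, "L2": np.tile([0, 2], 20)})
        out = maf_filter(m, min_maf=0.025)
        assert list(out.columns) == ["L2"]

    def test_boundary_maf_retained(self):
        # MAF exactly 2.5%: one hom-alt carrier in 40 genotypes = 2/80
        col = np.zeros(40)
        col[0] = 2
        m = pd.DataFrame({"L1": col})
        assert locus_maf(m)["L1"] == pytest.approx(0.025)
        assert list(maf_filter(m, min_maf=0.025).columns) == ["L1"]

    def test_monomorphic_removed(self):
        m = pd.DataFrame({"L1": np.zeros(10), "L2": np.tile([0.0, 2.0], 5)})
        assert list(maf_filter(m).columns) == ["L2"]

    def test_all_removed_warns_and_returns_empty(self):
        m = pd.DataFrame({"L1": np.zeros(10)})
        with pytest.warns(UserWarning, match="every locus"):
            out = maf_filter(m)
        assert out.shape[1] == 0


class TestMissingRateFilter:
    def test_zero_threshold_keeps_only_complete_loci(self):
        m = pd.DataFrame({"L1": [0, np.nan, 2], "L2": [0, 1, 2]})
        assert list(missing_rate_filter(m, 0.0).columns) == ["L2"]

    def test_threshold_one_is_identity(self):
        m = pd.DataFrame({"L1": [0, np.nan, 2], "L2": [np.nan] * 3})
        assert list(missing_rate_filter(m, 1.0).columns) == ["L1", "L2"]

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.integers(0, 3, size=(30, 50)).astype(float))
        mask = rng.random((30, 50)) < 0.3
        m[mask] = np.nan
        out = missing_rate_filter(m, 0.25)
        expected = [c for c in m.columns if m[c].isna().mean() <= 0.25]
        assert list(out.columns) == expected

    def test_filters_commute_on_surviving_set(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.integers(0, 3, size=(40, 60)).astype(float))
        m[rng.random((40, 60)) < 0.2] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = maf_filter(missing_rate_filter(m, 0.3))
            b = missing_rate_filter(maf_filter(m), 0.3)
        assert set(a.columns) == set(b.columns)


class TestKnnImpute:
    def test_no_missing_is_identity(self):
        m = _structured_panel()
        pd.testing.assert_frame_equal(knn_impute(m), m)

    def test_exact_duplicates_recover_missing_entry(self):
        base = np.tile([0.0, 1.0, 2.0, 0.0], (6, 5))[:6]
        m = pd.DataFrame(base.copy())
        m.iloc[0, 0] = np.nan
        out = knn_impute(m, k=5)
        assert out.iloc[0, 0] == base[1, 0]

    def test_observed_entries_never_altered(self):
        rng = np.random.default_rng(2)
        m = _structured_panel(seed=2)
        mask = rng.random(m.shape) < 0.1
        missing = m.copy()
        missing[mask] = np.nan
        out = knn_impute(missing)
        obs = ~np.asarray(missing.isna())
        assert (out.to_numpy()[obs] == m.to_numpy()[obs]).all()
        assert set(np.unique(out.to_numpy())) <= {0.0, 1.0, 2.0}

    def test_beats_mean_imputation_on_structured_panel(self):
        """KNN imputation error < column-mean error over 10 seeds."""
        knn_err, mean_err = [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            truth = _structured_panel(seed=seed)
            holes = truth.copy()
            mask = rng.random(truth.shape) < 0.1
            holes[mask] = np.nan
            t = truth.to_numpy()
            k_out = knn_impute(holes).to_numpy()
            m_out = mean_impute(holes).to_numpy()
            knn_err.append((k_out[mask] != t[mask]).mean())
            mean_err.append((m_out[mask] != t[mask]).mean())
        assert np.mean(knn_err) < np.mean(mean_err)

    def test_disconnected_genotype_named_in_error(self):
        m = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 1.0]], index=["gA", "gB"], columns=["L1", "L2"]
        )
        with pytest.raises(ValueError, match="gA"):
            knn_impute(m)


class TestRidgeBLUP:
    def _additive_data(self, n=200, p=50, h2=1.0, seed=0):
        panel = simulate_genotype_panel(
            [f"L{j}" for j in range(p)],
            PanelSpec(
                n_genotypes=n, breeding_system="outbred", snp_rate=1.0,
                maf_low=0.15, maf_high=0.5, seed=seed,
            ),
        )
        y, g = simulate_trait(panel, TraitSpec(n_qtl=min(20, p), h2=h2, seed=seed))
        return panel.astype(float), y

    def test_infinite_shrinkage_predicts_training_mean(self):
        X, y = self._additive_data(n=50, p=10)
        res = RidgeBLUP(X, y).fit(shrinkage=1e12)
        assert res.fittedvalues() == pytest.approx(np.full(50, y.mean()), abs=1e-3)

    def test_zero_shrinkage_single_perfect_marker(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=80)
        X = pd.DataFrame({"m": x})
        y = 3.0 * x + 1.0
        res = RidgeBLUP(X, y).fit(shrinkage=1e-8)
        assert np.corrcoef(res.fittedvalues(), y)[0, 1] == pytest.approx(1.0)

    def test_heritable_trait_recovered_out_of_sample(self):
        """n=200, p=50, h2=1 additive trait: held-out ability > 0.95."""
        X, y = self._additive_data(n=200, p=50, h2=1.0, seed=1)
        cv = cross_validate(X, y, n_folds=5, n_reps=2, seed=1)
        assert cv.ability > 0.95

    def test_zero_variance_phenotype_rejected(self):
        X, _ = self._additive_data(n=30, p=5)
        with pytest.raises(ValueError, match="variance"):
            RidgeBLUP(X, np.ones(30))

    def test_missing_markers_rejected(self):
        X, y = self._additive_data(n=30, p=5)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            RidgeBLUP(X, y)

    def test_summary_mentions_fit(self):
        X, y = self._additive_data(n=60, p=10, h2=0.8, seed=3)
        res = RidgeBLUP(X, y).fit()
        text = res.summary()
        assert "shrinkage lambda" in text and "markers" in text


class TestCrossValidate:
    def _data(self, h2, seed=0, n=120, p=60):
        panel = simulate_genotype_panel(
            [f"L{j}" for j in range(p)],
            PanelSpec(
                n_genotypes=n, breeding_system="outbred", snp_rate=1.0,
                maf_low=0.15, maf_high=0.5, seed=seed,
            ),
        )
        y, _ = simulate_trait(panel, TraitSpec(n_qtl=min(25, p // 2), h2=h2, seed=seed))
        return panel.astype(float), y

    def test_permuted_phenotype_gives_null_ability(self):
        X, y = self._data(h2=1.0, seed=4)
        rng = np.random.default_rng(4)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        cv = cross_validate(X, y_perm, n_folds=5, n_reps=5, seed=4)
        sd = np.std(cv.per_rep, ddof=1) if len(cv.per_rep) > 1 else 0.1
        assert abs(cv.ability) <= max(3 * sd, 0.25)

    def test_identical_seed_identical_result(self):
        X, y = self._data(h2=0.6, seed=5)
        a = cross_validate(X, y, n_folds=5, n_reps=2, seed=11)
        b = cross_validate(X, y, n_folds=5, n_reps=2, seed=11)
        assert a.ability == b.ability and a.per_rep == b.per_rep

    def test_ability_monotone_in_heritability(self):
        """Mean ability rises over h2 in {0.2, 0.5, 0.8} (10 seeds each)."""
        means = []
        for h2 in (0.2, 0.5, 0.8):
            vals = [
                cross_validate(*self._data(h2=h2, seed=s), n_folds=5, n_reps=1,
                               seed=s).ability
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_correlations_bounded(self):
        X, y = self._data(h2=0.5, seed=6)
        cv = cross_validate(X, y, n_folds=5, n_reps=3, seed=6)
        assert all(-1.0 <= r <= 1.0 for r in cv.per_rep + cv.per_fold)

    def test_too_few_genotypes_rejected(self):
        X, y = self._data(h2=0.5, seed=7, n=8, p=10)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, y, n_folds=10)


class TestCountSharedPolymorphic:
    def test_monomorphic_complete_locus_not_counted(self):
        m = pd.DataFrame({"L1": [0.0, 0.0, 0.0], "L2": [0.0, 1.0, 2.0]})
        assert count_shared_polymorphic(m) == 1

    def test_segregating_locus_with_missing_not_counted(self):
        m = pd.DataFrame({"L1": [0.0, np.nan, 2.0]})
        assert count_shared_polymorphic(m) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.integers(0, 3, size=(20, 80)).astype(float))
        m[rng.random((20, 80)) < 0.15] = np.nan
        brute = sum(
            1
            for c in m.columns
            if m[c].notna().all() and m[c].nunique() > 1
        )
        assert count_shared_polymorphic(m) == brute


class TestMissingThresholdSweep:
    def _sparse_dataset(self, seed):
        rng = np.random.default_rng(seed)
        truth = _structured_panel(n=70, L=150, seed=seed)
        y = truth.to_numpy() @ rng.normal(size=150) * 0.1
        y = y + rng.normal(scale=np.std(y), size=70)
        holes = truth.copy()
        # heterogeneous per-locus missingness so thresholds bite
        per_locus = rng.uniform(0, 0.5, size=150)
        mask = rng.random(truth.shape) < per_locus
        holes[mask] = np.nan
        return holes, pd.Series(y, index=truth.index)

    def test_marker_count_non_decreasing_in_threshold(self):
        holes, y = self._sparse_dataset(0)
        table = missing_threshold_sweep(
            holes, y, thresholds=[0.0, 0.3, 0.8], n_folds=5, n_reps=1, seed=0
        )
        counts = table["n_markers"].tolist()
        assert counts == sorted(counts)
        assert len(table) == 3

    def test_complete_data_ability_constant_across_thresholds(self):
        complete = _structured_panel(n=50, L=80, seed=9)
        rng = np.random.default_rng(9)
        y = pd.Series(
            complete.to_numpy() @ rng.normal(size=80), index=complete.index
        )
        table = missing_threshold_sweep(
            complete, y, thresholds=[0.0, 0.3, 0.6], n_folds=5, n_reps=1, seed=9
        )
        assert table["ability"].nunique() == 1
        assert table["n_markers"].nunique() == 1
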