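import numpy as np
import pandas as pd
import pytest

from phyloxylem import VariancePartition, partition, partition_suite
from phyloxylem.partition import ConfoundedDesignError

from conftest import brownian_traits


def projection_ess(y, X):
    """Oracle: explained SS via the explicit hat matrix of [1, X]."""
    n = len(y)
    D = np.column_stack([np.ones(n)] + ([X] if X is not None and X.size else []))
    P = D @ np.linalg.pinv(D)
    yc = y - y.mean()
    fitted = P @ y
    return float(np.sum((fitted - y.mean()) ** 2))


class TestHandExamples:
    def test_pure_group_structure(self):
        """y equal to its group means with constant climate: all explained
        variance is phylogeny-only."""
        y = np.array([1.0, 1.0, 5.0, 5.0, 9.0, 9.0])
        groups = np.array([0, 0, 1, 1, 2, 2])
        clim = np.full((6, 1), 3.0)  # constant -> dropped as uninformative
        res = partition(y, clim, groups)
        assert res.percent["phylo_only"] == pytest.approx(100.0)
        assert res.percent["climate_only"] == pytest.approx(0.0)
        assert res.percent["shared"] == pytest.approx(0.0)
        assert res.percent["unexplained"] == pytest.approx(0.0)

    def test_pure_climate_structure(self):
        """Hand ANOVA: groups {s1,s2},{s3,s4}, x = (0,2,0,2), y = x.
        Group means are equal (SS_groups = 0) while climate explains all
        of the total SS of 4."""
        y = np.array([0.0, 2.0, 0.0, 2.0])
        x = np.array([0.0, 2.0, 0.0, 2.0])
        groups = np.array([0, 0, 1, 1])
        res = partition(y, x, groups)
        assert res.ss["total"] == pytest.approx(4.0)
        assert res.percent["climate_only"] == pytest.approx(100.0)
        assert res.percent["phylo_only"] == pytest.approx(0.0, abs=1e-9)
        assert res.percent["shared"] == pytest.approx(0.0, abs=1e-9)


class TestAdditivityAndOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_components_sum_to_total(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 2))
        groups = rng.integers(0, 4, n)
        if len(np.unique(groups)) < 2:
            groups[0], groups[1] = 0, 1
        res = partition(y, X, groups)
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-8)
        comp_sum = sum(res.ss[k] for k in ("phylo_only", "climate_only", "shared", "unexplained"))
        assert comp_sum == pytest.approx(res.ss["total"], rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_projection_matrix_oracle(self, seed):
        """phylo_only must equal the increment in explained SS from adding
        the group factor to the climate model (computed via explicit
        projection matrices)."""
        rng = np.random.default_rng(100 + seed)
        n = 18
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 2))
        groups = np.repeat(np.arange(3), 6)
        G = pd.get_dummies(groups, drop_first=True).to_numpy(float)
        res = partition(y, X, groups)
        ess_clim = projection_ess(y, X)
        ess_grp = projection_ess(y, G)
        ess_full = projection_ess(y, np.column_stack([G, X]))
        assert res.ss["phylo_only"] == pytest.approx(ess_full - ess_clim, abs=1e-8)
        assert res.ss["climate_only"] == pytest.approx(ess_full - ess_grp, abs=1e-8)
        assert res.ss["shared"] == pytest.approx(
            ess_grp + ess_clim - ess_full, abs=1e-8
        )

    def test_df_accounting(self):
        rng = np.random.default_rng(7)
        n = 30
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 3))
        groups = np.repeat(np.arange(5), 6)
        res = partition(y, X, groups)
        assert sum(res.df.values()) == n - 1
        assert res.df["phylo_only"] == 4
        assert res.df["climate_only"] == 3


class TestInvariances:
    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        n = 24
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 2))
        groups = np.repeat(np.arange(4), 6)
        relabeled = np.array([10, 7, 99, 3])[groups]
        a = partition(y, X, groups)
        b = partition(y, X, relabeled)
        for k in a.percent:
            assert a.percent[k] == pytest.approx(b.percent[k], abs=1e-9)

    def test_affine_climate_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        n = 24
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 2))
        groups = np.repeat(np.arange(4), 6)
        a = partition(y, X, groups)
        b = partition(y, X * [100.0, 0.01] + [3.0, -7.0], groups)
        for k in a.percent:
            assert a.percent[k] == pytest.approx(b.percent[k], abs=1e-8)

    def test_empty_climate_reduces_to_anova_r2(self):
        rng = np.random.default_rng(10)
        n = 24
        groups = np.repeat(np.arange(4), 6)
        y = groups * 2.0 + rng.standard_normal(n)
        res = partition(y, None, groups)
        # one-way ANOVA R^2 oracle
        G = pd.get_dummies(groups, drop_first=True).to_numpy(float)
        r2 = projection_ess(y, G) / np.sum((y - y.mean()) ** 2)
        assert res.percent["phylo_only"] == pytest.approx(100 * r2, abs=1e-8)
        assert res.percent["climate_only"] == pytest.approx(0.0, abs=1e-9)


class TestErrorsAndEstimator:
    def test_confounded_design_error(self):
        rng = np.random.default_rng(11)
        n = 12
        groups = np.repeat([0, 1], 6)
        y = rng.standard_normal(n)
        x = (groups == 1).astype(float)  # exactly the group indicator
        with pytest.raises(ConfoundedDesignError):
            partition(y, x, groups)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            partition(np.arange(6.0), None, np.zeros(6, dtype=int))

    def test_estimator_surface(self):
        rng = np.random.default_rng(12)
        n = 24
        groups = np.repeat(np.arange(4), 6)
        y = groups * 1.0 + rng.standard_normal(n)
        X = rng.standard_normal((n, 1))
        vp = VariancePartition(grouping=groups).fit(X, y)
        assert vp.percent_phylogeny_ + vp.percent_climate_ + vp.percent_shared_ + vp.percent_unexplained_ == pytest.approx(100.0)


class TestSuiteOnTree:
    def test_partition_suite_rows_and_additivity(self, dataset200):
        tree, table = dataset200.tree, dataset200.table
        traits = np.sqrt(table[["VF", "FF"]])
        out = partition_suite(
            traits, table[["MAT", "MTCM"]], tree, cut_times=(59.0, 28.0)
        )
        assert len(out) == 4
        sums = out[[f"pct_{c}" for c in ("phylo_only", "climate_only", "shared", "unexplained")]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-6)

    def test_bm_traits_have_small_climate_only(self, yule150, cov150):
        """Pure-BM traits with climate uncorrelated to the tree: the
        climate-only share stays small on average."""
        rng = np.random.default_rng(13)
        g = yule150.cut(50.0)
        labels = g.labels(yule150.tip_labels)
        vals = []
        for _ in range(50):
            y = brownian_traits(cov150, 1.0, 1.0, rng)[:, 0]
            X = rng.standard_normal((150, 2))
            vals.append(partition(y, X, labels).percent["climate_only"])
        assert np.mean(vals) <= 5.0

    def test_star_grouping_with_pure_climate_effect(self, yule150):
        """A trait that is a pure climate effect shows ~no phylogeny-only
        component when groups are arbitrary singleton-free labels."""
        rng = np.random.default_rng(14)
        x = rng.standard_normal(150)
        y = 2.0 * x  # exact climate determinism
        labels = rng.integers(0, 10, 150)
        res = partition(y, x, labels)
        assert res.percent["phylo_only"] == pytest.approx(0.0, abs=1e-6)
        assert res.percent["unexplained"] == pytest.approx(0.0, abs=1e-6)
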