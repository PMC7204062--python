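"""ANOVA components, heritability, BLUEs, clustering, correlations."""

import numpy as np
import pandas as pd
import pytest

from rindqtl import pheno
from rindqtl import simulate as sim

from .conftest import balanced_table


def brute_force_mean_squares(y):
    """Independent sums-of-squares oracle via raw loops."""
    n, e, r = y.shape
    grand = y.mean()
    ss_g = sum(e * r * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_e = sum(n * r * (y[:, j].mean() - grand) ** 2 for j in range(e))
    ss_rep = sum(
        n * (y[:, j, k].mean() - y[:, j].mean()) ** 2 for j in range(e) for k in range(r)
    )
    ss_ge = sum(
        r * (y[i, j].mean() - y[i].mean() - y[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(e)
    )
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_g - ss_e - ss_rep - ss_ge
    return {
        "MS_G": ss_g / (n - 1),
        "MS_GE": ss_ge / ((n - 1) * (e - 1)),
        "MSE": ss_err / ((n - 1) * e * (r - 1)),
    }


class TestAnovaComponents:
    def test_all_equal_gives_zero_components(self):
        y = np.full((5, 2, 2), 3.14)
        vc = pheno.anova_components(balanced_table(y))
        assert (vc.sigma2_g, vc.sigma2_ge, vc.sigma2_eps) == (0.0, 0.0, 0.0)

    def test_components_match_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.normal(4.0, 1.0, (12, 2, 2))
        ms = brute_force_mean_squares(y)
        vc = pheno.anova_components(balanced_table(y))
        e, r = 2, 2
        assert vc.sigma2_eps == pytest.approx(ms["MSE"], abs=1e-10)
        assert vc.sigma2_ge == pytest.approx(max((ms["MS_GE"] - ms["MSE"]) / r, 0), abs=1e-10)
        assert vc.sigma2_g == pytest.approx(max((ms["MS_G"] - ms["MS_GE"]) / (r * e), 0), abs=1e-10)

    def test_constructed_mean_squares_give_2_1_1(self):
        # engineer a table whose mean squares are exactly MS_G=11, MS_GE=3, MSE=1
        # then sigma2_g = (11-3)/4 = 2, sigma2_ge = (3-1)/2 = 1, sigma2_eps = 1
        rng = np.random.default_rng(1)
        n, e, r = 40, 2, 2

        def scaled(x, target_ms, df, mult):
            x = x - x.mean()
            ss = (x**2).sum() * mult
            return x * np.sqrt(target_ms * df / ss)

        g = scaled(rng.normal(size=n), 11.0, n - 1, e * r)
        ge = rng.normal(size=(n, e))
        ge = ge - ge.mean(axis=0) - ge.mean(axis=1)[:, None] + ge.mean()
        ge = ge * np.sqrt(3.0 * (n - 1) * (e - 1) / (r * (ge**2).sum()))
        eps = rng.normal(size=(n, e, r))
        # project onto the pure error stratum (orthogonal to cell and rep means)
        eps = (
            eps
            - eps.mean(axis=2, keepdims=True)
            - eps.mean(axis=0, keepdims=True)
            + eps.mean(axis=(0, 2), keepdims=True)
        )
        eps = eps * np.sqrt(1.0 * (n - 1) * e * (r - 1) / ((eps**2).sum()))
        y = g[:, None, None] + ge[:, :, None] + eps
        vc = pheno.anova_components(balanced_table(y))
        assert vc.sigma2_g == pytest.approx(2.0, rel=1e-6)
        assert vc.sigma2_ge == pytest.approx(1.0, rel=1e-6)
        assert vc.sigma2_eps == pytest.approx(1.0, rel=1e-6)

    def test_noiseless_replicates_give_zero_mse(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 2, 1))
        y = np.repeat(base, 2, axis=2)  # replicates identical
        vc = pheno.anova_components(balanced_table(y))
        assert vc.sigma2_eps == 0.0

    def test_unbalanced_rejected_with_named_cell(self):
        y = np.zeros((3, 2, 2))
        t = balanced_table(y)
        t = t[~((t["line"] == "L1") & (t["env"] == "E2") & (t["rep"] == 1))]
        with pytest.raises(ValueError, match="L1.*E2"):
            pheno.anova_components(t)

    def test_single_environment_drops_ge(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(10, 1, 3))
        vc = pheno.anova_components(balanced_table(y))
        assert vc.e == 1 and vc.sigma2_ge == 0.0


class TestHeritability:
    def test_printed_formula_value(self):
        vc = pheno.VarianceComponents(sigma2_g=2, sigma2_ge=1, sigma2_eps=2, e=2, r=2)
        assert pheno.broad_sense_heritability(vc) == pytest.approx(2 / 3)

    def test_limits(self):
        assert pheno.broad_sense_heritability(
            pheno.VarianceComponents(1.0, 0.0, 0.0, e=2, r=2)
        ) == 1.0
        assert pheno.broad_sense_heritability(
            pheno.VarianceComponents(0.0, 1.0, 1.0, e=2, r=2)
        ) == 0.0

    def test_all_zero_warns_and_returns_zero(self):
        vc = pheno.VarianceComponents(0.0, 0.0, 0.0, e=1, r=1)
        with pytest.warns(UserWarning):
            assert pheno.broad_sense_heritability(vc) == 0.0

    @pytest.mark.parametrize("grid", [np.linspace(0.2, 3.0, 5)])
    def test_monotonicity_in_components(self, grid):
        base = dict(sigma2_ge=0.5, sigma2_eps=0.5, e=2, r=2)
        h_up = [
            pheno.broad_sense_heritability(pheno.VarianceComponents(sigma2_g=g, **base))
            for g in grid
        ]
        assert np.all(np.diff(h_up) > 0)
        h_down = [
            pheno.broad_sense_heritability(
                pheno.VarianceComponents(sigma2_g=1.0, sigma2_ge=v, sigma2_eps=0.5, e=2, r=2)
            )
            for v in grid
        ]
        assert np.all(np.diff(h_down) < 0)


class TestBLUE:
    def test_balanced_equals_line_means(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(15, 2, 2))
        t = balanced_table(y)
        blue = pheno.estimate_blue(t)
        means = t.groupby("line")["value"].mean()
        assert np.max(np.abs(blue - means[blue.index])) < 1e-8

    def test_location_equivariance(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(10, 2, 2))
        t = balanced_table(y)
        b0 = pheno.estimate_blue(t)
        t2 = t.assign(value=t["value"] + 7.5)
        b1 = pheno.estimate_blue(t2)
        assert np.allclose(b1 - b0, 7.5, atol=1e-8)

    def test_unbalanced_matches_dense_gls_oracle(self):
        # 3 lines, env E2 missing one line entirely
        rows = [
            ("A", "E1", 1, 5.0), ("A", "E1", 2, 5.4), ("A", "E2", 1, 6.0), ("A", "E2", 2, 6.2),
            ("B", "E1", 1, 4.0), ("B", "E1", 2, 4.2), ("B", "E2", 1, 5.1), ("B", "E2", 2, 5.3),
            ("C", "E1", 1, 7.0), ("C", "E1", 2, 7.4),
        ]
        t = pd.DataFrame(rows, columns=["line", "env", "rep", "value"])
        vc = pheno.VarianceComponents(sigma2_g=1.0, sigma2_ge=0.4, sigma2_eps=0.2, e=2, r=2)
        blue = pheno.estimate_blue(t, components=vc)

        # independent dense GLS with the same model
        lines = ["A", "B", "C"]
        envs = ["E1", "E2"]
        li = np.array([lines.index(r[0]) for r in rows])
        ei = np.array([envs.index(r[1]) for r in rows])
        ri = np.array([envs.index(r[1]) * 2 + (r[2] - 1) for r in rows])
        yv = np.array([r[3] for r in rows])
        le = li * 2 + ei
        V = (
            0.4 * (le[:, None] == le[None, :])
            + 0.0 * (ri[:, None] == ri[None, :])
            + 0.2 * np.eye(len(yv))
        )
        X = np.zeros((len(yv), 4))
        X[np.arange(len(yv)), li] = 1
        X[:, 3] = (ei == 0) * 1.0 - (ei == 1) * 1.0
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ yv)
        assert np.allclose(blue.to_numpy(), beta[:3], atol=1e-8)

    def test_reml_close_to_moments_on_balanced_data(self):
        rng = np.random.default_rng(6)
        g = rng.normal(0, 1, 12)
        y = g[:, None, None] + rng.normal(0, 0.5, (12, 2, 2))
        t = balanced_table(y)
        b_m = pheno.estimate_blue(t, method="moments")
        b_r = pheno.estimate_blue(t, method="reml")
        assert np.max(np.abs(b_m - b_r)) < 1e-6  # balance collapses both to means


class TestClustering:
    def test_self_distance_zero_and_symmetry(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("ABCD"))
        res = pheno.standardize_and_cluster(m)
        d = res.distances
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)

    def test_two_line_antithetic_distance(self):
        # standardized columns (1,-1)/sd and (-1,1)/sd -> D = 2*sqrt(2)
        m = pd.DataFrame({"A": [1.0, -1.0], "B": [-1.0, 1.0]})
        res = pheno.standardize_and_cluster(m)
        assert res.distances.loc["A", "B"] == pytest.approx(2 * np.sqrt(2), abs=1e-10)

    def test_duplicated_stage_merges_first_at_zero(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=20)
        m = pd.DataFrame({"A": base, "B": base, "C": rng.normal(size=20)})
        res = pheno.standardize_and_cluster(m)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-10)
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 1}

    def test_zero_variance_column_rejected(self):
        m = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            pheno.standardize_and_cluster(m)

    def test_standardized_columns_unit_population_variance(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(2, 3, size=(30, 5)))
        z, _ = pheno.standardize_stage_matrix(m)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-10)

    def test_low_correlation_stage_is_outgroup(self):
        # V10-like stage with r_g <= 0.3 to the rest joins the tree last
        corr = np.full((4, 4), 0.85)
        np.fill_diagonal(corr, 1.0)
        corr[0, 1:] = corr[1:, 0] = 0.25
        cfg = sim.SimConfig(
            n_lines=250,
            chromosomes=(sim.ChromosomeSpec(100.0, 1_000_000, 21),),
            stage_names=("V10x", "S2", "S3", "S4"),
            genetic_corr=corr,
            h2_target=(0.8, 0.8, 0.8, 0.8),
            seed=21,
        )
        gmap = sim.simulate_genetic_map(cfg)
        pop, arch = sim.simulate_ril_population(gmap, 250, seed=21)
        table = sim.simulate_phenotypes(pop, arch, cfg)
        blues = {
            st: pheno.estimate_blue(table[table["stage"] == st].drop(columns="stage"))
            for st in cfg.stage_names
        }
        res = pheno.standardize_and_cluster(pd.DataFrame(blues))
        import scipy.cluster.hierarchy as h

        # cutting the tree into 2 clusters isolates the V10 analog (leaf 0)
        two = h.fcluster(res.linkage, t=2, criterion="maxclust")
        assert (two == two[0]).sum() == 1


class TestCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(10)
        g = rng.normal(0, 2.0, 30)  # real line effects so var_g > 0
        y = g[:, None, None] + rng.normal(size=(30, 2, 2))
        t = balanced_table(y)
        t2 = pd.concat([t.assign(stage="S1"), t.assign(stage="S2")])
        res = pheno.correlations(t2)
        assert res.r_p.loc["S1", "S2"] == pytest.approx(1.0)
        assert res.r_g.loc["S1", "S2"] == pytest.approx(1.0)

    def test_rg_recovers_generative_value(self):
        rng = np.random.default_rng(11)
        n, e, r = 100, 2, 2
        rho = 0.8
        L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
        vals = []
        for _ in range(200):
            g = rng.normal(size=(n, 2)) @ L.T
            ya = g[:, 0:1, None] + rng.normal(0, 0.7, (n, e, r))
            yb = g[:, 1:2, None] + rng.normal(0, 0.7, (n, e, r))
            t = pd.concat(
                [balanced_table(ya).assign(stage="A"), balanced_table(yb).assign(stage="B")]
            )
            vals.append(pheno.correlations(t).r_g.loc["A", "B"])
        assert np.nanmean(vals) == pytest.approx(0.8, abs=0.05)

    def test_independent_traits_rp_near_zero(self):
        rng = np.random.default_rng(12)
        n, e, r = 200, 1, 2
        means = []
        for _ in range(200):
            ya = rng.normal(size=(n, e, r))
            yb = rng.normal(size=(n, e, r))
            t = pd.concat(
                [balanced_table(ya).assign(stage="A"), balanced_table(yb).assign(stage="B")]
            )
            wide_a = t[t.stage == "A"].groupby("line")["value"].mean()
            wide_b = t[t.stage == "B"].groupby("line")["value"].mean()
            means.append(np.corrcoef(wide_a, wide_b[wide_a.index])[0, 1])
        assert abs(np.mean(means)) < 0.03

    def test_too_few_lines_rejected(self):
        t = pd.DataFrame(
            {"line": ["A", "B"], "env": ["E1", "E1"], "stage": ["S1", "S1"],
             "rep": [1, 1], "value": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="shared lines"):
            pheno.correlations(t)
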