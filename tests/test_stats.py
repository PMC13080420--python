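"""Statistical layer tests: ANOVA oracle equivalence, variance components,
heritability, CV, correlations and PCA."""

import numpy as np
import pandas as pd
import pytest

from peapheno.simulate import SimulationParams, simulate_study, simulate_trait_table
from peapheno.stats import (
    AnovaTable,
    coefficient_of_variation,
    correlation_matrix,
    correlation_network,
    estimate_variance_components,
    heritability,
    pca_biplot,
    relative_contributions,
    to_wide,
    two_way_anova,
    VarianceDecomposition,
)


def long_table(cube: np.ndarray, trait="y") -> pd.DataFrame:
    g, c, r = cube.shape
    rows = []
    for i in range(g):
        for j in range(c):
            for k in range(r):
                rows.append(dict(
                    accession=f"A{i:02d}", species_group="g",
                    condition=["control", "drought"][j] if c == 2 else f"cond{j+1}",
                    replicate=k + 1, trait=trait, value=cube[i, j, k],
                ))
    return pd.DataFrame(rows)


def brute_force_anova(cube: np.ndarray) -> dict[str, float]:
    """Definitional sums of squares via explicit loops (independent oracle)."""
    g, c, r = cube.shape
    grand = cube.mean()
    ss_g = ss_c = ss_gc = ss_e = 0.0
    for i in range(g):
        ss_g += c * r * (cube[i].mean() - grand) ** 2
    for j in range(c):
        ss_c += g * r * (cube[:, j].mean() - grand) ** 2
    for i in range(g):
        for j in range(c):
            cell = cube[i, j].mean()
            ss_gc += r * (cell - cube[i].mean() - cube[:, j].mean() + grand) ** 2
            for k in range(r):
                ss_e += (cube[i, j, k] - cell) ** 2
    return {"genotype": ss_g, "condition": ss_c, "genotype:condition": ss_gc, "residual": ss_e}


class TestTwoWayAnova:
    def test_constant_data_gives_zero_ss_and_missing_f(self):
        cube = np.full((3, 2, 2), 7.0)
        an = two_way_anova(long_table(cube), "y")
        assert np.allclose(an.table["sum_sq"], 0.0)
        assert an.table["F"].isna().all()

    def test_2x2x2_toy_matches_brute_force(self):
        cube = np.array([[[3.0, 5.0], [7.0, 9.0]], [[2.0, 4.0], [10.0, 14.0]]])
        an = two_way_anova(long_table(cube), "y")
        oracle = brute_force_anova(cube)
        for term, ss in oracle.items():
            assert an.table.loc[term, "sum_sq"] == pytest.approx(ss, abs=1e-10)

    def test_random_layouts_match_brute_force_and_statsmodels(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        for _ in range(5):
            g, c, r = int(rng.integers(2, 6)), 2, int(rng.integers(2, 4))
            cube = rng.normal(size=(g, c, r))
            table = long_table(cube)
            an = two_way_anova(table, "y")
            oracle = brute_force_anova(cube)
            for term, ss in oracle.items():
                assert an.table.loc[term, "sum_sq"] == pytest.approx(ss, abs=1e-10)
            fit = ols("value ~ C(accession) * C(condition)", data=table).fit()
            sm_tab = sm.stats.anova_lm(fit, typ=2)
            assert an.table.loc["genotype", "sum_sq"] == pytest.approx(
                sm_tab.loc["C(accession)", "sum_sq"]
            )
            assert an.table.loc["genotype:condition", "F"] == pytest.approx(
                sm_tab.loc["C(accession):C(condition)", "F"]
            )
            assert an.table.loc["condition", "p"] == pytest.approx(
                sm_tab.loc["C(condition)", "PR(>F)"]
            )

    def test_ss_additivity_on_arbitrary_input(self, rng):
        cube = rng.normal(size=(8, 2, 3)) * 10 + 5
        table = long_table(cube)
        an = two_way_anova(table, "y")
        total = ((cube - cube.mean()) ** 2).sum()
        assert an.total_ss == pytest.approx(total, rel=1e-12)

    def test_unbalanced_input_directed_to_error(self):
        cube = np.random.default_rng(0).normal(size=(3, 2, 3))
        table = long_table(cube).drop(index=[0])
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_anova(table, "y")

    def test_strong_genotype_effect_detected_reliably(self):
        """Large sigma2_G: genotype p < 0.001 in >= 95% of 100 seeded runs."""
        hits = 0
        for seed in range(100):
            t = simulate_trait_table(SimulationParams(
                n_accessions=15, n_reps=3, sigma2_G=4.0, sigma2_GC=0.5,
                sigma2_E=1.0, seed=seed,
            ))
            p = two_way_anova(t, "y").table.loc["genotype", "p"]
            hits += p < 1e-3
        assert hits >= 95


class TestVarianceComponents:
    def test_equal_mean_squares_leave_only_residual(self):
        frame = pd.DataFrame({
            "df": [5, 1, 5, 24],
            "sum_sq": [10.0, 2.0, 10.0, 48.0],
            "mean_sq": [2.0, 2.0, 2.0, 2.0],
            "F": [np.nan] * 4, "p": [np.nan] * 4,
        }, index=["genotype", "condition", "genotype:condition", "residual"])
        vc = estimate_variance_components(AnovaTable(table=frame, g=6, c=2, r=3))
        assert vc.sigma2_e == pytest.approx(2.0)
        assert vc.sigma2_g == vc.sigma2_c == vc.sigma2_gc == 0.0

    def test_truncation_flags_negative_solution(self):
        frame = pd.DataFrame({
            "df": [5, 1, 5, 24],
            "sum_sq": [30.0, 2.0, 5.0, 48.0],
            "mean_sq": [6.0, 2.0, 1.0, 2.0],  # MS_GC < MS_E -> negative s2_GC
            "F": [np.nan] * 4, "p": [np.nan] * 4,
        }, index=["genotype", "condition", "genotype:condition", "residual"])
        vc = estimate_variance_components(AnovaTable(table=frame, g=6, c=2, r=3))
        assert vc.sigma2_gc == 0.0
        assert "genotype:condition" in vc.truncated

    def test_parameter_recovery_over_repeated_simulation(self):
        """(2, 1, 1) generator at g=60, c=2, r=3: mean estimates within 3 MC SE."""
        ests = []
        for seed in range(200):
            t = simulate_trait_table(SimulationParams(
                n_accessions=60, n_reps=3, sigma2_G=2.0, sigma2_GC=1.0,
                sigma2_E=1.0, seed=seed,
            ))
            vc = estimate_variance_components(two_way_anova(t, "y"))
            ests.append([vc.sigma2_g, vc.sigma2_gc, vc.sigma2_e, heritability(vc)])
        e = np.asarray(ests)
        means, ses = e.mean(axis=0), e.std(axis=0, ddof=1) / np.sqrt(len(e))
        for mean, se, truth in zip(means, ses, [2.0, 1.0, 1.0, 0.5]):
            assert abs(mean - truth) <= 3 * se

    def test_ems_inversion_on_known_mean_squares(self):
        # MS built from s2 = (G, C, GC, E) = (2, 0.5, 1, 1), g=10, c=2, r=3
        g, c, r = 10, 2, 3
        ms_e = 1.0
        ms_gc = 1.0 + r * 1.0
        ms_g = ms_gc + r * c * 2.0
        ms_c = 1.0 + r * 1.0 + r * g * 0.5
        frame = pd.DataFrame({
            "df": [g - 1, c - 1, (g - 1) * (c - 1), g * c * (r - 1)],
            "sum_sq": [0.0] * 4,
            "mean_sq": [ms_g, ms_c, ms_gc, ms_e],
            "F": [np.nan] * 4, "p": [np.nan] * 4,
        }, index=["genotype", "condition", "genotype:condition", "residual"])
        vc = estimate_variance_components(AnovaTable(table=frame, g=g, c=c, r=r))
        assert vc.sigma2_g == pytest.approx(2.0)
        assert vc.sigma2_c == pytest.approx(0.5)
        assert vc.sigma2_gc == pytest.approx(1.0)
        assert vc.sigma2_e == pytest.approx(1.0)


class TestHeritability:
    def _vc(self, g, c_, gc, e):
        return VarianceDecomposition(
            sigma2_g=g, sigma2_c=c_, sigma2_gc=gc, sigma2_e=e, g=60, c=2, r=3
        )

    def test_pure_genotype_variance_gives_one(self):
        assert heritability(self._vc(1, 0, 0, 0)) == 1.0

    def test_zero_genotype_variance_gives_zero(self):
        assert heritability(self._vc(0, 0, 1, 1)) == 0.0

    def test_plot_basis_formula(self):
        assert heritability(self._vc(2, 5, 1, 1)) == pytest.approx(0.5)

    def test_entry_mean_basis_formula(self):
        h2 = heritability(self._vc(2, 0, 1, 1), basis="entry-mean")
        assert h2 == pytest.approx(2 / (2 + 0.5 + 1 / 6))

    def test_monotone_in_genotype_variance(self):
        vals = [heritability(self._vc(s, 0, 1, 1)) for s in (0.5, 1, 2, 4)]
        assert vals == sorted(vals)
        assert all(0 <= v <= 1 for v in vals)

    def test_zero_total_variance_is_missing(self):
        with pytest.warns(UserWarning, match="zero total"):
            assert np.isnan(heritability(self._vc(0, 0, 0, 0)))


class TestRelativeContributions:
    def test_single_component_is_100(self):
        vc = VarianceDecomposition(sigma2_g=3, sigma2_c=0, sigma2_gc=0, sigma2_e=0)
        assert relative_contributions(vc)["genotype"] == pytest.approx(100.0)

    def test_equal_components_are_25_each(self):
        vc = VarianceDecomposition(sigma2_g=1, sigma2_c=1, sigma2_gc=1, sigma2_e=1)
        out = relative_contributions(vc)
        assert all(v == pytest.approx(25.0) for v in out.values())
        assert sum(out.values()) == pytest.approx(100.0)

    def test_residual_exclusion_option(self):
        vc = VarianceDecomposition(sigma2_g=1, sigma2_c=1, sigma2_gc=2, sigma2_e=4)
        out = relative_contributions(vc, include_residual=False)
        assert "residual" not in out
        assert sum(out.values()) == pytest.approx(100.0)


class TestCV:
    def test_constant_values_give_zero(self):
        t = long_table(np.full((4, 2, 3), 5.0))
        cv = coefficient_of_variation(t, "y")
        assert np.allclose(cv.values, 0.0)

    def test_closed_form_two_values(self):
        t = pd.DataFrame([
            dict(accession="A", species_group="g", condition="control",
                 replicate=1, trait="y", value=1.0),
            dict(accession="A", species_group="g", condition="control",
                 replicate=2, trait="y", value=3.0),
        ])
        cv = coefficient_of_variation(t, "y")
        assert cv["control"] == pytest.approx(np.sqrt(2) / 2 * 100)

    def test_lognormal_cv_matches_analytic(self, rng):
        # lognormal(mu, s): CV = sqrt(exp(s^2) - 1)
        s = 0.3
        vals = rng.lognormal(0.0, s, size=20000)
        t = pd.DataFrame(dict(
            accession="A", species_group="g", condition="control",
            replicate=np.arange(len(vals)), trait="y", value=vals,
        ))
        cv = coefficient_of_variation(t, "y")
        assert cv["control"] == pytest.approx(np.sqrt(np.exp(s**2) - 1) * 100, rel=0.05)


class TestCorrelations:
    def _bivariate_table(self, rng, rho=0.7, n=500):
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        rows = []
        for i, (x, y) in enumerate(xy):
            for trait, v in (("t1", x), ("t2", y)):
                rows.append(dict(accession=f"A{i}", species_group="g",
                                 condition="control", replicate=1, trait=trait, value=v))
        return pd.DataFrame(rows)

    def test_self_copy_and_negation(self, rng):
        t = self._bivariate_table(rng, rho=0.5, n=50)
        wide = to_wide(t, "control")
        extra = t[t.trait == "t1"].copy()
        extra["trait"] = "t1_neg"
        extra["value"] *= -1
        corr = correlation_matrix(pd.concat([t, extra]), "control")
        assert corr.loc["t1", "t1"] == pytest.approx(1.0)
        assert corr.loc["t1", "t1_neg"] == pytest.approx(-1.0)

    def test_sampling_distribution_around_rho(self):
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            corr = correlation_matrix(self._bivariate_table(rng), "control")
            rs.append(corr.loc["t1", "t2"])
        rs = np.asarray(rs)
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean() - 0.7) <= 3 * se + 0.01  # small-n bias allowance

    def test_matrix_symmetric_unit_diagonal_psd(self):
        t = simulate_study(seed=9, n_accessions=30, n_reps=2)
        corr = correlation_matrix(t, "drought")
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        eigvals = np.linalg.eigvalsh(corr.to_numpy())
        assert eigvals.min() >= -1e-8

    def test_constant_trait_excluded_with_warning(self):
        t = simulate_study(seed=1, n_accessions=10, n_reps=2, traits=["FW"])
        const = t.copy()
        const["trait"] = "flat"
        const["value"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            corr = correlation_matrix(pd.concat([t, const]), "control")
        assert "flat" not in corr.columns

    def test_network_thresholds_and_categories(self):
        t = simulate_study(seed=5, n_accessions=25, n_reps=2)
        G = correlation_network(t, "control", draw_threshold=0.3, strong_threshold=0.6)
        assert G.nodes["FW"]["category"] == "biomass"
        assert G.nodes["CH"]["category"] == "architectural"
        assert G.nodes["PhE"]["category"] == "physiological"
        for _, _, d in G.edges(data=True):
            assert abs(d["r"]) >= 0.3
            assert d["strength"] == ("strong" if abs(d["r"]) >= 0.6 else "weak")
            assert d["sign"] == ("positive" if d["r"] > 0 else "negative")
        assert not any(a == b for a, b in G.edges())


def power_iteration_eig(mat: np.ndarray, k: int, iters=5000, tol=1e-12):
    """Top-k eigenpairs by power iteration with deflation (independent oracle)."""
    mat = mat.copy()
    vals, vecs = [], []
    rng = np.random.default_rng(0)
    for _ in range(k):
        v = rng.normal(size=mat.shape[0])
        v /= np.linalg.norm(v)
        for _ in range(iters):
            w = mat @ v
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
                v = w
                break
            v = w
        lam = float(v @ mat @ v)
        vals.append(lam)
        vecs.append(v)
        mat = mat - lam * np.outer(v, v)
    return np.array(vals), np.array(vecs).T


class TestPCA:
    def test_two_perfectly_correlated_traits_pc1_explains_all(self, rng):
        x = rng.normal(size=40)
        rows = []
        for i, v in enumerate(x):
            rows.append(dict(accession=f"A{i}", species_group="g", condition="control",
                             replicate=1, trait="t1", value=v))
            rows.append(dict(accession=f"A{i}", species_group="g", condition="control",
                             replicate=1, trait="t2", value=2 * v + 1))
        res = pca_biplot(pd.DataFrame(rows))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_independent_traits_share_variance_evenly(self, rng):
        p, n = 5, 4000
        rows = []
        for i in range(n):
            for j in range(p):
                rows.append(dict(accession=f"A{i}", species_group="g",
                                 condition="control", replicate=1,
                                 trait=f"t{j}", value=rng.normal()))
        res = pca_biplot(pd.DataFrame(rows))
        assert np.allclose(res.explained_variance_ratio, 1 / p, atol=0.03)

    def test_matches_power_iteration_oracle(self, rng):
        t = simulate_study(seed=11, n_accessions=20, n_reps=2)
        res = pca_biplot(t)
        wide = to_wide(t).dropna()
        Z = (wide - wide.mean()) / wide.std(ddof=1)
        corr = (Z.T @ Z).to_numpy() / (len(Z) - 1)
        vals, vecs = power_iteration_eig(corr, k=3)
        total = np.trace(corr)
        for j in range(3):
            assert res.explained_variance_ratio[j] == pytest.approx(vals[j] / total, abs=1e-6)
            dot = abs(res.loadings.iloc[:, j] @ vecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_invariants_orthonormal_and_ordered(self):
        t = simulate_study(seed=3, n_accessions=15, n_reps=2)
        res = pca_biplot(t)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() == pytest.approx(1.0)
        # sign convention: largest-|loading| entry positive
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_zero_variance_column_dropped_with_warning(self):
        t = simulate_study(seed=2, n_accessions=10, n_reps=2, traits=["FW", "DW"])
        const = t[t.trait == "FW"].copy()
        const["trait"] = "flat"
        const["value"] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_biplot(pd.concat([t, const]))
        assert "flat" in res.dropped
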