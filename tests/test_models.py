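"""OLS engine, VIF screening, ANCOVA and variance partitioning."""

import numpy as np
import pandas as pd
import pytest

import phylostruct as ps
from phylostruct.models import RankDeficiencyError
from phylostruct.spatial import SiteTable


def toy_sites(n=24, seed=0):
    rng = np.random.default_rng(seed)
    classes = np.array(["sedimentary", "crystalline", "inselberg"])[
        np.arange(n) % 3]
    return SiteTable(pd.DataFrame({
        "lat": rng.uniform(-10, -4, n),
        "lon": rng.uniform(-42, -35, n),
        "substrate": classes,
        "temp": rng.normal(25, 1.5, n),
        "precip": rng.normal(700, 150, n),
        "driest": rng.normal(30, 15, n),
    }, index=[f"t{i}" for i in range(n)]))


class TestOLS:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = ps.ols_fit(2 * x + 1, pd.DataFrame({"x": x}))
        assert fit.params["Intercept"] == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        fit = ps.ols_fit(y, X)
        M = np.column_stack([np.ones(40), X.to_numpy()])
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-8)
        assert fit.adj_r2 <= fit.r2

    def test_null_model_calibration(self):
        """y independent of X: R2 near 0 and coefficient p uniform."""
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(300):
            X = pd.DataFrame({"x": rng.normal(size=200)})
            fit = ps.ols_fit(rng.normal(size=200), X)
            pvals.append(fit.pvalues["x"])
        pvals = np.array(pvals)
        assert (pvals < 0.05).mean() == pytest.approx(0.05, abs=0.035)
        assert np.median(pvals) == pytest.approx(0.5, abs=0.1)

    def test_duplicated_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        with pytest.raises(RankDeficiencyError):
            ps.ols_fit([1.0, 2, 3, 4], X)


class TestVIF:
    def test_orthogonal_predictors_kept(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        kept, log = ps.vif_screen(X)
        assert kept == ["a", "b"]
        assert np.allclose(log["vif"], 1.0)

    def test_exact_collinearity_dropped_first(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x1": rng.normal(size=30),
                          "x2": rng.normal(size=30)})
        X["x3"] = X["x1"] + X["x2"]
        kept, log = ps.vif_screen(X, threshold=10)
        assert "x3" not in kept or "x1" not in kept  # one of the triple goes
        first_drop = log[log["dropped"]].iloc[0]
        assert np.isinf(first_drop["vif"])

    def test_correlated_climate_block_screened(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=60)
        X = pd.DataFrame({
            f"clim{i}": base + rng.normal(scale=0.3, size=60)
            for i in range(5)})
        kept, _ = ps.vif_screen(X, threshold=10)
        assert len(kept) < 5  # pairwise r ~ 0.9 forces at least one drop
        if len(kept) >= 2:  # survivors actually satisfy the threshold
            _, log2 = ps.vif_screen(X[kept], threshold=10)
            assert (log2.groupby("predictor")["vif"].last() <= 10).all()


class TestAncova:
    def test_pure_class_shifts_recovered_exactly(self):
        sites = toy_sites()
        shifts = {"sedimentary": 0.0, "crystalline": 2.0, "inselberg": -3.0}
        y = sites.table["substrate"].map(shifts).to_numpy()
        fit = ps.ancova(y, sites, climate_terms=["temp"], alpha=0.10)
        assert fit.params["Crystalline"] == pytest.approx(2.0, abs=1e-9)
        assert fit.params["Inselberg"] == pytest.approx(-3.0, abs=1e-9)
        assert fit.params["temp"] == pytest.approx(0.0, abs=1e-9)

    def test_climate_effect_coverage(self):
        """True slope inside +/-2 SE in at least 95% of simulations."""
        beta = 0.04
        hits = 0
        n_sim = 300
        for s in range(n_sim):
            sites = toy_sites(seed=s)
            rng = np.random.default_rng(10_000 + s)
            y = beta * sites.table["driest"].to_numpy() + rng.normal(
                scale=0.5, size=len(sites))
            fit = ps.ancova(y, sites, climate_terms=["temp", "driest"])
            hit = abs(fit.params["driest"] - beta) <= 2 * fit.bse["driest"]
            hits += hit
        assert hits / n_sim >= 0.93

    def test_false_flag_rate_near_alpha(self):
        """Permuted responses flag each term at about the alpha level."""
        sites = toy_sites(seed=9)
        base = np.linspace(-1, 1, len(sites))
        rng = np.random.default_rng(11)
        flags = []
        for _ in range(500):
            y = rng.permutation(base)
            fit = ps.ancova(y, sites, climate_terms=["temp", "driest"],
                            alpha=0.10)
            flags.append(fit.significant.drop("Intercept").to_numpy())
        rate = np.mean(flags)
        assert 0.07 <= rate <= 0.13

    def test_single_class_rejected(self):
        sites = toy_sites()
        tab = sites.table.copy()
        tab["substrate"] = "sedimentary"
        with pytest.raises(ValueError):
            ps.ancova(np.arange(len(tab), dtype=float), SiteTable(tab),
                      climate_terms=["temp"])


class TestVariancePartition:
    def test_orthogonal_blocks_have_no_overlap(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=n)
        w = rng.normal(size=n)
        y = x + w + rng.normal(scale=0.3, size=n)
        vp = ps.variance_partition(y, pd.DataFrame({"x": x}),
                                   pd.DataFrame({"w": w}), r2_flavour="raw")
        assert abs(vp.shared) < 0.05
        assert vp.climate > 0.3 and vp.edaphic > 0.3

    def test_identical_blocks_share_everything(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        y = x + rng.normal(scale=0.5, size=100)
        vp = ps.variance_partition(y, pd.DataFrame({"x": x}),
                                   pd.DataFrame({"w": x * 2.0}),
                                   r2_flavour="raw")
        assert abs(vp.climate) < 1e-9
        assert abs(vp.edaphic) < 1e-9
        assert vp.shared == pytest.approx(vp.r2_full)

    def test_fractions_match_three_independent_fits(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 100
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        W = pd.DataFrame(rng.normal(size=(n, 2)), columns=list("de"))
        y = rng.normal(size=n)
        vp = ps.variance_partition(y, X, W, r2_flavour="adjusted")

        def adj(cols):
            M = sm.add_constant(np.column_stack(cols))
            return sm.OLS(y, M).fit().rsquared_adj

        abc = adj([X.to_numpy(), W.to_numpy()])
        ab = adj([X.to_numpy()])
        bc = adj([W.to_numpy()])
        b = ab + bc - abc
        assert vp.shared == pytest.approx(b, abs=1e-10)
        assert vp.climate == pytest.approx(ab - b, abs=1e-10)
        assert vp.edaphic == pytest.approx(bc - b, abs=1e-10)
        assert vp.unexplained == pytest.approx(1 - abc, abs=1e-10)

    def test_invariant_to_reparameterization(self):
        rng = np.random.default_rng(8)
        n = 80
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["x1", "x2"])
        W = pd.DataFrame(rng.normal(size=(n, 2)), columns=["w1", "w2"])
        y = X["x1"] + W["w1"] + rng.normal(size=n)
        A = np.array([[2.0, 1.0], [0.0, -1.0]])  # invertible
        X2 = pd.DataFrame(X.to_numpy() @ A, columns=["u1", "u2"])
        v1 = ps.variance_partition(y, X, W, r2_flavour="raw")
        v2 = ps.variance_partition(y, X2, W, r2_flavour="raw")
        assert v1.shared == pytest.approx(v2.shared, abs=1e-10)
        assert v1.climate == pytest.approx(v2.climate, abs=1e-10)


def test_ancova_without_climate_matches_oneway_f():
    """With no climate terms and no filter the ANCOVA reduces to one-way
    analysis of variance across the three substrates."""
    import scipy.stats

    sites = toy_sites(seed=12)
    rng = np.random.default_rng(12)
    shifts = {"sedimentary": 0.0, "crystalline": 1.0, "inselberg": -1.0}
    y = sites.table["substrate"].map(shifts).to_numpy() + rng.normal(
        scale=1.0, size=len(sites))
    fit = ps.ancova(y, sites, climate_terms=[])
    groups = [y[sites.table["substrate"] == c]
              for c in ("sedimentary", "crystalline", "inselberg")]
    f_ref, _ = scipy.stats.f_oneway(*groups)
    # F for the model = (R2/dfm) / ((1-R2)/dfr)
    dfm, dfr = fit.df_model, fit.n - fit.df_model - 1
    f_model = (fit.r2 / dfm) / ((1 - fit.r2) / dfr)
    assert f_model == pytest.approx(f_ref, rel=1e-10)
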