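import numpy as np
import pandas as pd
import pytest

from phenocurate import (
    MixedModelREML,
    ModelSpec,
    VarianceComponents,
    fit_reml,
    predict_blues,
    restricted_loglik,
)
from phenocurate.reml import IdentifiabilityError

from conftest import balanced_frame, make_dataset


# ---------------------------------------------------------------------------
# independent dense oracles

def dense_reml_loglik(df, spec, comp):
    """Restricted log-likelihood via dense V, independent of the MME path."""
    acc, acc_idx = pd.factorize(df["accession_id"], sort=True)
    years = np.sort(df["year"].unique())
    tmap = {y: k for k, y in enumerate(years)}
    t = df["year"].map(tmap).to_numpy()
    y = df["value"].to_numpy(float)
    n, I, J = len(y), len(acc_idx), len(years)
    Zg = np.zeros((n, I)); Zg[np.arange(n), acc] = 1
    Za = np.zeros((n, J)); Za[np.arange(n), t] = 1
    R = np.diag([comp.sigma2_e_by_year[int(years[j])] for j in t])
    V = R.copy()
    if spec.genotype_role == "random":
        V += comp.sigma2_G * Zg @ Zg.T
    if spec.year_role == "random":
        V += comp.sigma2_A * Za @ Za.T
    if spec.genotype_role == "fixed":
        X = Zg
    elif spec.year_role == "fixed":
        X = Za
    else:
        X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    beta = np.linalg.solve(XVX, X.T @ Vi @ y)
    r = y - X @ beta
    p = X.shape[1]
    return -0.5 * ((n - p) * np.log(2 * np.pi) + np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(XVX)[1] + r @ Vi @ r)


def dense_gls_blues(df, sigma2_A, sigma2_e_by_year):
    """GLS fixed-accession solution with dense V: the BLUE oracle."""
    acc, acc_idx = pd.factorize(df["accession_id"], sort=True)
    years = np.sort(df["year"].unique())
    t = df["year"].map({y: k for k, y in enumerate(years)}).to_numpy()
    y = df["value"].to_numpy(float)
    n, I, J = len(y), len(acc_idx), len(years)
    X = np.zeros((n, I)); X[np.arange(n), acc] = 1
    Za = np.zeros((n, J)); Za[np.arange(n), t] = 1
    V = sigma2_A * Za @ Za.T + np.diag(
        [sigma2_e_by_year[int(years[j])] for j in t])
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return pd.Series(beta, index=pd.Index(acc_idx))


def anova_estimates(y2d):
    """Closed-form method-of-moments estimators on a balanced grid."""
    I, J = y2d.shape
    yi, yj, yy = y2d.mean(1), y2d.mean(0), y2d.mean()
    MSG = J * np.sum((yi - yy) ** 2) / (I - 1)
    MSA = I * np.sum((yj - yy) ** 2) / (J - 1)
    MSE = np.sum((y2d - yi[:, None] - yj[None, :] + yy) ** 2) / ((I - 1) * (J - 1))
    return (MSG - MSE) / J, (MSA - MSE) / I, MSE


# ---------------------------------------------------------------------------

class TestBalancedClosedForm:
    def test_matches_anova_method_of_moments(self):
        df, _, _ = balanced_frame(20, 6, seed=0)
        y2d = df["value"].to_numpy().reshape(20, 6)
        s2g, s2a, s2e = anova_estimates(y2d)
        m = MixedModelREML(heterogeneous_errors=False).fit(df)
        assert m.converged_
        assert m.sigma2_g_ == pytest.approx(s2g, rel=1e-6)
        assert m.sigma2_a_ == pytest.approx(s2a, rel=1e-6)
        assert list(m.sigma2_e_by_year_.values())[0] == pytest.approx(s2e, rel=1e-6)

    def test_standardized_residuals_have_unit_scale(self):
        df, _, _ = balanced_frame(200, 10, se=1.7, seed=2)
        m = MixedModelREML().fit(df)
        sd = pd.Series(m.standardized_residuals_).groupby(
            df["year"].to_numpy()).std()
        assert np.allclose(sd, 1.0, atol=0.1)


class TestDenseOracles:
    @pytest.mark.parametrize("roles", [("random", "random"),
                                       ("fixed", "random"),
                                       ("random", "fixed")])
    def test_loglik_matches_dense_formula(self, roles):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(9):
            for j in rng.choice(5, size=rng.integers(2, 5), replace=False):
                rows.append((f"A{i}", 2000 + int(j), float(rng.normal(100, 4))))
        df = make_dataset(rows).df
        spec = ModelSpec(genotype_role=roles[0], year_role=roles[1])
        years = np.sort(df["year"].unique())
        comp = VarianceComponents(
            mu=None,
            sigma2_G=3.0 if roles[0] == "random" else None,
            sigma2_A=1.5 if roles[1] == "random" else None,
            sigma2_e_by_year={int(y): 0.8 + 0.1 * k for k, y in enumerate(years)},
        )
        m = MixedModelREML(genotype_role=roles[0], year_role=roles[1],
                           min_year_df=0)
        got = m.restricted_loglik(df, comp)
        want = dense_reml_loglik(df, spec, comp)
        assert got == pytest.approx(want, rel=1e-10)

    def test_two_observation_toy_closed_form(self):
        # one record per accession/year: V is diagonal and the restricted
        # likelihood collapses to a single Gaussian contrast
        df = make_dataset([("A", 2001, 12.0), ("B", 2002, 18.0)]).df
        comp = VarianceComponents(
            mu=None, sigma2_G=2.0, sigma2_A=1.0,
            sigma2_e_by_year={2001: 0.5, 2002: 1.5})
        v1, v2 = 2.0 + 1.0 + 0.5, 2.0 + 1.0 + 1.5
        # GLS mean and its information under V = diag(v1, v2)
        w1, w2 = 1 / v1, 1 / v2
        mu = (w1 * 12 + w2 * 18) / (w1 + w2)
        by_hand = -0.5 * (np.log(2 * np.pi) + np.log(v1) + np.log(v2)
                          + np.log(w1 + w2)
                          + w1 * (12 - mu) ** 2 + w2 * (18 - mu) ** 2)
        m = MixedModelREML(min_year_df=0)
        got = m.restricted_loglik(df, comp)
        assert got == pytest.approx(by_hand, rel=1e-12)

    def test_blues_match_dense_gls(self):
        df = make_dataset([("A", 2001, 80.0), ("A", 2002, 95.0),
                           ("B", 2001, 85.0), ("B", 2002, 99.0),
                           ("C", 2001, 70.0), ("C", 2002, 88.0)]).df
        fit = MixedModelREML(genotype_role="fixed", min_year_df=0).fit(df)
        oracle = dense_gls_blues(df, fit.sigma2_a_, fit.sigma2_e_by_year_)
        assert np.allclose(fit.genotype_effects_.to_numpy(),
                           oracle.to_numpy(), rtol=1e-8)

    def test_fit_is_local_maximum_of_restricted_loglik(self):
        df, _, _ = balanced_frame(15, 5, seed=3)
        ds = df
        m = MixedModelREML(min_year_df=0).fit(ds)
        base = m.loglik_
        comp = m.components_
        probe = MixedModelREML(min_year_df=0)
        for bump in ("G", "A", "e"):
            c = VarianceComponents(
                mu=comp.mu,
                sigma2_G=comp.sigma2_G * (1.1 if bump == "G" else 1.0),
                sigma2_A=comp.sigma2_A * (1.1 if bump == "A" else 1.0),
                sigma2_e_by_year={
                    y: v * (1.1 if bump == "e" else 1.0)
                    for y, v in comp.sigma2_e_by_year.items()},
            )
            assert probe.restricted_loglik(ds, c) <= base + 1e-9

    def test_restricted_loglik_deterministic(self):
        df, _, _ = balanced_frame(10, 4, seed=6)
        m = MixedModelREML(min_year_df=0).fit(df)
        probe = MixedModelREML(min_year_df=0)
        a = probe.restricted_loglik(df, m.components_)
        b = probe.restricted_loglik(df, m.components_)
        assert a == b

    def test_year_set_mismatch_rejected(self):
        df, _, _ = balanced_frame(5, 3, seed=1)
        comp = VarianceComponents(mu=None, sigma2_G=1, sigma2_A=1,
                                  sigma2_e_by_year={1999: 1.0})
        with pytest.raises(ValueError, match="year set"):
            MixedModelREML().restricted_loglik(df, comp)


class TestEquivariance:
    def test_translation_shifts_blues_exactly(self):
        df, _, _ = balanced_frame(12, 4, seed=9)
        df = df.sample(frac=0.8, random_state=0).reset_index(drop=True)
        b1 = MixedModelREML(genotype_role="fixed").fit(df).blues()
        df2 = df.copy(); df2["value"] += 13.5
        b2 = MixedModelREML(genotype_role="fixed").fit(df2).blues()
        assert np.allclose(b2["blue"], b1["blue"] + 13.5, atol=1e-8)

    def test_scaling_multiplies_variances_by_square(self):
        df, _, _ = balanced_frame(25, 5, seed=11)
        m1 = MixedModelREML().fit(df)
        df2 = df.copy(); df2["value"] *= 3.0
        m2 = MixedModelREML().fit(df2)
        assert m2.sigma2_g_ == pytest.approx(9 * m1.sigma2_g_, rel=1e-5)
        assert m2.sigma2_a_ == pytest.approx(9 * m1.sigma2_a_, rel=1e-5)
        for y in m1.sigma2_e_by_year_:
            assert m2.sigma2_e_by_year_[y] == pytest.approx(
                9 * m1.sigma2_e_by_year_[y], rel=1e-5)


class TestDegenerateAndErrors:
    def test_noise_free_data_gives_zero_residuals(self):
        df = make_dataset([("A", 2001, 100.0), ("A", 2002, 100.0),
                           ("B", 2001, 100.0), ("B", 2002, 100.0)]).df
        m = MixedModelREML().fit(df)
        assert np.all(m.residuals_ == 0)
        assert m.sigma2_g_ == 0 and m.converged_
        assert "sigma2_e" in " ".join(m.boundary_)

    def test_noise_free_fixed_fit_recovers_means(self):
        # without noise the BLUEs reproduce the generating accession means
        base = {"A": 90.0, "B": 100.0, "C": 110.0}
        year_eff = {2001: -2.0, 2002: 2.0}
        rows = [(a, y, base[a] + year_eff[y]) for a in base for y in year_eff]
        df = make_dataset(rows).df
        m = MixedModelREML(genotype_role="fixed").fit(df)
        diffs = m.genotype_effects_.to_numpy() - np.array([90, 100, 110.0])
        assert np.allclose(diffs - diffs[0], 0, atol=1e-8)

    def test_single_year_is_unidentifiable(self):
        df = make_dataset([("A", 2001, 1.0), ("B", 2001, 2.0)]).df
        with pytest.raises(IdentifiabilityError):
            MixedModelREML().fit(df)

    def test_confounded_year_named_in_error(self):
        # accession C appears only in 2003, which holds no other accessions
        df = make_dataset([("A", 2001, 1.0), ("A", 2002, 2.0),
                           ("B", 2001, 3.0), ("B", 2002, 4.0),
                           ("C", 2003, 9.0)]).df
        with pytest.raises(IdentifiabilityError, match="2003"):
            MixedModelREML(genotype_role="fixed").fit(df)

    def test_blues_require_fixed_genotype(self):
        df, _, _ = balanced_frame(5, 3, seed=0)
        m = MixedModelREML().fit(df)
        with pytest.raises(ValueError):
            m.blues()

    def test_both_fixed_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(genotype_role="fixed", year_role="fixed")


class TestRecovery:
    def test_variance_components_recovered_on_sparse_design(self):
        # sparse incidence, heterogeneous errors: mean estimate near truth
        rng = np.random.default_rng(2024)
        est_g, est_a = [], []
        for rep in range(8):
            rows = []
            I, J = 1200, 10
            g = rng.normal(0, 2.0, I)
            a = rng.normal(0, np.sqrt(2.0), J)
            se = rng.uniform(0.8, 1.5, J)
            for i in range(I):
                for j in rng.choice(J, size=rng.integers(2, 5), replace=False):
                    rows.append((f"A{i:04d}", 2000 + int(j),
                                 float(100 + g[i] + a[j] + rng.normal(0, se[j]))))
            m = MixedModelREML().fit(make_dataset(rows).df)
            est_g.append(m.sigma2_g_)
            est_a.append(m.sigma2_a_)
        assert np.mean(est_g) == pytest.approx(4.0, rel=0.1)
        assert np.mean(est_a) == pytest.approx(2.0, rel=0.35)

    def test_zero_genetic_variance_estimated_near_zero(self):
        rng = np.random.default_rng(77)
        rows = []
        for i in range(800):
            for j in rng.choice(8, size=2, replace=False):
                rows.append((f"A{i:04d}", 2000 + int(j),
                             float(50 + rng.normal(0, 1.0))))
        m = MixedModelREML().fit(make_dataset(rows).df)
        assert m.sigma2_g_ < 0.05

    def test_functional_wrappers(self):
        df, _, _ = balanced_frame(6, 3, seed=0)
        fit = fit_reml(df, ModelSpec(genotype_role="fixed"))
        tab = predict_blues(fit)
        assert list(tab.columns) == ["blue", "se"]
        assert len(tab) == 6
        ll = restricted_loglik(df, ModelSpec(genotype_role="fixed"),
                               fit.components_)
        assert ll == pytest.approx(fit.loglik_, rel=1e-9)
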