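"""REML engine for the two-way additive mixed model with year-specific errors.

The model is ``y_ij = mu + g_i + a_j + e_ij`` for accession *i* observed in
campaign year *j*, with ``e_ij ~ N(0, sigma2_e[j])``. Depending on the
analysis stage the accession term is random (variance components,
heritability) or fixed (outlier detection, BLUEs); the campaign term is
random except in the campaign-quality fit, where it is fixed.

Estimation maximises the restricted log-likelihood over log-parameterised
variance components. The mixed-model (Henderson) coefficient matrix for this
design has a diagonal accession block, which is absorbed analytically, so one
likelihood-and-gradient evaluation costs O(n_records) plus a dense solve in
the (small) number of years. Gradients are analytic, via the standard
identities ``Z'PZ = G^-1 - G^-1 C^uu G^-1`` and ``Py = R^-1 (y - W b)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .datatypes import PhenotypeDataset

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "MixedModelREML",
    "IdentifiabilityError",
    "fit_reml",
    "predict_blues",
    "restricted_loglik",
]

_LOG2PI = np.log(2.0 * np.pi)


class IdentifiabilityError(ValueError):
    """Raised when the design cannot separate the requested effects."""


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one mixed-model fit.

    ``genotype_role`` switches between the random-genotype fit used for
    variance components and the fixed-genotype fit used for outlier
    detection and BLUEs. ``year_role`` is random throughout the pipeline
    except in the campaign-quality stage, which fixes the campaign means.
    """

    genotype_role: str = "random"
    year_role: str = "random"
    heterogeneous_errors: bool = True
    tol: float = 1e-8
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.genotype_role not in ("fixed", "random"):
            raise ValueError(f"genotype_role must be fixed|random, got {self.genotype_role!r}")
        if self.year_role not in ("fixed", "random"):
            raise ValueError(f"year_role must be fixed|random, got {self.year_role!r}")
        if self.genotype_role == "fixed" and self.year_role == "fixed":
            raise ValueError("at least one of genotype/year must be random")
        if not self.tol > 0:
            raise ValueError("tol must be positive")


@dataclass
class VarianceComponents:
    """Estimated variance components of one fit.

    ``sigma2_G`` is absent (None) when the genotype term was fixed,
    ``sigma2_A`` when the year term was fixed. ``sigma2_e_by_year`` maps each
    fitted campaign year to its residual variance.
    """

    mu: Optional[float]
    sigma2_G: Optional[float]
    sigma2_A: Optional[float]
    sigma2_e_by_year: dict[int, float] = field(default_factory=dict)

    def mean_error_variance(self, how: str = "unweighted") -> float:
        """Collapse the year-specific error variances to a single sigma2_e.

        ``how`` is one of ``unweighted`` (mean over years, the default used
        for heritability), ``median``, or a mapping is not needed for
        ``pooled`` since identical values collapse trivially.
        """
        v = np.array(list(self.sigma2_e_by_year.values()), dtype=float)
        if v.size == 0:
            raise ValueError("no year-specific variances available")
        if how == "unweighted":
            return float(v.mean())
        if how == "median":
            return float(np.median(v))
        raise ValueError(f"unknown summary {how!r}")


def _extract_frame(X) -> pd.DataFrame:
    if isinstance(X, PhenotypeDataset):
        return X.df
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("expected a PhenotypeDataset or a long-format DataFrame")


class MixedModelREML(BaseEstimator):
    """REML fit of the additive accession + year model, scikit-learn style.

    Parameters
    ----------
    genotype_role : {"random", "fixed"}
        Random for variance components / BLUPs, fixed for BLUEs and
        standardized residuals.
    year_role : {"random", "fixed"}
        Fixed only in the campaign-quality fit.
    heterogeneous_errors : bool
        One residual variance per campaign year (years with fewer than
        ``min_year_df`` residual degrees of freedom share a pooled variance
        and are recorded in ``pooled_years_``).
    tol, gtol, max_iter
        Optimiser stopping rules: relative change of the restricted
        log-likelihood, projected-gradient norm, iteration cap.
    variance_floor_factor : float
        Lower bound on every variance, as a fraction of var(y); boundary
        solutions are reported in ``boundary_``, never silently clipped.

    Attributes
    ----------
    mu_ : float or None
        Intercept (only when both terms are random).
    sigma2_g_, sigma2_a_ : float or None
        Accession / year variance components.
    sigma2_e_by_year_ : dict year -> float
    genotype_effects_ : pandas.Series
        BLUPs of g_i (random) or BLUEs on the observation scale (fixed).
    blues_se_ : pandas.Series
        Standard errors of the BLUEs (fixed-genotype fits only).
    year_effects_ : pandas.Series
        BLUPs of a_j, or fixed campaign means in the campaign-quality fit.
    residuals_, standardized_residuals_ : ndarray
        Conditional residuals per record, in input order; standardization
        divides by the fitted sigma_e of the record's year.
    loglik_ : float
        Restricted log-likelihood at the optimum.
    converged_ : bool
    boundary_ : set of component names at the variance floor.
    pooled_years_ : list of years whose error variance was pooled.
    """

    def __init__(
        self,
        genotype_role: str = "random",
        year_role: str = "random",
        heterogeneous_errors: bool = True,
        tol: float = 1e-8,
        gtol: float = 1e-6,
        max_iter: int = 200,
        min_year_df: int = 3,
        variance_floor_factor: float = 1e-8,
    ) -> None:
        self.genotype_role = genotype_role
        self.year_role = year_role
        self.heterogeneous_errors = heterogeneous_errors
        self.tol = tol
        self.gtol = gtol
        self.max_iter = max_iter
        self.min_year_df = min_year_df
        self.variance_floor_factor = variance_floor_factor

    # ------------------------------------------------------------------
    def _spec_check(self) -> None:
        ModelSpec(self.genotype_role, self.year_role, self.heterogeneous_errors,
                  self.tol, self.max_iter)

    def _design(self, df: pd.DataFrame) -> None:
        acc_codes, acc_index = pd.factorize(df["accession_id"], sort=True)
        years = np.sort(df["year"].unique())
        year_pos = {y: k for k, y in enumerate(years)}
        self._a = np.asarray(acc_codes, dtype=np.int64)
        self._t = df["year"].map(year_pos).to_numpy(dtype=np.int64)
        yv = df["value"].to_numpy(dtype=float)
        # centering avoids catastrophic cancellation in y'Py for traits with
        # large means; the REML objective is invariant because the constant
        # vector lies in the fixed-effect column space of every configuration
        self._y_shift = float(yv.mean())
        self._y = yv - self._y_shift
        self._acc_index = pd.Index(acc_index, name="accession_id")
        self._years = years
        self._I = len(acc_index)
        self._J = len(years)
        self._n = len(df)
        if self._I < 2 or self._J < 2:
            raise IdentifiabilityError(
                f"need >= 2 accessions and >= 2 years, got {self._I} x {self._J}"
            )
        if self.genotype_role == "fixed":
            # a year whose records all come from single-year accessions cannot
            # separate its campaign effect from those accessions' fixed effects
            nyears_per_acc = np.bincount(self._a, weights=None, minlength=self._I)
            distinct = pd.DataFrame({"a": self._a, "t": self._t}).drop_duplicates()
            ny = distinct.groupby("a").size().reindex(range(self._I)).to_numpy()
            for j in range(self._J):
                accs_in_j = np.unique(self._a[self._t == j])
                if len(accs_in_j) and np.all(ny[accs_in_j] == 1):
                    raise IdentifiabilityError(
                        f"year {self._years[j]} is fully confounded with "
                        "accessions observed only in that year"
                    )

        # error-variance parameter groups: one per year, small years pooled
        n_per_year = np.bincount(self._t, minlength=self._J)
        if not self.heterogeneous_errors:
            self._year_group = np.zeros(self._J, dtype=np.int64)
            self._n_groups = 1
            self.pooled_years_ = []
        else:
            own = n_per_year - 1 >= self.min_year_df
            groups = np.full(self._J, -1, dtype=np.int64)
            g = 0
            for j in range(self._J):
                if own[j]:
                    groups[j] = g
                    g += 1
            pooled = np.where(~own)[0]
            if len(pooled):
                groups[pooled] = g
                g += 1
            self._year_group = groups
            self._n_groups = g
            self.pooled_years_ = [int(self._years[j]) for j in pooled]

    # ------------------------------------------------------------------
    def _eval(self, sg2: float | None, sa2: float | None, se2: np.ndarray,
              want_grad: bool = True):
        """Restricted log-likelihood, gradient and solution at one point.

        ``se2`` holds one variance per error group. Returns
        ``(nll, grad, aux)`` where grad is d(nll)/d(log variance) in the
        order (sigma2_G?, sigma2_A?, error groups...).
        """
        a, t, y = self._a, self._t, self._y
        I, J, n = self._I, self._J, self._n
        grp = self._year_group
        big_random = self.genotype_role == "random"
        small_random = self.year_role == "random"
        intercept = big_random and small_random

        se2_rec = se2[grp[t]]
        r = 1.0 / se2_rec
        ry = r * y

        A = np.bincount(a, weights=r, minlength=I)
        q = np.bincount(a, weights=ry, minlength=I)
        if big_random:
            A = A + 1.0 / sg2

        njr = np.bincount(t, weights=r, minlength=J)
        u_year = np.bincount(t, weights=ry, minlength=J)
        m = J + (1 if intercept else 0)

        # B: accession x small-block cross-products of W'R^-1 W
        B = sp.csr_matrix((r, (a, t)), shape=(I, J))
        Bd = np.zeros((I, m))
        Bd[:, :J] = B.toarray()
        u_small = np.empty(m)
        u_small[:J] = u_year
        E = np.zeros((m, m))
        E[np.arange(J), np.arange(J)] = njr
        if small_random:
            E[np.arange(J), np.arange(J)] += 1.0 / sa2
        if intercept:
            rowsum = Bd[:, :J].sum(axis=1)
            Bd[:, J] = rowsum
            E[J, J] = njr.sum()
            E[:J, J] = njr
            E[J, :J] = njr
            u_small[J] = u_year.sum()

        F = Bd / A[:, None]
        S = E - Bd.T @ F
        try:
            cf = sla.cho_factor(S, lower=True)
        except sla.LinAlgError:
            bad = np.full(self._n_params, 0.0)
            return 1e30, bad, None
        logdet_S = 2.0 * np.sum(np.log(np.diag(cf[0])))

        rhs = u_small - F.T @ q
        s = sla.cho_solve(cf, rhs)
        g_big = (q - Bd @ s) / A
        yPy = float(ry @ y - (g_big @ q + s @ u_small))

        logdet_C = float(np.sum(np.log(A)) + logdet_S)
        logdet_R = float(np.sum(np.log(se2_rec)))
        logdet_G = 0.0
        if big_random:
            logdet_G += I * np.log(sg2)
        if small_random:
            logdet_G += J * np.log(sa2)
        p = 1 if intercept else (I if not big_random else J)
        ll = -0.5 * ((n - p) * _LOG2PI + logdet_R + logdet_G + logdet_C + yPy)

        fitted = g_big[a] + s[:J][t]
        if intercept:
            fitted = fitted + s[J]
        resid = y - fitted

        aux = {
            "g_big": g_big, "s_small": s, "resid": resid, "A": A,
            "cf": cf, "F": F, "Bd": Bd, "se2_rec": se2_rec, "p": p,
        }
        if not want_grad:
            return -ll, None, aux

        # ----- analytic gradient (d nll / d log sigma2) -----
        Sinv = sla.cho_solve(cf, np.eye(m))
        G1 = F @ Sinv                      # I x m
        rowquad = np.einsum("ij,ij->i", G1, F)     # (A^-1 B S^-1 B' A^-1)_ii
        rr = r * resid
        grad = []
        if big_random:
            tr_Cgg = float(np.sum(1.0 / A) + np.sum(rowquad))
            trP = I / sg2 - tr_Cgg / sg2**2
            quad = float(np.sum(np.bincount(a, weights=rr, minlength=I) ** 2))
            grad.append(0.5 * (trP - quad) * sg2)
        if small_random:
            tr_Caa = float(np.trace(Sinv[:J, :J]))
            trP = J / sa2 - tr_Caa / sa2**2
            quad = float(np.sum(np.bincount(t, weights=rr, minlength=J) ** 2))
            grad.append(0.5 * (trP - quad) * sa2)
        # leverage h_i = w_i' C^-1 w_i per record
        diag_big = 1.0 / A + rowquad
        h = diag_big[a] + Sinv[t, t] - 2.0 * G1[a, t]
        if intercept:
            h = h + Sinv[J, J] + 2.0 * Sinv[t, J] - 2.0 * G1[a, J]
        trP_rec = r - r * r * h
        quad_rec = rr * rr
        for k in range(self._n_groups):
            mask = grp[t] == k
            trP_k = float(trP_rec[mask].sum())
            quad_k = float(quad_rec[mask].sum())
            grad.append(0.5 * (trP_k - quad_k) * se2[k])
        return -ll, np.asarray(grad), aux

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "MixedModelREML":
        """Fit the model to a PhenotypeDataset or long-format DataFrame."""
        self._spec_check()
        df = _extract_frame(X)
        if df["trait"].nunique() > 1 if "trait" in df.columns else False:
            raise ValueError("fit one trait at a time; split the dataset first")
        self._design(df)
        big_random = self.genotype_role == "random"
        small_random = self.year_role == "random"

        var_y = float(np.var(self._y, ddof=1)) if self._n > 1 else 0.0
        if var_y == 0.0:
            return self._fit_degenerate(df)

        floor = self.variance_floor_factor * var_y
        cap = 1e6 * var_y
        self._n_params = int(big_random) + int(small_random) + self._n_groups
        x0, names = [], []
        if big_random:
            x0.append(0.4 * var_y); names.append("sigma2_G")
        if small_random:
            x0.append(0.2 * var_y); names.append("sigma2_A")
        x0 += [0.4 * var_y] * self._n_groups
        names += [f"sigma2_e[group {k}]" for k in range(self._n_groups)]
        x0 = np.log(np.asarray(x0))
        bounds = [(np.log(floor), np.log(cap))] * self._n_params

        def unpack(phi):
            v = np.exp(phi)
            i = 0
            sg2 = v[i] if big_random else None
            i += int(big_random)
            sa2 = v[i] if small_random else None
            i += int(small_random)
            return sg2, sa2, v[i:]

        def obj(phi):
            nll, grad, _ = self._eval(*unpack(phi), want_grad=True)
            return nll, grad

        res = scipy.optimize.minimize(
            obj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": self.tol,
                     "gtol": self.gtol, "maxcor": 20},
        )
        # L-BFGS-B line searches stall well above machine precision; polish
        # with damped Newton on the analytic gradient (Hessian by finite
        # differences of the gradient -- cheap at <= ~40 parameters).
        phi, n_newton = self._newton_polish(obj, res.x, np.asarray(bounds))
        sg2, sa2, se2 = unpack(phi)
        nll, grad, aux = self._eval(sg2, sa2, se2, want_grad=True)

        at_bound = (phi <= np.asarray(bounds)[:, 0] + 1e-9)
        free_grad = np.where(at_bound, np.minimum(grad, 0.0), grad)
        self.n_iter_ = int(res.nit) + n_newton
        self.converged_ = (
            float(np.max(np.abs(free_grad))) < self.gtol
            or bool(res.success)
        )
        self.message_ = str(res.message)
        self.boundary_ = {
            nm for nm, lo in zip(names, res.x) if lo <= np.log(floor) + 1e-9
        }
        self._store(df, sg2, sa2, se2, aux, float(-nll))
        return self

    def _newton_polish(self, obj, phi0: np.ndarray, bounds: np.ndarray,
                       max_steps: int = 30) -> tuple[np.ndarray, int]:
        """Damped Newton refinement within bounds; returns (phi, n_steps).

        Coordinates pinned at the variance floor with an outward-pointing
        gradient are frozen rather than pushed through the bound.
        """
        phi = np.asarray(phi0, dtype=float).copy()
        k = len(phi)
        h = 1e-5
        steps = 0
        for steps in range(max_steps):
            nll, gr = obj(phi)
            at_lo = phi <= bounds[:, 0] + 1e-9
            free = ~(at_lo & (gr > 0))
            if not np.any(free) or np.max(np.abs(gr[free])) < 1e-12:
                break
            H = np.zeros((k, k))
            for j in range(k):
                e = np.zeros(k); e[j] = h
                H[:, j] = (obj(phi + e)[1] - obj(phi - e)[1]) / (2 * h)
            H = (H + H.T) / 2.0
            idx = np.where(free)[0]
            try:
                step = np.linalg.solve(
                    H[np.ix_(idx, idx)] + 1e-12 * np.eye(len(idx)), gr[idx]
                )
            except np.linalg.LinAlgError:
                break
            gnorm = np.max(np.abs(gr[free]))
            lam, improved = 1.0, False
            while lam > 1e-4:
                cand = phi.copy()
                cand[idx] = phi[idx] - lam * step
                cand = np.clip(cand, bounds[:, 0], bounds[:, 1])
                f2, g2 = obj(cand)
                # near the optimum f is flat to rounding; a shrinking
                # gradient is the sharper acceptance signal
                if f2 <= nll or np.max(np.abs(g2[free])) < gnorm:
                    phi, improved = cand, True
                    break
                lam /= 2.0
            if not improved:
                break
        return phi, steps

    def _fit_degenerate(self, df: pd.DataFrame) -> "MixedModelREML":
        """All observed values identical: every variance sits at zero."""
        self._n_params = 0
        aux = None
        self.n_iter_ = 0
        self.converged_ = True
        self.message_ = "degenerate input (zero phenotypic variance)"
        self.boundary_ = {"sigma2_G", "sigma2_A", "sigma2_e"}
        big_random = self.genotype_role == "random"
        small_random = self.year_role == "random"
        sg2 = 0.0 if big_random else None
        sa2 = 0.0 if small_random else None
        se2 = np.zeros(self._n_groups)
        mu = float(self._y.mean()) + self._y_shift
        self.mu_ = mu if (big_random and small_random) else None
        self.sigma2_g_ = sg2
        self.sigma2_a_ = sa2
        self.sigma2_e_by_year_ = {int(yy): 0.0 for yy in self._years}
        gvals = np.zeros(self._I)
        if not big_random:  # fixed genotype: cell means are the values
            sums = np.bincount(self._a, weights=self._y, minlength=self._I)
            cnts = np.bincount(self._a, minlength=self._I)
            gvals = sums / cnts + self._y_shift
        self.genotype_effects_ = pd.Series(gvals, index=self._acc_index)
        if not big_random:
            self.blues_se_ = pd.Series(np.zeros(self._I), index=self._acc_index)
        if self.year_role == "fixed":
            ysum = np.bincount(self._t, weights=self._y, minlength=self._J)
            ycnt = np.bincount(self._t, minlength=self._J)
            self.year_effects_ = pd.Series(
                ysum / ycnt + self._y_shift, index=pd.Index(self._years, name="year")
            )
        else:
            self.year_effects_ = pd.Series(np.zeros(self._J), index=pd.Index(self._years, name="year"))
        self.residuals_ = np.zeros(self._n)
        self.standardized_residuals_ = np.zeros(self._n)
        self.loglik_ = 0.0
        return self

    def _store(self, df, sg2, sa2, se2, aux, loglik) -> None:
        intercept = self.genotype_role == "random" and self.year_role == "random"
        shift = self._y_shift
        self.mu_ = float(aux["s_small"][self._J]) + shift if intercept else None
        self.sigma2_g_ = float(sg2) if sg2 is not None else None
        self.sigma2_a_ = float(sa2) if sa2 is not None else None
        self.sigma2_e_by_year_ = {
            int(yy): float(se2[self._year_group[j]]) for j, yy in enumerate(self._years)
        }
        g_big = aux["g_big"] + (shift if self.genotype_role == "fixed" else 0.0)
        self.genotype_effects_ = pd.Series(g_big, index=self._acc_index)
        year_eff = aux["s_small"][: self._J] + (
            shift if self.year_role == "fixed" else 0.0
        )
        self.year_effects_ = pd.Series(
            year_eff, index=pd.Index(self._years, name="year")
        )
        if self.genotype_role == "fixed":
            A, F, cf = aux["A"], aux["F"], aux["cf"]
            Sinv = sla.cho_solve(cf, np.eye(F.shape[1]))
            rowquad = np.einsum("ij,ij->i", F @ Sinv, F)
            self.blues_se_ = pd.Series(np.sqrt(1.0 / A + rowquad), index=self._acc_index)
        resid = aux["resid"]
        self.residuals_ = resid
        with np.errstate(divide="ignore", invalid="ignore"):
            self.standardized_residuals_ = resid / np.sqrt(aux["se2_rec"])
        self.loglik_ = loglik
        self._fit_index = df.index.to_numpy()

    # ------------------------------------------------------------------
    @property
    def components_(self) -> VarianceComponents:
        return VarianceComponents(
            mu=self.mu_,
            sigma2_G=self.sigma2_g_,
            sigma2_A=self.sigma2_a_,
            sigma2_e_by_year=dict(self.sigma2_e_by_year_),
        )

    def blues(self) -> pd.DataFrame:
        """BLUEs (observation scale) with standard errors; fixed-genotype fits only."""
        if self.genotype_role != "fixed":
            raise ValueError("BLUEs require a fixed-genotype fit")
        if not self.converged_:
            raise ValueError("fit did not converge; BLUEs unavailable")
        return pd.DataFrame(
            {"blue": self.genotype_effects_, "se": self.blues_se_}
        ).rename_axis("accession_id")

    def restricted_loglik(self, X, components: VarianceComponents) -> float:
        """Evaluate the restricted log-likelihood at given variance components.

        The design must match ``X``; used to verify that the fitted solution
        is a (local) maximum of the REML objective.
        """
        self._spec_check()
        df = _extract_frame(X)
        self._design(df)
        years = set(int(v) for v in self._years)
        given = set(int(k) for k in components.sigma2_e_by_year)
        if years != given:
            raise ValueError(
                f"year set mismatch: data has {sorted(years)}, components {sorted(given)}"
            )
        # map per-year variances onto groups (group value = mean over its years)
        se2 = np.zeros(self._n_groups)
        cnt = np.zeros(self._n_groups)
        for j, yy in enumerate(self._years):
            se2[self._year_group[j]] += components.sigma2_e_by_year[int(yy)]
            cnt[self._year_group[j]] += 1
        se2 /= cnt
        self._n_params = 0
        nll, _, _ = self._eval(
            components.sigma2_G if self.genotype_role == "random" else None,
            components.sigma2_A if self.year_role == "random" else None,
            se2, want_grad=False,
        )
        return float(-nll)


# ---------------------------------------------------------------------------
# thin functional wrappers

def fit_reml(ds, spec: ModelSpec = ModelSpec()) -> MixedModelREML:
    """Fit the additive mixed model by REML; returns the fitted estimator."""
    return MixedModelREML(
        genotype_role=spec.genotype_role,
        year_role=spec.year_role,
        heterogeneous_errors=spec.heterogeneous_errors,
        tol=spec.tol,
        max_iter=spec.max_iter,
    ).fit(ds)


def predict_blues(fit: MixedModelREML) -> pd.DataFrame:
    """Per-accession BLUEs with standard errors, on the observation scale."""
    return fit.blues()


def restricted_loglik(ds, spec: ModelSpec, components: VarianceComponents) -> float:
    """REML objective at ``components`` for dataset ``ds`` under ``spec``."""
    m = MixedModelREML(
        genotype_role=spec.genotype_role,
        year_role=spec.year_role,
        heterogeneous_errors=spec.heterogeneous_errors,
        tol=spec.tol,
        max_iter=spec.max_iter,
    )
    return m.restricted_loglik(ds, components)
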