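"""Second-stage censored regression of DEA inefficiency on environmental factors.

CRS efficiency scores theta in (0, 1] are transformed to inefficiency
1/theta - 1, which is exactly zero for efficient hospitals — giving the
dependent variable a point mass at zero that motivates a left-censored
(Tobit) normal model.  Two estimators are provided:

* pooled Tobit: latent y* = x'beta + e, e ~ N(0, sigma_e^2), observed
  y = max(y*, 0); log-likelihood contributions are log phi((y - x'b)/s) - log s
  for uncensored rows and log Phi(-x'b/s) for censored rows;
* random-intercept panel Tobit: a hospital-level effect u_g ~ N(0, sigma_u^2)
  is added to the latent index and integrated out by Gauss-Hermite quadrature
  — matching the grouped panel structure (groups = hospitals, one observation
  per year).

Model comparison follows the published procedure: fit a small set of
candidate covariate sets and rank them by the Wald chi-square statistic that
all non-constant coefficients are zero.  Multicollinearity screening uses
variance inflation factors from auxiliary least-squares regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

#: the six candidate covariate sets of the published model comparison
MODEL_SETS: dict[str, list[str]] = {
    "m1": ["Z1", "Z2", "Z3", "Z4", "Z5", "Z6"],
    "m2": ["Z1", "Z2", "Z3", "Z5", "Z6"],
    "m3": ["Z1", "Z3", "D1", "D2", "D3", "Z5", "Z7"],
    "m4": ["Z1", "Z2", "Z3", "D1", "D2", "D3", "Z5", "Z7"],
    "m5": ["Z1", "Z2", "Z3", "Z4", "D1", "D2", "D3", "Z5", "Z7"],
    "m6": ["Z1", "Z2", "Z3", "Z4", "D1", "D2", "D3", "Z5", "Z6"],
}

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def transform_scores(scores, tol: float = 1e-8) -> np.ndarray:
    """Map efficiency scores in (0, 1] to inefficiency 1/score - 1.

    A score of 1 maps to exactly 0 (the censoring point).  Scores within
    ``tol`` of 1 — on either side — are treated as exactly 1, so that LP
    round-off on efficient units still produces the censoring mass.  Scores
    outside (0, 1 + tol] raise a ``ValueError``.
    """
    s = np.asarray(scores, dtype=float)
    if (s <= 0).any() or (s > 1 + tol).any():
        bad = s[(s <= 0) | (s > 1 + tol)]
        raise ValueError(f"scores must lie in (0, 1]; offending values: {bad}")
    s = np.minimum(s, 1.0)
    out = 1.0 / s - 1.0
    out[s >= 1.0 - tol] = 0.0
    return out


class RankDeficientError(ValueError):
    """Design matrix is not full column rank; names the collinear columns."""


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # columns whose removal restores rank = the collinear set
        collinear = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                collinear.append(names[j])
        raise RankDeficientError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear columns: {collinear or names}"
        )


class Tobit:
    """Left-censored (at zero) regression model, pooled or random-intercept.

    Parameters
    ----------
    endog : array (n,)
        Non-negative inefficiency scores; zeros are the censored mass.
    exog : array (n, k)
        Design matrix including the constant column.
    exog_names : list of str
    groups : array (n,), optional
        Group labels (hospital ids).  When given, ``fit`` estimates the
        random-intercept model unless ``random_effects=False``.
    n_quad : int
        Gauss-Hermite nodes for integrating out the group effect (>= 3).
    """

    def __init__(self, endog, exog, exog_names=None, groups=None, n_quad: int = 32):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        k = self.exog.shape[1]
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(k)
        ]
        if (self.endog < 0).any():
            raise ValueError("endog must be non-negative (left-censored at 0)")
        if not (self.endog > 0).any():
            raise ValueError("degenerate model: all observations censored at 0")
        _check_full_rank(self.exog, self.exog_names)
        if n_quad < 3:
            raise ValueError("quadrature needs at least 3 nodes")
        self.n_quad = n_quad
        self.groups = None
        self._group_index = None
        if groups is not None:
            groups = np.asarray(groups)
            labels, index = np.unique(groups, return_inverse=True)
            self.groups = labels
            self._group_index = index
        self.censored = self.endog <= 0

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        endog: str = "ineff",
        covariates=None,
        group: str | None = "dmu_id",
        add_constant: bool = True,
        n_quad: int = 32,
    ) -> "Tobit":
        """Build the model from a tidy table of inefficiency and covariates."""
        covariates = list(covariates) if covariates is not None else [
            c for c in data.columns if c not in (endog, group, "year")
        ]
        X = data[covariates].to_numpy(dtype=float)
        names = list(covariates)
        if add_constant:
            X = np.column_stack([X, np.ones(len(data))])
            names = names + ["const"]
        groups = data[group].to_numpy() if group is not None and group in data else None
        return cls(data[endog].to_numpy(dtype=float), X, names, groups, n_quad)

    # -- likelihoods ---------------------------------------------------------
    def _row_loglike(self, xb: np.ndarray, sigma_e: float) -> np.ndarray:
        """Per-observation log-density given the latent mean ``xb``."""
        z = (self.endog - xb) / sigma_e
        ll = np.where(
            self.censored,
            special.log_ndtr(-xb / sigma_e),
            -_LOG_SQRT_2PI - 0.5 * z**2 - np.log(sigma_e),
        )
        return ll

    def loglike_pooled(self, params: np.ndarray) -> float:
        """params = [beta, log sigma_e]."""
        beta, log_se = params[:-1], params[-1]
        sigma_e = np.exp(log_se)
        return float(np.sum(self._row_loglike(self.exog @ beta, sigma_e)))

    def score_pooled(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of the pooled log-likelihood."""
        beta, log_se = params[:-1], params[-1]
        sigma_e = np.exp(log_se)
        xb = self.exog @ beta
        z = (self.endog - xb) / sigma_e
        a = -xb / sigma_e
        # inverse Mills ratio at the censoring point, computed in log space
        log_phi = -_LOG_SQRT_2PI - 0.5 * a**2
        mills = np.exp(log_phi - special.log_ndtr(a))
        dmu = np.where(self.censored, -mills / sigma_e, z / sigma_e)
        dlogs = np.where(self.censored, -mills * a, z**2 - 1.0)
        g_beta = self.exog.T @ dmu
        return np.concatenate([g_beta, [float(np.sum(dlogs))]])

    def loglike_re(self, params: np.ndarray) -> float:
        """params = [beta, log sigma_e, log sigma_u]; GH-integrated likelihood."""
        beta, log_se, log_su = params[:-2], params[-2], params[-1]
        sigma_e, sigma_u = np.exp(log_se), np.exp(log_su)
        nodes, weights = np.polynomial.hermite.hermgauss(self.n_quad)
        u = np.sqrt(2.0) * sigma_u * nodes  # (K,)
        xb = self.exog @ beta
        n_groups = len(self.groups)
        # log f(y_i | xb + u_k) for every node: (K, n)
        total = 0.0
        ll_nodes = np.empty((self.n_quad, len(self.endog)))
        for k in range(self.n_quad):
            ll_nodes[k] = self._row_loglike(xb + u[k], sigma_e)
        group_ll = np.zeros((self.n_quad, n_groups))
        for k in range(self.n_quad):
            group_ll[k] = np.bincount(
                self._group_index, weights=ll_nodes[k], minlength=n_groups
            )
        log_w = np.log(weights)[:, None]
        total = np.sum(special.logsumexp(log_w + group_ll, axis=0))
        total -= n_groups * 0.5 * np.log(np.pi)
        return float(total)

    # -- fitting -------------------------------------------------------------
    def _start_params(self, random_effects: bool) -> np.ndarray:
        """Least-squares start: OLS beta on all rows, log residual sd."""
        beta, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
        resid = self.endog - self.exog @ beta
        s = max(np.std(resid), 1e-3)
        start = np.concatenate([beta, [np.log(s)]])
        if random_effects:
            start = np.concatenate([start, [np.log(max(s / 2, 1e-3))]])
        return start

    def fit(
        self,
        random_effects: bool | None = None,
        start_params=None,
        n_starts: int = 3,
        gtol: float = 1e-8,
        maxiter: int = 2000,
    ) -> "TobitResults":
        """Maximum-likelihood fit.

        ``random_effects`` defaults to True when group labels were supplied.
        Several deterministic starting points (least-squares start plus fixed
        perturbations) are tried and the best likelihood kept.
        """
        if random_effects is None:
            random_effects = self.groups is not None
        if random_effects and self.groups is None:
            raise ValueError("random-effects fit requires group labels")
        if random_effects and len(self.groups) < 2:
            raise ValueError("random-effects fit requires >= 2 groups")
        negll = (
            (lambda p: -self.loglike_re(p))
            if random_effects
            else (lambda p: -self.loglike_pooled(p))
        )
        jac = None if random_effects else (lambda p: -self.score_pooled(p))
        base = (
            np.asarray(start_params, dtype=float)
            if start_params is not None
            else self._start_params(random_effects)
        )
        starts = [base]
        for i in range(1, n_starts):
            pert = base.copy()
            pert[-1] += 0.5 * i          # inflate scale start
            pert[:-1] *= 1.0 - 0.1 * i   # shrink slope start
            starts.append(pert)
        best = None
        for s in starts:
            res = optimize.minimize(
                negll,
                s,
                jac=jac,
                method="BFGS",
                options={"gtol": gtol, "maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"Tobit optimisation failed: {best}")
        params = best.x
        hess = numdiff.approx_hess1(params, negll)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        return TobitResults(self, params, cov, -best.fun, random_effects, best)


@dataclass
class TobitResults:
    """MLE output: coefficients, dispersion, covariance, Wald statistic."""

    model: Tobit
    _params: np.ndarray
    _cov: np.ndarray
    llf: float
    random_effects: bool
    optim_result: object

    @property
    def k(self) -> int:
        return self.model.exog.shape[1]

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params[: self.k], index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.maximum(np.diag(self._cov)[: self.k], 0.0))
        return pd.Series(se, index=self.model.exog_names)

    @property
    def sigma_e(self) -> float:
        return float(np.exp(self._params[self.k]))

    @property
    def sigma_u(self) -> float:
        if not self.random_effects:
            return 0.0
        return float(np.exp(self._params[self.k + 1]))

    @property
    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._cov[: self.k, : self.k],
            index=self.model.exog_names,
            columns=self.model.exog_names,
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.model.exog_names)

    @property
    def n_obs(self) -> int:
        return len(self.model.endog)

    @property
    def n_groups(self) -> int | None:
        return None if self.model.groups is None else len(self.model.groups)

    @property
    def obs_per_group(self) -> float | None:
        if self.model.groups is None:
            return None
        return self.n_obs / self.n_groups

    def wald_test(self, terms=None) -> tuple[float, int]:
        """Wald chi-square that the named coefficients are jointly zero.

        Defaults to every non-constant coefficient (the conventional
        whole-model statistic).  Returns (statistic, degrees of freedom).
        """
        names = self.model.exog_names
        if terms is None:
            terms = [t for t in names if t != "const"]
        idx = [names.index(t) for t in terms]
        if not idx:
            return 0.0, 0
        b = self._params[idx]
        V = self._cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        return stat, len(idx)

    @property
    def wald_stat(self) -> float:
        return self.wald_test()[0]

    @property
    def wald_df(self) -> int:
        return self.wald_test()[1]

    def summary(self) -> str:
        w, df = self.wald_test()
        lines = [
            "Tobit regression (left-censored at 0)"
            + (" — random intercepts" if self.random_effects else " — pooled"),
            f"n_obs = {self.n_obs}"
            + (
                f", groups = {self.n_groups}, obs/group = {self.obs_per_group:.1f}"
                if self.n_groups
                else ""
            ),
            f"log-likelihood = {self.llf:.4f}   Wald chi2({df}) = {w:.2f}",
            f"sigma_e = {self.sigma_e:.4f}"
            + (f"   sigma_u = {self.sigma_u:.4f}" if self.random_effects else ""),
            "",
            f"{'term':>8} {'coef':>10} {'se':>9} {'z':>8} {'P>|z|':>8}",
        ]
        for name in self.model.exog_names:
            b, se, p = self.params[name], self.bse[name], self.pvalues[name]
            z = b / se if se > 0 else np.nan
            lines.append(f"{name:>8} {b:>10.4f} {se:>9.4f} {z:>8.2f} {p:>8.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        w, df = self.wald_test()
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "sigma_e": self.sigma_e,
            "sigma_u": self.sigma_u,
            "loglik": self.llf,
            "wald_chi2": w,
            "wald_df": df,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "random_effects": self.random_effects,
        }


def wald_test(fit: TobitResults, terms=None) -> tuple[float, int]:
    """Module-level convenience wrapper around ``TobitResults.wald_test``."""
    return fit.wald_test(terms)


def compare_models(
    data: pd.DataFrame,
    model_sets: dict[str, list[str]] | None = None,
    endog: str = "ineff",
    group: str | None = "dmu_id",
    random_effects: bool | None = None,
    n_quad: int = 32,
) -> pd.DataFrame:
    """Fit candidate covariate sets and rank them by the Wald statistic.

    Candidates that fail (e.g. rank-deficient designs) are reported with the
    error message instead of aborting the remaining fits.  Returns a frame
    sorted by descending Wald chi-square, with the fitted ``TobitResults``
    in the ``fit`` column.
    """
    model_sets = model_sets or MODEL_SETS
    rows = []
    for name, covs in model_sets.items():
        try:
            model = Tobit.from_dataframe(
                data, endog=endog, covariates=covs,
                group=group if group in data.columns else None, n_quad=n_quad,
            )
            fit = model.fit(random_effects=random_effects)
            w, df = fit.wald_test()
            rows.append(
                {
                    "model": name,
                    "wald_chi2": w,
                    "wald_df": df,
                    "loglik": fit.llf,
                    "n_obs": fit.n_obs,
                    "fit": fit,
                    "error": "",
                }
            )
        except (RankDeficientError, ValueError, RuntimeError) as err:
            rows.append(
                {
                    "model": name,
                    "wald_chi2": np.nan,
                    "wald_df": np.nan,
                    "loglik": np.nan,
                    "n_obs": np.nan,
                    "fit": None,
                    "error": str(err),
                }
            )
    out = pd.DataFrame(rows)
    if len(out) > 1:
        out = out.sort_values("wald_chi2", ascending=False, na_position="last")
    return out.reset_index(drop=True)


def vif(data: pd.DataFrame, covariates=None) -> pd.Series:
    """Variance inflation factor per covariate.

    VIF_j = 1 / (1 - R^2_j) from the least-squares regression of covariate j
    on the remaining covariates plus an intercept.  A (near-)constant
    covariate has no defined VIF and raises a ``ValueError``.
    """
    import statsmodels.api as sm

    covariates = list(covariates) if covariates is not None else [
        c for c in data.columns if c not in ("dmu_id", "dmu", "year")
    ]
    X = data[covariates].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(covariates):
        y = X[:, j]
        if np.std(y) == 0:
            raise ValueError(f"VIF undefined for constant covariate {name!r}")
        others = np.delete(X, j, axis=1)
        res = sm.OLS(y, sm.add_constant(others)).fit()
        out[name] = float(1.0 / (1.0 - res.rsquared))
    return pd.Series(out)
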