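"""Socio-economic association analysis for bounded prevalence outcomes.

Area-level prevalence is a proportion in [0, 1], so associations with
deprivation, age, ethnicity, urbanicity and smoke-control status are
modelled with beta regression: y ~ Beta(mu * phi, (1 - mu) * phi) with a
logit link on the mean, logit(mu) = X beta, and a constant precision phi.
A coefficient is then the change in the logit of expected prevalence per
unit of the covariate.

The model API follows the statsmodels convention: construct
:class:`BetaRegression` from arrays or a DataFrame, call :meth:`fit`, and
read estimates, standard errors and Wald intervals off the returned
:class:`BetaRegressionResults` (with a text ``summary()``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import digamma, expit, gammaln

DEFAULT_COVARIATES = ["median_age", "imd_score", "pct_white", "urban", "sca"]


def squeeze_proportions(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Compress boundary proportions into the open interval (0, 1).

    The standard transformation ``y' = (y * (n - 1) + 0.5) / n`` keeps
    interior values nearly unchanged while moving exact zeros and ones
    (common in low-prevalence areas) off the boundary, where the beta
    likelihood is undefined.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    n = n if n is not None else y.size
    return (y * (n - 1) + 0.5) / n


def _loglike(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    k = X.shape[1]
    beta, log_phi = params[:k], params[k]
    phi = np.exp(log_phi)
    mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    p, q = mu * phi, (1.0 - mu) * phi
    ll = (
        gammaln(phi) - gammaln(p) - gammaln(q)
        + (p - 1.0) * np.log(y) + (q - 1.0) * np.log1p(-y)
    )
    return float(ll.sum())


def _score(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    k = X.shape[1]
    beta, log_phi = params[:k], params[k]
    phi = np.exp(log_phi)
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    p, q = mu * phi, (1.0 - mu) * phi
    ystar = np.log(y) - np.log1p(-y)
    mustar = digamma(p) - digamma(q)
    # d ll / d eta = phi * (ystar - mustar) * mu * (1 - mu)
    d_eta = phi * (ystar - mustar) * mu * (1.0 - mu)
    g_beta = X.T @ d_eta
    d_phi = (
        digamma(phi) - mu * digamma(p) - (1.0 - mu) * digamma(q)
        + mu * np.log(y) + (1.0 - mu) * np.log1p(-y)
    ).sum()
    return np.concatenate([g_beta, [d_phi * phi]])  # chain rule for log_phi


def _numerical_hessian(f, x0: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = x0.size
    h = eps * np.maximum(1.0, np.abs(x0))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            xpp = x0.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x0.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (
                f(xpp) - f(xpm) - f(xmp) + f(xmm)
            ) / (4.0 * h[i] * h[j])
    return H


class BetaRegressionResults:
    """Fitted beta regression: estimates, uncertainty and diagnostics."""

    def __init__(self, model, params, cov_params, llf, converged, n_iter):
        self.model = model
        k = len(model.exog_names)
        self.params = pd.Series(params[:k], index=model.exog_names)
        self.phi = float(np.exp(params[k]))
        self._raw_params = params
        self.cov_params = cov_params
        self.bse = pd.Series(np.sqrt(np.diag(cov_params)[:k]),
                             index=model.exog_names)
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        self.nobs = model.endog.size

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "ci_low": self.params - z * self.bse,
                "ci_high": self.params + z * self.bse,
            }
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return expit(self.model.exog @ self.params.to_numpy())

    def to_frame(self, stratum: str = "all") -> pd.DataFrame:
        """Long coefficient table (term, estimate, SE, CI, stratum)."""
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "ci_low": ci["ci_low"].to_numpy(),
                "ci_high": ci["ci_high"].to_numpy(),
                "stratum": stratum,
            }
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Beta regression (logit link, constant precision)",
            f"n = {self.nobs}   log-likelihood = {self.llf:.2f}   "
            f"phi = {self.phi:.2f}   converged = {self.converged}",
            "-" * 72,
            f"{'term':<20}{'coef':>12}{'se':>10}{'ci_low':>12}{'ci_high':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<20}{self.params[name]:>12.4f}{self.bse[name]:>10.4f}"
                f"{ci.loc[name, 'ci_low']:>12.4f}{ci.loc[name, 'ci_high']:>12.4f}"
            )
        return "\n".join(lines)


class BetaRegression:
    """Beta regression with logit mean link and constant precision.

    Parameters
    ----------
    endog : array of proportions strictly inside (0, 1)
        Apply :func:`squeeze_proportions` first if boundary values occur.
    exog : (n, k) design matrix including the intercept column
    exog_names : column names for the design matrix
    """

    def __init__(self, endog, exog, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        if np.any((self.endog <= 0) | (self.endog >= 1)):
            raise ValueError(
                "endog must lie strictly in (0, 1); use squeeze_proportions "
                "for boundary values"
            )
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.exog_names = list(
            exog_names
            if exog_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        covariates: list[str],
        region_col: str | None = None,
        reference_region: str | None = None,
        squeeze: bool = True,
    ) -> "BetaRegression":
        """Build the model from a covariate table (complete-case).

        Region enters as indicator contrasts against ``reference_region``
        (default: first region in sorted order).  Boolean covariates are
        cast to 0/1; rows with any missing value are dropped.
        """
        import logging

        cols = [response] + covariates + ([region_col] if region_col else [])
        df = data[cols].dropna().copy()
        y = df[response].to_numpy(dtype=float)
        if squeeze:
            y = squeeze_proportions(y)
        X = [np.ones(len(df))]
        names = ["intercept"]
        for c in covariates:
            col = df[c].astype(float).to_numpy()
            if np.ptp(col) == 0:
                # constant within the (sub)sample, e.g. SCA status in a
                # rural stratum — uninformative and collinear with the
                # intercept, so dropped rather than failing the fit
                logging.getLogger(__name__).warning(
                    "covariate %r is constant in this sample; dropped", c
                )
                continue
            X.append(col)
            names.append(c)
        if region_col:
            regions = sorted(df[region_col].unique())
            ref = reference_region if reference_region is not None else regions[0]
            for r in regions:
                if r == ref:
                    continue
                X.append((df[region_col] == r).astype(float).to_numpy())
                names.append(f"region[{r}]")
        return cls(y, np.column_stack(X), names)

    def fit(self, maxiter: int = 500, tol: float = 1e-10) -> BetaRegressionResults:
        """Maximum likelihood via BFGS with analytic score.

        Starting values: OLS on the empirical logit for the mean
        coefficients and a method-of-moments precision.  Standard errors
        come from the inverse observed information (numerical Hessian of
        the log-likelihood at the optimum).  Raises on non-convergence
        with the optimiser message.
        """
        X, y = self.exog, self.endog
        ylogit = np.log(y) - np.log1p(-y)
        beta0, *_ = np.linalg.lstsq(X, ylogit, rcond=None)
        mu0 = expit(X @ beta0)
        resid_var = max(np.var(y - mu0), 1e-6)
        phi0 = max(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 1.0)
        x0 = np.concatenate([beta0, [np.log(phi0)]])

        res = optimize.minimize(
            lambda p: -_loglike(p, X, y),
            x0,
            jac=lambda p: -_score(p, X, y),
            method="BFGS",
            options={"maxiter": maxiter, "gtol": max(tol, 1e-7) * len(y)},
        )
        # BFGS sometimes reports precision loss while sitting at the
        # optimum; judge convergence by the score itself (per observation)
        grad = _score(res.x, X, y)
        converged = bool(res.success) or np.max(np.abs(grad)) <= 1e-4 * len(y)
        if not converged:
            raise RuntimeError(
                f"beta regression did not converge: {res.message} "
                f"(iterations: {res.nit}, |grad|_max: {np.max(np.abs(grad)):.3g})"
            )
        H = _numerical_hessian(lambda p: _loglike(p, X, y), res.x)
        cov = np.linalg.inv(-H)
        return BetaRegressionResults(
            self, res.x, cov, _loglike(res.x, X, y), converged, res.nit
        )


def stratified_models(
    data: pd.DataFrame,
    response: str = "prevalence",
    covariates: list[str] | None = None,
    region_col: str | None = "region",
    reference_region: str | None = None,
) -> dict[str, BetaRegressionResults]:
    """Fit the all-LSOA model plus urban-only and rural-only strata.

    The all-LSOA model includes the urban indicator; the stratified models
    drop it.  An empty stratum is skipped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    covariates = covariates or [
        c for c in DEFAULT_COVARIATES if c in data.columns
    ]
    out: dict[str, BetaRegressionResults] = {}
    out["all"] = BetaRegression.from_dataframe(
        data, response, covariates, region_col, reference_region
    ).fit()
    strat_covs = [c for c in covariates if c != "urban"]
    for name, mask in [
        ("urban", data["urban"].astype(bool)),
        ("rural", ~data["urban"].astype(bool)),
    ]:
        subset = data[mask]
        if len(subset) == 0:
            logger.warning("stratum %s is empty; skipped", name)
            continue
        out[name] = BetaRegression.from_dataframe(
            subset, response, strat_covs, region_col, reference_region
        ).fit()
    return out


def prevalence_decile_table(
    prevalence: pd.Series,
    covariates: pd.DataFrame,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Socio-economic indicator means by decile of area prevalence.

    Areas are ranked by prevalence (ties broken by area code for
    determinism) and split into ten near-equal groups; decile 1 is the
    lowest prevalence.  Requires at least 10 areas.
    """
    covariate_cols = covariate_cols or [
        c for c in ["imd_score", "pct_white", "median_age", "urban"]
        if c in covariates.columns
    ]
    df = covariates.set_index("lsoa").copy()
    df["prevalence"] = prevalence
    df = df[df["prevalence"].notna()]
    if len(df) < 10:
        raise ValueError("need at least 10 areas for a decile table")
    order = (
        df.rename_axis("lsoa")
        .reset_index()
        .sort_values(["prevalence", "lsoa"], kind="mergesort")
        .set_index("lsoa")
    )
    n = len(order)
    order["decile"] = np.arange(n) * 10 // n + 1
    agg = {c: "mean" for c in covariate_cols}
    agg["prevalence"] = "mean"
    out = order.groupby("decile").agg(agg).reset_index()
    if "urban" in out.columns:
        # report urban share as a percentage
        out["urban"] = out["urban"].astype(float) * 100.0
        out = out.rename(columns={"urban": "urban_pct"})
    return out.rename(columns={"prevalence": "prevalence_mean"})


def region_decile_points(
    prevalence: pd.Series,
    covariates: pd.DataFrame,
    covariate: str = "imd_score",
    urban_only: bool = True,
    weight_col: str | None = "population",
) -> pd.DataFrame:
    """Region × covariate-decile summary points for gradient charts.

    Within each region, (urban) LSOAs are grouped into deciles of the
    explanatory covariate; each point carries the mean covariate, the mean
    prevalence, and the total population weight of its decile.  Regions
    with fewer than 10 LSOAs degrade to the available quantiles and are
    flagged.
    """
    df = covariates.set_index("lsoa").copy()
    df["prevalence"] = prevalence
    df = df[df["prevalence"].notna()]
    if urban_only:
        df = df[df["urban"].astype(bool)]
    rows = []
    for region, grp in df.groupby("region"):
        g = grp.sort_values([covariate], kind="mergesort")
        g = g.assign(_code=g.index).sort_values(
            [covariate, "_code"], kind="mergesort"
        )
        n = len(g)
        n_bins = min(10, n)
        degraded = n < 10
        g["decile"] = np.arange(n) * n_bins // n + 1
        for dec, sub in g.groupby("decile"):
            w = (
                sub[weight_col].sum()
                if weight_col and weight_col in sub.columns
                else len(sub)
            )
            rows.append(
                {
                    "region": region,
                    "decile": int(dec),
                    "covariate": covariate,
                    "mean_covariate": sub[covariate].mean(),
                    "mean_prevalence_pct": sub["prevalence"].mean(),
                    "weight": w,
                    "degraded": degraded,
                }
            )
    return pd.DataFrame(rows)
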