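"""Random-effects meta-regression with REML residual heterogeneity.

Models the study-level log effects as

    y_i = x_i' beta + u_i + e_i,   u_i ~ N(0, tau^2),  e_i ~ N(0, v_i)

with known sampling variances v_i.  The residual between-study variance
tau^2 is estimated by restricted maximum likelihood (bounded scalar
search); at the REML tau^2 the coefficients are the weighted
least-squares solution with weights 1/(v_i + tau^2).

Effect modifiers are tested one at a time by default, mirroring common
practice when exploring heterogeneity in a meta-analysis; joint models
are available via ``joint=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effect_measures import Estimate

__all__ = ["MetaRegressionFit", "Coefficient", "meta_regress", "screen_modifiers",
           "restricted_loglik", "code_covariates"]

# size_class is an ordered factor; code it 0/1/2 rather than with dummies
_ORDERED_CODINGS = {"size_class": {"small": 0, "moderate": 1, "large": 2}}


@dataclass(frozen=True)
class Coefficient:
    name: str
    estimate: float
    se: float
    z: float
    p: float


@dataclass
class MetaRegressionFit:
    coefficients: list[Coefficient]
    tau_squared_resid: float
    k: int
    covariate_coding: dict[str, str]
    reml_loglik: float

    def coef(self, name: str) -> Coefficient:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(name)


def code_covariates(covariates: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """Numerically code a covariate table.

    Numeric columns pass through.  ``size_class`` is coded as an ordered
    integer (small=0, moderate=1, large=2).  Other categorical columns
    are treatment-coded 0/1 indicators against their first (sorted)
    level.  Returns the design columns and a record of the coding used.
    """
    cols = {}
    coding: dict[str, str] = {}
    for name in covariates.columns:
        col = covariates[name]
        if name in _ORDERED_CODINGS:
            mapping = _ORDERED_CODINGS[name]
            cols[name] = col.map(mapping).astype(float)
            coding[name] = f"ordered integer {mapping}"
        elif pd.api.types.is_numeric_dtype(col):
            cols[name] = col.astype(float)
            coding[name] = "numeric, as supplied"
        else:
            levels = sorted(col.dropna().astype(str).unique())
            if len(levels) < 2:
                cols[name] = pd.Series(np.zeros(len(col)), index=col.index)
                coding[name] = f"constant level {levels}"
                continue
            ref = levels[0]
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float)
            coding[name] = f"treatment coding, reference {ref!r}"
    return pd.DataFrame(cols, index=covariates.index), coding


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Restricted log-likelihood of tau^2 (additive constants dropped)."""
    V = v + tau2
    w = 1.0 / V
    XtW = X.T * w
    XtWX = XtW @ X
    beta = np.linalg.solve(XtWX, XtW @ y)
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (float(np.sum(np.log(V))) + logdet + float(np.sum(w * r * r)))


def meta_regress(estimates: list[Estimate], covariates: pd.DataFrame,
                 method: str = "reml") -> MetaRegressionFit:
    """Fit one random-effects meta-regression model by REML.

    Parameters
    ----------
    estimates
        Study effects on the analysis scale.
    covariates
        Table keyed (indexed) by study_id; one or more covariate
        columns, all entering this single model jointly.  An empty
        table fits the intercept-only model, whose intercept is the
        REML random-effects pooled mean (numerically different from
        the DerSimonian-Laird moment estimate).  For the usual
        heterogeneity screen of one modifier at a time use
        :func:`screen_modifiers`.
    method
        Only ``"reml"`` is implemented.

    Raises
    ------
    ValueError
        For a constant covariate (singular design, named in the
        message) or more coefficients than studies allow (k must be at
        least p + 2).
    """
    if method != "reml":
        raise ValueError(f"unsupported method {method!r}; only 'reml' is implemented")
    k = len(estimates)
    ids = [e.study_id for e in estimates]
    missing = [s for s in ids if s not in covariates.index]
    if covariates.shape[1] > 0 and missing:
        raise ValueError(f"covariate table lacks rows for: {missing}")
    y = np.array([e.y for e in estimates])
    v = np.array([e.v for e in estimates])

    if covariates.shape[1] > 0:
        coded, coding = code_covariates(covariates.loc[ids])
        for name in coded.columns:
            if np.ptp(coded[name].to_numpy()) == 0:
                raise ValueError(f"covariate {name!r} is constant across studies; singular design")
        X = np.column_stack([np.ones(k), coded.to_numpy(dtype=float)])
        names = ["intercept"] + list(coded.columns)
    else:
        coding = {}
        X = np.ones((k, 1))
        names = ["intercept"]
    p = X.shape[1]
    if k < p + 2:
        raise ValueError(f"k = {k} studies cannot support {p} coefficients (need k >= p + 2)")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient (collinear covariates)")

    # Bounded scalar REML search; the upper bound comfortably exceeds any
    # plausible residual heterogeneity for log-scale effects.
    upper = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1.0)
    res = optimize.minimize_scalar(
        lambda t2: -restricted_loglik(t2, y, v, X),
        bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    ll_hat = restricted_loglik(tau2, y, v, X)
    ll_zero = restricted_loglik(0.0, y, v, X)
    if ll_zero >= ll_hat:
        tau2, ll_hat = 0.0, ll_zero

    w = 1.0 / (v + tau2)
    XtWX = (X.T * w) @ X
    beta = np.linalg.solve(XtWX, (X.T * w) @ y)
    cov = np.linalg.inv(XtWX)
    ses = np.sqrt(np.diag(cov))
    coefs = []
    for name, b, se in zip(names, beta, ses):
        z = b / se
        coefs.append(Coefficient(name=name, estimate=float(b), se=float(se),
                                 z=float(z), p=float(2.0 * stats.norm.sf(abs(z)))))
    return MetaRegressionFit(coefficients=coefs, tau_squared_resid=tau2, k=k,
                             covariate_coding=coding, reml_loglik=float(ll_hat))


def screen_modifiers(estimates: list[Estimate],
                     covariates: pd.DataFrame) -> dict[str, MetaRegressionFit]:
    """Test each potential effect modifier in its own univariable model.

    This is the default way heterogeneity sources are screened: each
    covariate column is fitted singly against the study effects, so the
    reported coefficient for a factor is not adjusted for the others.
    Returns a map from covariate name to its fit.
    """
    return {name: meta_regress(estimates, covariates[[name]])
            for name in covariates.columns}
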