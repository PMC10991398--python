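"""Cumulative-link (proportional-odds) models of final team rank.

The response is the final ranking position (1 = winner, larger = worse),
modelled as P(rank <= j | x) = logistic(theta_j - x.beta) with shared
slopes across thresholds, so a NEGATIVE coefficient means better (higher)
placement.  Fitting is maximum likelihood via statsmodels' OrderedModel
with deterministic quasi-Newton settings.  The module also provides the
maximum-likelihood pseudo R-squared (r2ML), variance inflation factors,
the quadratic / interaction / top-k logistic robustness fits, and the
experience-stratified (Aiken-West simple slopes) fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.api import Logit
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .cohort import STRATA

#: Feature set of the headline models (overtime risk in minutes for
#: numerical conditioning; share_med is the omitted reference category
#: because the three shares sum to one).
DEFAULT_TERMS = (
    "share_high",
    "share_low",
    "collab_low",
    "collab_high",
    "landing_risk_high",
    "landing_risk_low",
    "time_high_risk_min",
    "time_low_risk_min",
)

SHARE_TERMS = ("share_high", "share_med", "share_low")

_OPTIM = {"method": "bfgs", "maxiter": 1000, "gtol": 1e-5, "disp": False}


class RankDeficientDesign(ValueError):
    """The design matrix is not full rank; names the collinear terms."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: terms, optional centered quadratic terms, optional
    (term, moderator) interaction products, optional stratum filter."""

    terms: tuple[str, ...] = DEFAULT_TERMS
    quadratic_terms: tuple[str, ...] = ()
    interaction_terms: tuple[tuple[str, str], ...] = ()
    stratum_filter: str | None = None
    response: str = "final_rank"

    def __post_init__(self):
        for q in self.quadratic_terms:
            if q not in self.terms:
                raise ValueError(f"quadratic term {q!r} not among terms")
        for a, _ in self.interaction_terms:
            if a not in self.terms:
                raise ValueError(f"interaction base term {a!r} not among terms")


@dataclass
class OrdinalFit:
    """A fitted cumulative-link model.

    ``params`` etc. are indexed by design-column name; quadratic columns
    are named ``<term>_sq`` (centered before squaring, centers recorded in
    ``centers``), interactions ``<a>_x_<b>``.
    """

    spec: ModelSpec
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    thresholds: np.ndarray
    logl: float
    logl_null: float
    n: int
    levels: np.ndarray
    converged: bool
    centers: dict[str, float] = field(default_factory=dict)
    vif: pd.Series | None = None

    @property
    def r2_ml(self) -> float:
        return r2_ml(self.logl_null, self.logl, self.n)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.pvalues,
            }
        )


def build_design(data: pd.DataFrame, spec: ModelSpec, centers: dict | None = None):
    """Design matrix per spec: raw terms, centered-squared quadratics,
    products for interactions.  Returns (X DataFrame, centers dict).
    Pass ``centers`` to reuse the centering of a previous fit."""
    X = data.loc[:, list(spec.terms)].astype(float).copy()
    given = centers
    centers = {}
    for q in spec.quadratic_terms:
        c = float(X[q].mean()) if given is None else given[q]
        centers[q] = c
        X[f"{q}_sq"] = (X[q] - c) ** 2
    for a, b in spec.interaction_terms:
        moderator = data[b].astype(float) if b not in X.columns else X[b]
        X[f"{a}_x_{b}"] = X[a] * moderator
    _check_full_rank(X)
    return X, centers


def _check_full_rank(X: pd.DataFrame) -> None:
    cols = list(X.columns)
    zero_var = [c for c in cols if np.std(X[c].to_numpy(float)) == 0]
    if zero_var:
        raise RankDeficientDesign(f"zero-variance terms: {zero_var}")
    A = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in cols])
    A = A / np.linalg.norm(A, axis=0)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # Identify offenders by dropping columns one at a time.
        offenders = []
        for i, c in enumerate(cols, start=1):
            sub = np.delete(A, i, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                offenders.append(c)
        raise RankDeficientDesign(f"collinear terms: {offenders or cols}")


def null_loglikelihood(y) -> float:
    """Closed-form log-likelihood of the thresholds-only model (MLE
    probabilities are the empirical level frequencies)."""
    _, counts = np.unique(np.asarray(y), return_counts=True)
    n = counts.sum()
    return float((counts * np.log(counts / n)).sum())


def fit_ordinal(
    data: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05, compute_vif: bool = True
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds cumulative-logit fit."""
    if spec.stratum_filter is not None:
        data = data[data["stratum"] == spec.stratum_filter]
    y_raw = data[spec.response].to_numpy()
    levels = np.unique(y_raw)
    if len(levels) < 3:
        raise ValueError(f"response must take >= 3 ordered levels, got {len(levels)}")
    logl_null = null_loglikelihood(y_raw)

    if not spec.terms:
        # Thresholds-only model: analytic.
        cum = np.cumsum(np.unique(y_raw, return_counts=True)[1])[:-1] / len(y_raw)
        empty = pd.Series(dtype=float)
        return OrdinalFit(
            spec=spec, terms=[], params=empty, bse=empty, ci_low=empty,
            ci_high=empty, pvalues=empty,
            thresholds=np.log(cum / (1 - cum)),
            logl=logl_null, logl_null=logl_null, n=len(y_raw), levels=levels,
            converged=True,
        )

    X, centers = build_design(data, spec)
    y = pd.Series(pd.Categorical(y_raw, categories=list(levels), ordered=True))
    model = OrderedModel(y, X.to_numpy(float), distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(**_OPTIM)
    converged = bool(res.mle_retvals.get("converged", False))

    k = X.shape[1]
    names = list(X.columns)
    params = pd.Series(np.asarray(res.params)[:k], index=names)
    bse = pd.Series(np.asarray(res.bse)[:k], index=names)
    zcrit = norm.ppf(1 - alpha / 2)
    pvals = pd.Series(2 * norm.sf(np.abs(params / bse)), index=names)
    thresholds = np.asarray(model.transform_threshold_params(res.params))[1:-1]

    fit = OrdinalFit(
        spec=spec,
        terms=names,
        params=params,
        bse=bse,
        ci_low=params - zcrit * bse,
        ci_high=params + zcrit * bse,
        pvalues=pvals,
        thresholds=np.asarray(thresholds),
        logl=float(res.llf),
        logl_null=logl_null,
        n=len(y_raw),
        levels=levels,
        converged=converged,
        centers=centers,
    )
    if compute_vif and k >= 2:
        fit.vif = vif(X)
    if not converged:
        warnings.warn(f"ordinal fit did not converge (spec={spec})")
    return fit


def r2_ml(logl_null: float, logl_model: float, n: int) -> float:
    """Maximum-likelihood pseudo R-squared:
    ``1 - exp((2/n) * (logl_null - logl_model))``, in [0, 1)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 1.0 - float(np.exp((2.0 / n) * (logl_null - logl_model)))


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: 1 / (1 - R^2) of each column regressed
    on the others (intercept included).  Perfect collinearity gives inf."""
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("vif needs >= 2 columns")
    A = X.to_numpy(float)
    out = {}
    for i, c in enumerate(cols):
        yv = A[:, i]
        if np.std(yv) == 0:
            raise ValueError(f"column {c!r} has zero variance")
        Z = np.column_stack([np.ones(len(A)), np.delete(A, i, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, yv, rcond=None)
        resid = yv - Z @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def fit_stratified(
    data: pd.DataFrame, spec: ModelSpec, min_rows: int = 200, **kw
) -> dict[str, OrdinalFit]:
    """The base spec fitted separately per experience stratum (simple
    slopes by stratification)."""
    fits = {}
    counts = {s: int((data["stratum"] == s).sum()) for s in STRATA}
    small = {s: c for s, c in counts.items() if c < min_rows}
    if small:
        raise ValueError(f"undersized strata (min {min_rows} rows): {small}")
    for s in STRATA:
        fits[s] = fit_ordinal(data, replace(spec, stratum_filter=s), **kw)
    return fits


def fit_quadratic(data: pd.DataFrame, spec: ModelSpec, which=None, **kw) -> OrdinalFit:
    """The spec augmented with centered-and-squared interdependence shares."""
    which = tuple(which) if which is not None else tuple(
        t for t in spec.terms if t in SHARE_TERMS
    )
    return fit_ordinal(data, replace(spec, quadratic_terms=which), **kw)


def fit_interaction(
    data: pd.DataFrame, spec: ModelSpec, moderator: str = "z_experience", which=None, **kw
) -> OrdinalFit:
    """The spec augmented with share x standardized-experience products."""
    if data[moderator].std(ddof=0) == 0:
        raise RankDeficientDesign(f"moderator {moderator!r} has zero variance")
    which = tuple(which) if which is not None else tuple(
        t for t in spec.terms if t in SHARE_TERMS
    )
    terms = spec.terms if moderator in spec.terms else spec.terms + (moderator,)
    inter = tuple((t, moderator) for t in which)
    return fit_ordinal(data, replace(spec, terms=terms, interaction_terms=inter), **kw)


@dataclass
class LogisticFit:
    """Binary logistic robustness fit of a top-k outcome."""

    k: int
    params: pd.Series
    bse: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    logl: float
    logl_null: float
    n: int
    converged: bool
    separation: bool


def fit_logistic_topk(
    data: pd.DataFrame, spec: ModelSpec, k: int = 5, alpha: float = 0.05
) -> LogisticFit:
    """MLE logistic regression of 1{final_rank <= k} on the spec's terms."""
    if spec.stratum_filter is not None:
        data = data[data["stratum"] == spec.stratum_filter]
    y = (data[spec.response].to_numpy(int) <= k).astype(int)
    if y.min() == y.max():
        raise ValueError(f"degenerate top-{k} outcome: all {'ones' if y[0] else 'zeros'}")
    X, _ = build_design(data, spec)
    Xc = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    names = ["const"] + list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = Logit(y, Xc).fit(disp=False, maxiter=200)
    params = pd.Series(np.asarray(res.params), index=names)
    bse = pd.Series(np.asarray(res.bse), index=names)
    separation = bool(np.any(np.abs(params) > 50) or np.any(~np.isfinite(bse)))
    zcrit = norm.ppf(1 - alpha / 2)
    return LogisticFit(
        k=k,
        params=params,
        bse=bse,
        ci_low=params - zcrit * bse,
        ci_high=params + zcrit * bse,
        pvalues=pd.Series(2 * norm.sf(np.abs(params / bse)), index=names),
        logl=float(res.llf),
        logl_null=float(res.llnull),
        n=len(y),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
    )


def coefficient_difference(
    fit, term_a: str, term_b: str, round_to_int: bool = False
) -> float:
    """beta_a - beta_b, optionally rounded to whole ranking positions.

    ``fit`` may be any object with a ``params`` mapping, or a plain mapping
    of term -> coefficient (e.g. a printed coefficient table).
    """
    params = fit.params if hasattr(fit, "params") else fit
    for t in (term_a, term_b):
        if t not in params:
            raise KeyError(f"term {t!r} not in fit")
    diff = float(params[term_a]) - float(params[term_b])
    return float(round(diff)) if round_to_int else diff


def predicted_vs_observed(fit: OrdinalFit, data: pd.DataFrame) -> pd.DataFrame:
    """Observed rank vs model-expected rank (sum_j j * P(rank = j | x)) per
    row, for calibration plots."""
    if fit.spec.stratum_filter is not None:
        data = data[data["stratum"] == fit.spec.stratum_filter]
    y = data[fit.spec.response].to_numpy()
    if not fit.terms:
        xb = np.zeros(len(data))
    else:
        X, _ = build_design(
            data, replace(fit.spec, stratum_filter=None), centers=fit.centers or None
        )
        X = X[fit.terms]
        xb = X.to_numpy(float) @ fit.params.to_numpy()
    theta = np.concatenate([[-np.inf], fit.thresholds, [np.inf]])
    with np.errstate(over="ignore"):
        cdf = 1.0 / (1.0 + np.exp(-(theta[None, :] - xb[:, None])))
    probs = np.diff(cdf, axis=1)
    expected = probs @ fit.levels.astype(float)
    return pd.DataFrame({"observed": y, "expected": expected})
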