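"""Information-theoretic multimodel inference for site-level regressions.

Implements the full chain behind an AICc model-averaging analysis:
predictor scaling, marginality-respecting enumeration of all sub-models of
a global model, OLS and random-intercept fits (maximum likelihood, so
log-likelihoods are comparable across fixed-effect structures), AICc /
delta / Akaike weights over the full candidate set, full ("zero
substitution") model averaging with Burnham–Anderson unconditional standard
errors, variance inflation factors, and Moran's I spatial autocorrelation
of residuals with inverse-distance weights.

Marginality means an interaction term may enter a model only together with
all of its lower-order components, so the candidate set for a global model
with mains A, F, T, Temp and interactions A:F, A:T, F:T, A:F:T contains
19 hierarchical structures on {A, F, T} times 2 for the free main Temp —
38 models.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.formula.api as smf

from .errors import ModelFitError

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # normal 97.5% quantile


# ---------------------------------------------------------------- scaling

def scale_predictors(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center/scale columns to mean 0, sample sd 1; returns scaling metadata."""
    out = table.copy()
    meta: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = pd.to_numeric(out[col])
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} is constant; cannot scale")
        out[col] = (x - mu) / sd
        meta[col] = (mu, sd)
    return out, meta


def transform_response(
    values, transform: str = "identity", offset: float | None = None
) -> tuple[np.ndarray, float]:
    """Apply ln / ln-with-offset / identity to a response vector.

    ``ln_offset`` uses half the smallest positive value by default; the
    offset actually applied is returned so outputs can record it.
    """
    v = np.asarray(values, dtype=float)
    if transform == "identity":
        return v.copy(), 0.0
    if transform == "ln":
        if (v <= 0).any():
            raise ValueError("ln transform requires all values > 0; use ln_offset")
        return np.log(v), 0.0
    if transform == "ln_offset":
        if offset is None:
            positive = v[v > 0]
            if len(positive) == 0:
                raise ValueError("ln_offset requires at least one positive value")
            offset = float(positive.min()) / 2.0
        return np.log(v + offset), offset
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------- model specs

@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, fixed terms, optional random intercept.

    Terms are patsy-style; interactions use ':' between component names.
    The intercept is always implied.
    """

    response: str
    terms: tuple[str, ...]
    random_intercept: str | None = None
    transform: str = "identity"

    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"

    def label(self) -> str:
        return "+".join(self.terms) if self.terms else "(intercept)"


def _components(term: str) -> frozenset[str]:
    return frozenset(term.split(":"))


def _respects_marginality(subset: set[str]) -> bool:
    comp = {_components(t): t for t in subset}
    for t in subset:
        parts = sorted(_components(t))
        if len(parts) < 2:
            continue
        for r in range(1, len(parts)):
            for lower in itertools.combinations(parts, r):
                if frozenset(lower) not in comp:
                    return False
    return True


def enumerate_candidate_models(global_spec: ModelSpec) -> list[ModelSpec]:
    """All marginality-respecting sub-models of a global model.

    Includes the intercept-only model; the random intercept (if any) is
    carried unchanged into every candidate.  Order is deterministic: by
    model size, then by term positions in the global spec.
    """
    terms = list(global_spec.terms)
    if not _respects_marginality(set(terms)):
        raise ValueError("global model does not respect marginality")
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(range(len(terms)), r):
            subset = tuple(terms[i] for i in combo)
            if _respects_marginality(set(subset)):
                out.append(replace(global_spec, terms=subset))
    return out


# ---------------------------------------------------------------- fitting

@dataclass
class FittedModel:
    spec: ModelSpec
    coefficients: pd.Series
    ses: pd.Series
    loglik: float
    k: int
    n: int
    residuals: pd.Series
    r2: tuple[float, float | None]  # (ordinary, None) for OLS; (marginal, conditional) mixed


def _check_singular(exog: np.ndarray, names: list[str], spec: ModelSpec) -> None:
    if exog.shape[1] == 0:
        return
    _, R, piv = scipy.linalg.qr(exog, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(exog.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < exog.shape[1]:
        aliased = sorted(names[i] for i in piv[rank:])
        raise ModelFitError(f"singular design for {spec.formula()}; aliased terms: {aliased}")


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    """Fit one candidate: OLS if no random term, else ML mixed model.

    ``k`` counts the intercept, slopes, the residual variance and (for
    mixed models) the random-intercept variance, as AICc requires.
    """
    if spec.random_intercept is None:
        model = smf.ols(spec.formula(), data=data)
        _check_singular(model.exog, list(model.exog_names), spec)
        res = model.fit()
        k = len(res.params) + 1
        n = int(res.nobs)
        if n <= k + 1:
            raise ModelFitError(f"n={n} too small for k={k} parameters ({spec.formula()})")
        return FittedModel(
            spec=spec,
            coefficients=res.params,
            ses=res.bse,
            loglik=float(res.llf),
            k=k,
            n=n,
            residuals=pd.Series(np.asarray(res.resid), index=data.index),
            r2=(float(res.rsquared), None),
        )

    model = smf.mixedlm(spec.formula(), data=data, groups=data[spec.random_intercept])
    _check_singular(model.exog, list(model.exog_names), spec)
    res = None
    last_err: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # boundary fits (random-intercept variance -> 0) can leave a singular
        # Hessian in some optimizers; try several before giving up
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=False, method=method)
            except np.linalg.LinAlgError as e:
                last_err = e
                continue
            if cand.converged and np.isfinite(cand.llf):
                res = cand
                break
    if res is None:
        raise ModelFitError(
            f"mixed model did not converge: {spec.formula()}"
            + (f" ({last_err})" if last_err else "")
        )
    fe = res.fe_params
    k = len(fe) + 2
    n = int(res.nobs)
    if n <= k + 1:
        raise ModelFitError(f"n={n} too small for k={k} parameters ({spec.formula()})")
    var_f = float(np.var(model.exog @ fe.to_numpy()))
    var_re = float(np.asarray(res.cov_re)[0, 0])
    var_e = float(res.scale)
    total = var_f + var_re + var_e
    # fixed-effect covariance from the fitted variance components:
    # (sum_g X_g' V_g^-1 X_g)^-1 with V_g = var_e I + var_re 11'; well
    # defined at the var_re -> 0 boundary where the Hessian-based SEs fail
    groups = np.asarray(data[spec.random_intercept])
    A = np.zeros((model.exog.shape[1], model.exog.shape[1]))
    for g in pd.unique(groups):
        Xg = model.exog[groups == g]
        ng = Xg.shape[0]
        shrink = var_re / (var_e + ng * var_re) if var_re > 0 else 0.0
        col = Xg.sum(axis=0, keepdims=True)
        A += (Xg.T @ Xg - shrink * (col.T @ col)) / var_e
    bse = pd.Series(np.sqrt(np.diag(np.linalg.inv(A))), index=fe.index)
    # marginal residuals (fixed part only): robust to a zero RE variance,
    # where BLUP-based residuals are undefined
    marginal_resid = np.asarray(model.endog) - model.exog @ fe.to_numpy()
    return FittedModel(
        spec=spec,
        coefficients=fe,
        ses=bse,
        loglik=float(res.llf),
        k=k,
        n=n,
        residuals=pd.Series(marginal_resid, index=data.index),
        r2=(var_f / total, (var_f + var_re) / total),
    )


# ---------------------------------------------------------------- AICc table

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelTable:
    """Candidate models with AICc, delta and Akaike weights (full set).

    Weights are computed over the full candidate set; ``presented()``
    filters rows to delta < 6 for reporting, without renormalising.
    """

    models: list[FittedModel]
    frame: pd.DataFrame = field(init=False)

    def __post_init__(self):
        ns = {m.n for m in self.models}
        if len(ns) != 1:
            raise ValueError(f"models fitted on different n: {sorted(ns)}")
        rows = []
        for i, m in enumerate(self.models):
            rows.append(
                dict(
                    model_id=i,
                    terms=m.spec.label(),
                    k=m.k,
                    loglik=m.loglik,
                    AICc=aicc(m.loglik, m.k, m.n),
                    r2m=m.r2[0],
                    r2c=m.r2[1] if m.r2[1] is not None else np.nan,
                )
            )
        df = pd.DataFrame(rows)
        df["delta"] = df["AICc"] - df["AICc"].min()
        rel = np.exp(-0.5 * df["delta"].to_numpy())
        df["weight"] = rel / rel.sum()
        self.frame = df.sort_values(["AICc", "model_id"], kind="mergesort").reset_index(
            drop=True
        )

    @property
    def weights(self) -> np.ndarray:
        """Akaike weights in the original ``models`` order."""
        return (
            self.frame.sort_values("model_id")["weight"].to_numpy()
        )

    def presented(self, max_delta: float = 6.0) -> pd.DataFrame:
        return self.frame[self.frame["delta"] < max_delta].reset_index(drop=True)


def aicc_table(models: list[FittedModel]) -> ModelTable:
    return ModelTable(models)


# ---------------------------------------------------------------- averaging

def average_coefficients(
    models: list[FittedModel],
    weights,
    conditional: bool = False,
) -> pd.DataFrame:
    """Model-averaged partial coefficients with unconditional SEs and CIs.

    Full (zero-substitution) averaging by default: a model lacking a term
    contributes estimate 0 and SE 0 to that term's average.  The
    unconditional SE follows Burnham & Anderson:
    ``SE = sum_m w_m * sqrt(SE_m^2 + (b_m - b_bar)^2)``.  With
    ``conditional=True`` each term is averaged only over the models that
    contain it (weights renormalised).
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(models):
        raise ValueError("one weight per model required")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalised over the same models")
    order: list[str] = []
    for m in models:
        for name in m.coefficients.index:
            if name not in order:
                order.append(name)
    rows = []
    for name in order:
        present = np.array([name in m.coefficients.index for m in models])
        betas = np.array(
            [float(m.coefficients[name]) if p else 0.0 for m, p in zip(models, present)]
        )
        ses = np.array([float(m.ses[name]) if p else 0.0 for m, p in zip(models, present)])
        if conditional:
            wm = w * present
            wm = wm / wm.sum()
        else:
            wm = w
        est = float(wm @ betas)
        se = float(wm @ np.sqrt(ses ** 2 + (betas - est) ** 2))
        rows.append(
            dict(
                term=name,
                estimate=est,
                unconditional_se=se,
                ci_low=est - Z_95 * se,
                ci_high=est + Z_95 * se,
                importance=float(w[present].sum()),
            )
        )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------- diagnostics

def vif(table: pd.DataFrame, columns: list[str]) -> dict[str, float]:
    """Variance inflation factor of each column regressed on the others.

    Main effects only (interactions are excluded by the caller).  Perfect
    collinearity is reported as +inf with a warning, not an exception.
    """
    if len(columns) < 2:
        raise ValueError("VIF needs at least two columns")
    X = table[columns].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, col in enumerate(columns):
        y = X[:, j]
        others = np.column_stack([np.ones(len(y)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"column {col!r} is constant")
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
        if r2 >= 1.0 - 1e-12:
            logger.warning("perfect collinearity for %s; VIF = inf", col)
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return out


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    sd: float
    p_value: float


def morans_i(residuals, coords, weighting: str = "inverse_distance") -> MoranResult:
    """Moran's I of residuals with inverse-distance spatial weights.

    Expectation under no autocorrelation is -1/(n-1); the variance uses the
    normality assumption and the p-value a two-sided normal approximation.
    """
    if weighting != "inverse_distance":
        raise ValueError("only inverse-distance weighting is implemented")
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 sites")
    if xy.shape != (n, 2):
        raise ValueError("coords must be (n, 2)")
    if np.var(z) == 0:
        raise ValueError("residual variance is zero")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        raise ValueError("coincident site coordinates give infinite weights")
    W = np.zeros((n, n))
    W[off] = 1.0 / d[off]
    z = z - z.mean()
    s0 = W.sum()
    I = (n / s0) * float(z @ W @ z) / float(z @ z)
    e = -1.0 / (n - 1)
    s1 = 0.5 * float(((W + W.T) ** 2).sum())
    s2 = float(((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum())
    var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / ((n * n - 1.0) * s0 * s0) - e * e
    sd = float(np.sqrt(var))
    p = 2.0 * float(scipy.stats.norm.sf(abs(I - e) / sd))
    return MoranResult(I=float(I), expected=e, sd=sd, p_value=p)
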