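"""Phylogenetic generalized least squares with factor designs and AIC selection.

The response (log10 cecal length) is regressed on log10 body mass with
categorical cofactors (diet, clade, flight) under three residual-covariance
structures: statistical independence, Brownian motion (covariance equals
shared branch length), and Ornstein-Uhlenbeck (correlation exp(-alpha d) on
patristic distance, alpha profiled by ML).  Factors use treatment (dummy)
coding against explicit reference levels, so each fitted offset is a
contrast with the reference category.  All likelihoods are ML, not REML:
AIC is compared across designs with different fixed effects, and REML
likelihoods are not comparable across fixed-effect structures.

Model ladders are ranked by AIC; candidates with delta-AIC >= 3 relative to
the best model are flagged as rejected (a difference of 3 corresponds
roughly to a p-value of 0.051).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import EvolutionModel, PhyloCovariance, transform_covariance, vcv

_LOG_2PI = np.log(2.0 * np.pi)

DEFAULT_REFERENCE_LEVELS = {
    "diet": "carnivore-vertebrates",
    "clade": "Inopinaves",
    "flight": "strong flyer",
}

AIC_REJECTION_DELTA = 3.0  # delta-AIC at which support is considered substantially weaker


@dataclass(frozen=True)
class DesignSpec:
    """Fixed-effect structure for one regression.

    ``factors`` is a subset of {"diet", "clade", "flight"}; with
    ``interaction=True`` (single factor only — sparse categories preclude
    richer interactions) each level also gets its own slope on the covariate.
    """

    factors: tuple[str, ...] = ()
    interaction: bool = False
    response: str = "log_cecum"
    covariate: str = "log_mass"
    reference_levels: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.interaction and len(self.factors) != 1:
            raise ValueError("interaction designs allow exactly one factor")
        unknown = [f for f in self.factors if f not in ("diet", "clade", "flight")]
        if unknown:
            raise ValueError(f"unknown factors {unknown}")

    def reference_for(self, factor: str) -> str:
        for f, level in self.reference_levels:
            if f == factor:
                return level
        return DEFAULT_REFERENCE_LEVELS[factor]

    def with_references(self, references: dict) -> "DesignSpec":
        merged = {f: self.reference_for(f) for f in self.factors}
        merged.update(references)
        return replace(self, reference_levels=tuple(sorted(merged.items())))

    def label(self) -> str:
        if not self.factors:
            return "simple allometry"
        kind = ("different slopes and intercepts" if self.interaction
                else "same slope, different intercepts")
        return f"{kind} ({' & '.join(self.factors)})"


def build_design(traits: pd.DataFrame, spec: DesignSpec):
    """Construct the design matrix and column labels for a spec.

    Treatment coding: intercept, covariate, then one dummy per non-reference
    level of each factor (levels actually present in the data, in canonical
    order); interaction designs add a covariate slope modifier per
    non-reference level.  A requested reference level absent from the data is
    an error — its contrasts would be uninterpretable.
    """
    n = len(traits)
    cols = [np.ones(n), np.asarray(traits[spec.covariate], dtype=float)]
    labels = ["(Intercept)", spec.covariate]
    for factor in spec.factors:
        values = traits[factor].astype(str).to_numpy()
        if hasattr(traits[factor], "cat"):
            order = [lev for lev in traits[factor].cat.categories
                     if lev in set(values)]
        else:
            order = sorted(set(values))
        ref = spec.reference_for(factor)
        if ref not in set(values):
            raise ValueError(f"reference level {ref!r} of factor {factor!r} "
                             "is absent from the data")
        for level in order:
            if level == ref:
                continue
            cols.append((values == level).astype(float))
            labels.append(f"{factor}[{level}]")
        if spec.interaction:
            x = np.asarray(traits[spec.covariate], dtype=float)
            for level in order:
                if level == ref:
                    continue
                cols.append(x * (values == level))
                labels.append(f"{spec.covariate}:{factor}[{level}]")
    X = np.column_stack(cols)
    return X, labels


@dataclass
class GLSFit:
    beta: np.ndarray
    se: np.ndarray
    labels: list[str]
    loglik: float
    k: int
    aic: float
    df_resid: int
    n: int
    model: EvolutionModel
    sigma2_ml: float
    fitted: np.ndarray = field(repr=False)

    def coef(self, label: str) -> float:
        return float(self.beta[self.labels.index(label)])

    def coef_se(self, label: str) -> float:
        return float(self.se[self.labels.index(label)])

    def summary_frame(self) -> pd.DataFrame:
        t = self.beta / self.se
        p = 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame({"Value": self.beta, "SE": self.se,
                             "t": t, "p-value": p}, index=self.labels)


def _gls_solve(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Exact ML GLS for fixed V.  Returns (beta, se, loglik, sigma2_ml, fitted).

    beta = (X' V^-1 X)^-1 X' V^-1 y; sigma2 by ML (divisor n); standard
    errors use the unbiased divisor n - p so they pair with t-tests on
    n - p degrees of freedom.
    """
    n, p = X.shape
    try:
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"covariance not positive definite: {exc}")
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Vi_X = linalg.cho_solve(cho, X, check_finite=False)
    Vi_y = linalg.cho_solve(cho, y, check_finite=False)
    XtViX = X.T @ Vi_X
    cond = np.linalg.cond(XtViX)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("design matrix is rank deficient "
                                    "(collinear columns)")
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    rss = resid @ linalg.cho_solve(cho, resid, check_finite=False)
    sigma2_ml = rss / n
    sigma2_ub = rss / (n - p)
    loglik = -0.5 * (n * (_LOG_2PI + np.log(sigma2_ml) + 1.0) + logdet)
    se = np.sqrt(np.diag(sigma2_ub * np.linalg.inv(XtViX)))
    return beta, se, loglik, sigma2_ml, X @ beta


def _ou_alpha_bounds(C: PhyloCovariance) -> tuple[float, float]:
    depth = float(np.diag(C.matrix).max())
    return 1e-6, 500.0 / depth


def gls_fit(y: np.ndarray, X, C: PhyloCovariance, model: EvolutionModel,
            labels: Sequence[str] | None = None) -> GLSFit:
    """Fit one GLS under one evolution model.

    For ``kind="ou"`` with ``alpha=None`` the decay rate is profiled:
    a coarse log-spaced grid over [1e-6, 500/tree-depth] followed by bounded
    scalar refinement around the best grid point (tolerance 1e-6).  The
    parameter count k is the number of fixed effects plus one for the
    residual variance, plus one more when alpha is estimated.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if labels is None:
        labels = [f"b{j}" for j in range(p)]
    if n != C.n or n != len(y):
        raise ValueError("y, X, and covariance dimensions disagree")

    k_extra = 0
    if model.kind == "ou" and model.alpha is None:
        lo, hi = _ou_alpha_bounds(C)
        grid = np.geomspace(lo, hi, 40)

        def nll(alpha: float) -> float:
            V = transform_covariance(C, EvolutionModel.ou(alpha)).matrix
            try:
                return -_gls_solve(y, X, V)[2]
            except np.linalg.LinAlgError:
                return np.inf

        grid_nll = [nll(a) for a in grid]
        j = int(np.argmin(grid_nll))
        bracket = (grid[max(0, j - 1)], grid[min(len(grid) - 1, j + 1)])
        res = optimize.minimize_scalar(nll, bounds=bracket, method="bounded",
                                       options={"xatol": 1e-6})
        alpha_hat = float(res.x) if res.fun <= grid_nll[j] else float(grid[j])
        model = EvolutionModel.ou(alpha_hat)
        k_extra = 1
    elif model.kind == "ou":
        k_extra = 1

    V = transform_covariance(C, model).matrix
    beta, se, loglik, sigma2, fitted = _gls_solve(y, X, V)
    k = p + 1 + k_extra
    return GLSFit(beta=beta, se=se, labels=list(labels), loglik=float(loglik),
                  k=k, aic=float(-2.0 * loglik + 2.0 * k), df_resid=n - p,
                  n=n, model=model, sigma2_ml=float(sigma2), fitted=fitted)


def fit_design(traits: pd.DataFrame, C: PhyloCovariance, spec: DesignSpec,
               model: EvolutionModel) -> GLSFit:
    """Build the design for ``spec`` and fit it under ``model``.

    ``traits`` must already be aligned to the covariance taxon order.
    """
    X, labels = build_design(traits, spec)
    y = np.asarray(traits[spec.response], dtype=float)
    return gls_fit(y, X, C, model, labels=labels)


def coef_test(fit: GLSFit, coefficient: str,
              hypothesized: float = 0.0) -> tuple[float, int, float]:
    """Two-sided t-test of one coefficient against a hypothesized value.

    Degrees of freedom are n minus the number of fixed effects (the
    conventional GLS residual df).  Returns (t, df, p).
    """
    b = fit.coef(coefficient)
    se = fit.coef_se(coefficient)
    return t_test(b, se, fit.df_resid, hypothesized)


def t_test(value: float, se: float, df: int,
           hypothesized: float = 0.0) -> tuple[float, int, float]:
    t = (value - hypothesized) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), int(df), p


def relevel_fit(traits: pd.DataFrame, C: PhyloCovariance, spec: DesignSpec,
                new_reference_levels: dict,
                model: EvolutionModel) -> GLSFit:
    """Refit with different factor reference levels.

    A change of reference is a linear reparameterization of the same model
    space: fitted values, log-likelihood, and AIC are unchanged; offsets
    become contrasts with the new reference category.
    """
    return fit_design(traits, C, spec.with_references(new_reference_levels),
                      model)


@dataclass
class LadderEntry:
    spec: DesignSpec
    model_kind: str
    fit: GLSFit | None
    error: str | None = None
    delta_aic: float | None = None
    rejected: bool | None = None

    @property
    def aic(self) -> float | None:
        return None if self.fit is None else self.fit.aic


@dataclass
class ModelLadder:
    entries: list[LadderEntry]

    @property
    def best(self) -> LadderEntry:
        ok = [e for e in self.entries if e.fit is not None]
        if not ok:
            raise ValueError("no model in the ladder could be fitted")
        return min(ok, key=lambda e: e.fit.aic)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            alpha = (e.fit.model.alpha if e.fit is not None
                     and e.fit.model.kind == "ou" else None)
            rows.append({
                "design": e.spec.label(),
                "model": e.model_kind,
                "alpha": alpha,
                "AIC": e.aic,
                "deltaAIC": e.delta_aic,
                "rejected": e.rejected,
                "error": e.error,
            })
        return pd.DataFrame(rows)


LADDER_MODELS = ("independent", "brownian", "ou")


def fit_ladder(traits: pd.DataFrame, tree_or_cov, specs: Sequence[DesignSpec],
               models: Sequence[str] = LADDER_MODELS) -> ModelLadder:
    """Fit every design under every evolution model and rank by AIC.

    Per-fit failures (e.g. rank deficiency) do not abort the ladder; the
    failed cell carries its error message.  Delta-AIC is computed from
    unrounded AICs; entries with delta >= 3 are flagged rejected.
    """
    C = (tree_or_cov if isinstance(tree_or_cov, PhyloCovariance)
         else vcv(tree_or_cov))
    entries = []
    for spec in specs:
        for kind in models:
            model = (EvolutionModel("ou", alpha=None)
                     if kind == "ou" else EvolutionModel(kind))
            try:
                fit = fit_design(traits, C, spec, model)
                entries.append(LadderEntry(spec, kind, fit))
            except (np.linalg.LinAlgError, ValueError) as exc:
                entries.append(LadderEntry(spec, kind, None, error=str(exc)))
    aics = [e.fit.aic for e in entries if e.fit is not None]
    if aics:
        best = min(aics)
        for e in entries:
            if e.fit is not None:
                e.delta_aic = e.fit.aic - best
                e.rejected = e.delta_aic >= AIC_REJECTION_DELTA
    return ModelLadder(entries)


def study_designs(include_flight: bool = True) -> list[DesignSpec]:
    """The design ladder compared in the study: simple allometry; additive
    single factors; clade+diet; clade+diet+flight; and single-factor
    interaction (different-slopes) designs."""
    specs = [
        DesignSpec(),
        DesignSpec(factors=("clade",)),
        DesignSpec(factors=("diet",)),
        DesignSpec(factors=("clade", "diet")),
        DesignSpec(factors=("clade",), interaction=True),
        DesignSpec(factors=("diet",), interaction=True),
    ]
    if include_flight:
        specs.insert(3, DesignSpec(factors=("flight",)))
        specs.insert(5, DesignSpec(factors=("clade", "diet", "flight")))
        specs.append(DesignSpec(factors=("flight",), interaction=True))
    return specs
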