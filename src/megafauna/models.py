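"""Candidate extinction models: enumeration, fitting, AIC selection, lumping.

Extinction severity per region is regressed on climate-change scores and/or
hominin-history categories.  The primary fits are least squares on the
arcsine-square-root scale (the only reading with a defined AIC); a
quasi-binomial GLM on the raw proportions serves as a consistency check.
Anomaly and velocity of the same climate variable are never allowed in one
model, since velocity is computed from anomaly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ComparisonError,
    ConvergenceError,
    DesignError,
    DomainError,
    InvalidConfigError,
    NestingError,
    SparseCategoryError,
)
from .synthetic import ARCHAIC_CLASSES, HOMININ_CLASSES

CLIMATE_TERMS = ("T_anom", "T_vel", "P_anom", "P_vel")
_EXCLUSIVE = (("T_anom", "T_vel"), ("P_anom", "P_vel"))
HOMININ_CODINGS = ("h3", "h5", "arrival")


def arcsine_transform(p) -> np.ndarray:
    """Variance-stabilizing transform y = arcsin(sqrt(p)) on [0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: predictor set plus response transform."""

    climate: tuple = ()
    hominin: str | None = None  # "h3" | "h5" | "arrival" | None
    interactions: tuple = ()  # climate terms interacted with hominin
    transform: str = "arcsine-sqrt"

    def __post_init__(self) -> None:
        for t in self.climate:
            if t not in CLIMATE_TERMS:
                raise InvalidConfigError(f"unknown climate term {t!r}")
        for a, b in _EXCLUSIVE:
            if a in self.climate and b in self.climate:
                raise InvalidConfigError(
                    f"{a} and {b} are the anomaly and velocity of the same "
                    "variable and may not enter one model"
                )
        if self.hominin is not None and self.hominin not in HOMININ_CODINGS:
            raise InvalidConfigError(f"unknown hominin coding {self.hominin!r}")
        if set(self.interactions) - set(self.climate):
            raise InvalidConfigError("interactions must involve included climate terms")
        if self.interactions and self.hominin is None:
            raise InvalidConfigError("interactions need a hominin coding")
        if not self.climate and self.hominin is None:
            raise InvalidConfigError("model needs at least one predictor")

    def label(self) -> str:
        parts = list(self.climate)
        if self.hominin:
            parts.append(f"hominin[{self.hominin}]")
        parts.extend(f"hominin:{t}" for t in self.interactions)
        return " + ".join(parts)


def _hominin_columns(data: pd.DataFrame, coding: str):
    """Dummy (or numeric) columns for the requested hominin coding."""
    cls = data["hominin_class"]
    if coding == "h3":
        return {
            "HS": (cls == "Homo_sapiens-only").astype(float).to_numpy(),
            "AC": cls.isin(ARCHAIC_CLASSES).astype(float).to_numpy(),
        }
    if coding == "h5":
        return {
            c: (cls == c).astype(float).to_numpy() for c in HOMININ_CLASSES[1:]
        }
    if coding == "arrival":
        return {"arrival_time": data["arrival_time"].to_numpy(dtype=float)}
    raise InvalidConfigError(f"unknown hominin coding {coding!r}")


def build_design(spec: ModelSpec, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) and column names for a spec."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    for t in spec.climate:
        cols[t] = data[t].to_numpy(dtype=float)
    if spec.hominin:
        hcols = _hominin_columns(data, spec.hominin)
        cols.update(hcols)
        for t in spec.interactions:
            for hname, hvals in hcols.items():
                cols[f"{hname}x{t}"] = hvals * data[t].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols)


@dataclass
class ModelFit:
    """Fit summary shared by the arcsine-OLS and quasi-binomial routes."""

    spec: ModelSpec | None
    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    n: int
    df_resid: int
    rss: float | None
    loglik: float | None
    aic: float | None
    r2: float | None
    fstat: float | None
    f_df: tuple[int, int] | None
    f_pvalue: float | None
    dispersion: float | None
    fitted: np.ndarray
    residuals: np.ndarray
    response: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def table(self) -> pd.DataFrame:
        """Coefficient table mirroring the reference output schema."""
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.params,
                "sd": self.bse,
                "Z": self.tvalues,
                "p": self.pvalues,
            }
        )


def ols_fit(X: np.ndarray, y: np.ndarray, names: list[str], spec=None) -> ModelFit:
    """Gaussian-identity least squares with a fully specified AIC convention.

    AIC = -2 loglik + 2(k+1) where loglik is the full Gaussian log-likelihood
    at sigma^2 = RSS/n (2 pi terms included) and k+1 counts the coefficients
    plus sigma^2.  Coefficient tests use the unbiased RSS/(n-k) variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, R = np.linalg.qr(X)
        aliased = [names[j] for j in range(k) if abs(R[j, j]) < 1e-10] if names else []
        raise DesignError(f"design matrix rank deficient; aliased columns: {aliased}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    if sigma2_ml > 0:
        loglik = -(n / 2.0) * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    else:
        loglik = np.inf
    aic = -2 * loglik + 2 * (k + 1)
    df_resid = n - k
    s2 = rss / df_resid if df_resid > 0 else np.nan
    cov = s2 * np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    if k > 1 and df_resid > 0 and rss > 0:
        fstat = ((tss - rss) / (k - 1)) / (rss / df_resid)
        f_df = (k - 1, df_resid)
        f_p = float(stats.f.sf(fstat, *f_df))
    else:
        fstat, f_df, f_p = None, None, None
    return ModelFit(
        spec=spec,
        names=list(names),
        params=beta,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        n=n,
        df_resid=df_resid,
        rss=rss,
        loglik=float(loglik),
        aic=float(aic),
        r2=r2,
        fstat=None if fstat is None else float(fstat),
        f_df=f_df,
        f_pvalue=f_p,
        dispersion=None,
        fitted=fitted,
        residuals=resid,
        response=y,
    )


def fit_arcsine_glm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Least squares on arcsin(sqrt(proportion)), equal weights per region."""
    X, names = build_design(spec, data)
    y = arcsine_transform(data["proportion"])
    return ols_fit(X, y, names, spec=spec)


def fit_quasibinomial_glm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Quasi-binomial GLM (logit link, variance mu(1-mu)) on raw proportions.

    Dispersion is Pearson chi^2 / df; coefficient tests use dispersion-scaled
    standard errors.  No AIC is defined under quasi-likelihood.
    """
    X, names = build_design(spec, data)
    y = np.asarray(data["proportion"], dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise DomainError("proportions must lie in [0, 1]")
    yc = np.clip(y, 1e-10, 1 - 1e-10)
    model = sm.GLM(yc, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:
        raise ConvergenceError(f"quasi-binomial IRLS failed: {exc}")
    if not res.converged:
        raise ConvergenceError("quasi-binomial IRLS did not converge")
    # quasi-likelihood: scale SEs by the Pearson chi^2 / df dispersion
    # (applied after the unit-scale IRLS so saturated fits stay defined)
    disp = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan
    bse = np.asarray(res.bse) * np.sqrt(max(disp, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = np.asarray(res.params) / bse
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    fitted = res.fittedvalues
    return ModelFit(
        spec=spec,
        names=list(names),
        params=np.asarray(res.params),
        bse=bse,
        tvalues=zvals,
        pvalues=pvals,
        n=len(y),
        df_resid=int(res.df_resid),
        rss=None,
        loglik=None,
        aic=None,
        r2=None,
        fstat=None,
        f_df=None,
        f_pvalue=None,
        dispersion=disp,
        fitted=np.asarray(fitted),
        residuals=y - np.asarray(fitted),
        response=y,
    )


def enumerate_candidates(
    mode: str,
    best_climate: ModelSpec | None = None,
    best_hominin: ModelSpec | None = None,
) -> list[ModelSpec]:
    """Candidate model specs for one comparison family.

    climate: every non-empty subset of the four climate scores that never
    pairs the anomaly and velocity of one variable (8 specs).  hominin: the
    three codings (lumped 3-level, full 5-level, arrival-time covariate).
    combined: the best-hominin coding plus every subset of the best-climate
    terms, with and without hominin x climate interactions.
    """
    if mode == "climate":
        specs = []
        for r in (1, 2, 3, 4):
            for sub in combinations(CLIMATE_TERMS, r):
                try:
                    specs.append(ModelSpec(climate=sub))
                except InvalidConfigError:
                    continue
        return specs
    if mode == "hominin":
        return [ModelSpec(hominin=c) for c in HOMININ_CODINGS]
    if mode == "combined":
        if best_climate is None or best_hominin is None:
            raise InvalidConfigError("combined mode needs the best climate and hominin specs")
        terms = best_climate.climate
        specs = []
        for r in range(len(terms) + 1):
            for sub in combinations(terms, r):
                specs.append(ModelSpec(climate=sub, hominin=best_hominin.hominin))
                if sub:
                    specs.append(
                        ModelSpec(
                            climate=sub,
                            hominin=best_hominin.hominin,
                            interactions=sub,
                        )
                    )
        return specs
    raise InvalidConfigError(f"unknown mode {mode!r}")


def aic_select(fits: list[ModelFit]) -> tuple[ModelFit, pd.DataFrame]:
    """Minimum-AIC fit plus the ranked table; AIC ties favour fewer parameters."""
    if not fits:
        raise InvalidConfigError("no fits to select from")
    y0 = fits[0].response
    for f in fits[1:]:
        if len(f.response) != len(y0) or not np.allclose(f.response, y0):
            raise ComparisonError("fits do not share a response vector")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, len(fits[i].params)))
    ranked = pd.DataFrame(
        {
            "model": [fits[i].spec.label() if fits[i].spec else "?" for i in order],
            "k": [len(fits[i].params) for i in order],
            "aic": [fits[i].aic for i in order],
        }
    )
    ranked["delta_aic"] = ranked["aic"] - ranked["aic"].iloc[0]
    return fits[order[0]], ranked


def f_test_nested(fit_small: ModelFit, fit_big: ModelFit) -> tuple[float, float, tuple[int, int]]:
    """Partial F-test of a nested pair sharing one response vector."""
    if not set(fit_small.names) <= set(fit_big.names):
        raise NestingError("smaller model's terms are not a subset of the larger's")
    if len(fit_small.response) != len(fit_big.response) or not np.allclose(
        fit_small.response, fit_big.response
    ):
        raise NestingError("fits do not share a response vector")
    dk = len(fit_big.params) - len(fit_small.params)
    if dk == 0:
        return 0.0, 1.0, (0, fit_big.df_resid)
    num = (fit_small.rss - fit_big.rss) / dk
    den = fit_big.rss / fit_big.df_resid
    F = num / den
    p = float(stats.f.sf(F, dk, fit_big.df_resid))
    return float(F), p, (dk, fit_big.df_resid)


def lump_hominin_categories(
    data: pd.DataFrame, alpha: float = 0.05
) -> list[tuple[str, ...]]:
    """Merge adjacent hominin categories whose contrast is non-significant.

    The five classes are ordered by length of hominin co-occurrence.  Group
    means are fitted on the arcsine scale; each pass tests every
    adjacent-group contrast and merges all pairs with p > alpha at once
    (chains collapse together), iterating to a fixpoint.  Returns the final
    partition as ordered tuples.
    """
    counts = data["hominin_class"].value_counts()
    present = [c for c in HOMININ_CLASSES if c in counts.index]
    for c in present:
        if counts[c] < 2:
            raise SparseCategoryError(f"category {c!r} has {counts[c]} region(s)")
    y = arcsine_transform(data["proportion"])
    cls = data["hominin_class"].to_numpy()
    groups: list[tuple[str, ...]] = [(c,) for c in present]
    while len(groups) > 1:
        G = np.column_stack(
            [np.isin(cls, g).astype(float) for g in groups]
        )
        n_g = G.sum(axis=0)
        means = (G.T @ y) / n_g
        resid = y - G @ means
        df = len(y) - len(groups)
        s2 = float(resid @ resid) / df
        pvals = []
        for j in range(len(groups) - 1):
            se = np.sqrt(s2 * (1 / n_g[j] + 1 / n_g[j + 1]))
            t = (means[j + 1] - means[j]) / se
            pvals.append(2 * stats.t.sf(abs(t), df))
        merge = [p > alpha for p in pvals]
        if not any(merge):
            break
        new_groups = [groups[0]]
        for j in range(1, len(groups)):
            if merge[j - 1]:
                new_groups[-1] = new_groups[-1] + groups[j]
            else:
                new_groups.append(groups[j])
        groups = new_groups
    return groups
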