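"""Potential extant richness at minimal human impact, and extinction proportions.

Current extant large-mammal richness reflects losses of the last millennium,
so per-continent quasi-binomial models (logit link, variance mu(1-mu)) relate
large richness — expressed as a fraction of the regional large+small species
pool — to small-mammal richness and a human-impact index.  Where impact is a
significant predictor, richness is re-predicted at the continent's lowest
recorded impact; elsewhere the observed value stands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    ConvergenceError,
    InvalidConfigError,
    RangeError,
    UndefinedProportionError,
)
from .synthetic import round_half_up

DEFAULT_ALPHA = 0.10  # impact-significance gate for applying the correction


@dataclass
class QuasiLogitFit:
    """Per-continent quasi-binomial richness model."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    dispersion: float
    continent: object
    impact_range: tuple[float, float]
    dropped: list

    def predict_fraction(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.params["const"])
        for name, b in self.params.items():
            if name != "const":
                eta = eta + b * table[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_extant_model(
    table: pd.DataFrame,
    continent,
    predictors: tuple[str, ...] = ("small_richness", "human_impact"),
) -> QuasiLogitFit:
    """Quasi-binomial GLM of large richness as a pool fraction, per continent.

    Response: extant_large / (extant_large + small_richness), fitted by IRLS
    with logit link and variance mu(1-mu); dispersion from Pearson chi^2/df.
    Zero-variance predictors are dropped with a warning.
    """
    sub = table[table["continent"] == continent]
    if len(sub) < 5:
        raise InvalidConfigError(
            f"continent {continent!r} has {len(sub)} regions; need >= 5"
        )
    pool = sub["extant_large"] + sub["small_richness"]
    if (pool <= 0).any():
        raise InvalidConfigError("regional species pool must be positive")
    frac = (sub["extant_large"] / pool).clip(1e-6, 1 - 1e-6)

    dropped = []
    cols = []
    for pcol in predictors:
        if sub[pcol].nunique() <= 1:
            warnings.warn(f"predictor {pcol!r} has zero variance; dropped")
            dropped.append(pcol)
        else:
            cols.append(pcol)
    X = sm.add_constant(sub[cols].astype(float), has_constant="add")
    model = sm.GLM(frac.to_numpy(), X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:
        raise ConvergenceError(f"IRLS failed for continent {continent!r}: {exc}")
    if not res.converged:
        raise ConvergenceError(
            f"IRLS did not converge for continent {continent!r}",
            trace=list(getattr(res, "fit_history", {}).get("deviance", [])),
        )
    # quasi-family dispersion: Pearson chi^2 / df, applied to the SEs
    disp = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan
    bse = res.bse * np.sqrt(max(disp, 0.0))
    from scipy import stats as _st

    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = res.params / bse
    pvals = pd.Series(2 * _st.norm.sf(np.abs(zvals)), index=res.params.index)
    return QuasiLogitFit(
        params=res.params,
        bse=bse,
        pvalues=pvals,
        dispersion=disp,
        continent=continent,
        impact_range=(
            float(sub["human_impact"].min()),
            float(sub["human_impact"].max()),
        ),
        dropped=dropped,
    )


def estimate_potential_richness(
    fit: QuasiLogitFit,
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_impact: float | None = None,
) -> pd.Series:
    """Estimated extant richness per region of the fit's continent.

    If the human-impact coefficient is significant at ``alpha``, richness is
    predicted with every region's impact set to the continent minimum (which
    is inside the fitted range by construction); otherwise the observed
    richness is returned unchanged.  Predictions are rounded half-up.
    """
    sub = table[table["continent"] == fit.continent].copy()
    gate_open = (
        "human_impact" in fit.params.index
        and float(fit.pvalues["human_impact"]) <= alpha
    )
    if not gate_open:
        return pd.Series(
            sub["extant_large"].to_numpy(), index=sub["region_id"], name="estimated_extant"
        )
    lo, hi = fit.impact_range
    target = lo if min_impact is None else float(min_impact)
    if not lo - 1e-12 <= target <= hi + 1e-12:
        raise RangeError(
            f"impact {target} outside fitted range [{lo}, {hi}] for {fit.continent!r}"
        )
    sub["human_impact"] = target
    frac = fit.predict_fraction(sub)
    pool = (sub["extant_large"] + sub["small_richness"]).to_numpy(dtype=float)
    est = round_half_up(frac * pool)
    return pd.Series(est, index=sub["region_id"], name="estimated_extant")


def extinction_proportion(extinct: int, estimated_extant: int) -> float:
    """extinct / (extinct + estimated_extant)."""
    if extinct < 0 or estimated_extant < 0:
        raise InvalidConfigError("counts must be nonnegative")
    if extinct + estimated_extant == 0:
        raise UndefinedProportionError("no extinct and no extant species")
    return extinct / (extinct + estimated_extant)


def build_extinction_table(
    table: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> tuple[pd.DataFrame, list]:
    """Fit per-continent models, apply the correction, form proportions.

    ``table`` needs columns region_id, continent, extinct, extant_large,
    small_richness, human_impact.  Regions with an undefined proportion are
    excluded and returned in the exclusion log (never silently dropped).
    """
    est = {}
    for cont in sorted(table["continent"].unique()):
        fit = fit_extant_model(table, cont)
        est.update(estimate_potential_richness(fit, table, alpha).to_dict())
    out = table.copy()
    out["estimated_extant"] = out["region_id"].map(est)
    excluded = []
    props = []
    for _, row in out.iterrows():
        try:
            props.append(
                extinction_proportion(int(row["extinct"]), int(row["estimated_extant"]))
            )
        except UndefinedProportionError:
            excluded.append(row["region_id"])
            props.append(np.nan)
    out["proportion_extinct"] = props
    return out[~out["proportion_extinct"].isna()].reset_index(drop=True), excluded
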