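"""Island-attribute statistics: correlations, species-area regression and
backward stepwise model selection by AIC.

All regressions follow the island-biogeography convention of a power-law
species-area relationship fitted on the log10-log10 scale:
log10(S) = b + z * log10(A). Ordinary fits are delegated to statsmodels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .community import ValidationError


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of (transformed) species richness on island attributes."""
    response: str
    terms: pd.DataFrame = field(repr=False)   # index term; estimate, se, p
    r_squared: float
    aic: float
    n: int
    transform: str = "log10"
    zero_offset: float = 0.0
    dropped_zero_sites: int = 0

    def estimate(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])

    @property
    def predictors(self) -> list[str]:
        return [t for t in self.terms.index if t != "Intercept"]


def attribute_correlations(
    attrs: pd.DataFrame,
    variables: tuple[str, ...] = ("area_ha", "isolation", "habitat_richness"),
    transform: str = "log10",
) -> pd.DataFrame:
    """Pairwise Pearson r among island variables (log10-transformed by
    default, as in the richness models)."""
    sub = attrs[list(variables)].astype(float)
    if transform == "log10":
        if (sub <= 0).any().any():
            raise ValidationError("log10 transform requires positive values")
        sub = np.log10(sub)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if (sub.std(ddof=1) == 0).any():
        raise ValidationError("constant variable: correlation undefined")
    return sub.corr(method="pearson")


def _design(
    attrs: pd.DataFrame, richness, predictors, transform, zero_offset, drop_zeros
):
    y = np.asarray(richness, dtype=float)
    X = attrs[list(predictors)].astype(float).copy()
    dropped = 0
    if drop_zeros and (y == 0).any():
        keep = y > 0
        dropped = int((~keep).sum())
        y = y[keep]
        X = X.loc[keep]
    y = y + zero_offset
    if transform == "log10":
        if (y <= 0).any():
            raise ValidationError(
                "zero richness under log10: drop empty sites or set zero_offset"
            )
        if (X <= 0).any().any():
            raise ValidationError("log10 transform requires positive predictors")
        y = np.log10(y)
        X = np.log10(X)
    if len(y) < len(predictors) + 2:
        raise ValidationError("too few islands for the requested model")
    return y, X, dropped


def species_area_regression(
    richness,
    attrs: pd.DataFrame,
    predictors: tuple[str, ...] = ("area_ha",),
    transform: str = "log10",
    zero_offset: float = 0.0,
    drop_zeros: bool = False,
    response_name: str = "richness",
) -> RegressionResult:
    """OLS of log10(richness + zero_offset) on log10 predictors.

    Sites with zero richness are either excluded (``drop_zeros=True``, the
    treatment matching taxa absent from some islands) or lifted by an
    explicit ``zero_offset``.
    """
    y, X, dropped = _design(attrs, richness, predictors, transform,
                            zero_offset, drop_zeros)
    exog = sm.add_constant(X.to_numpy(), has_constant="add")
    fit = sm.OLS(y, exog).fit()
    terms = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "p": fit.pvalues},
        index=["Intercept"] + list(X.columns),
    )
    return RegressionResult(
        response=response_name, terms=terms, r_squared=float(fit.rsquared),
        aic=float(fit.aic), n=int(fit.nobs), transform=transform,
        zero_offset=zero_offset, dropped_zero_sites=dropped,
    )


def backward_stepwise_aic(
    richness,
    attrs: pd.DataFrame,
    candidates: tuple[str, ...] = ("area_ha", "isolation", "habitat_richness"),
    transform: str = "log10",
    zero_offset: float = 0.0,
    drop_zeros: bool = False,
    response_name: str = "richness",
) -> RegressionResult:
    """Backward elimination from the full model: at each step drop the term
    whose removal lowers AIC most; stop when no removal lowers AIC.

    The intercept is never a candidate for removal; the selection can
    terminate at the intercept-only model.
    """
    current = list(candidates)

    def fit_for(preds):
        return species_area_regression(
            richness, attrs, tuple(preds), transform=transform,
            zero_offset=zero_offset, drop_zeros=drop_zeros,
            response_name=response_name,
        ) if preds else _intercept_only(richness, attrs, transform, zero_offset,
                                        drop_zeros, response_name)

    best = fit_for(current)
    while current:
        trials = [(fit_for([p for p in current if p != drop]), drop)
                  for drop in current]
        cand, dropped = min(trials, key=lambda t: t[0].aic)
        if cand.aic < best.aic:
            best = cand
            current.remove(dropped)
        else:
            break
    return best


def _intercept_only(richness, attrs, transform, zero_offset, drop_zeros,
                    response_name):
    y, _, dropped = _design(attrs, richness, attrs.columns[:0], transform,
                            zero_offset, drop_zeros)
    fit = sm.OLS(y, np.ones((len(y), 1))).fit()
    terms = pd.DataFrame({"estimate": fit.params, "se": fit.bse,
                          "p": fit.pvalues}, index=["Intercept"])
    return RegressionResult(
        response=response_name, terms=terms, r_squared=float(fit.rsquared),
        aic=float(fit.aic), n=int(fit.nobs), transform=transform,
        zero_offset=zero_offset, dropped_zero_sites=dropped,
    )
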