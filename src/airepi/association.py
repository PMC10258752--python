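"""Regression of cumulative infection counts on repertoire metrics.

Each metric is modelled separately, always adjusted for the presence of
older siblings: a linear model on the additional-infections scale and
log-link Poisson models whose exponentiated coefficients are relative
risks per one standard deviation of the metric. Confidence intervals are
normal-approximation (Wald) 95% intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateInputError,
    FitError,
    InsufficientDataError,
    RankError,
    ValidationError,
)

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("clonality", "richness", "simpson_diversity", "shannon_bits")

_Z = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EffectEstimate:
    """One model term: point estimate with its 95% confidence interval."""

    term: str
    estimate: float
    ci_low: float
    ci_high: float
    scale: str  # "additional_infections" | "relative_risk"

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError(
                f"{self.term}: estimate {self.estimate} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )


def standardize(values) -> np.ndarray:
    """Center to mean 0 and scale to sample (ddof=1) standard deviation 1."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or np.unique(x).size < 2:
        raise DegenerateInputError(
            "standardization needs a 1-D vector with at least 2 distinct values"
        )
    return (x - x.mean()) / x.std(ddof=1)


def _outcome_column(table: pd.DataFrame, year: int) -> str:
    col = f"ari_year{year}"
    if col not in table.columns:
        raise ValidationError(f"cohort table missing outcome column {col!r}")
    return col


def _design(table: pd.DataFrame, metric: str) -> tuple[np.ndarray, list[str]]:
    """Intercept + standardized metric + older-sibling indicator.

    A constant sibling column is dropped with a warning rather than
    breaking the fit.
    """
    if metric not in table.columns:
        raise ValidationError(f"cohort table missing metric column {metric!r}")
    z = standardize(table[metric].to_numpy(dtype=float))
    sib = table["older_siblings"].to_numpy(dtype=float)
    cols = [np.ones(len(table)), z]
    names = ["intercept", metric]
    if np.unique(sib).size < 2:
        warnings.warn(
            "older_siblings is constant; sibling term dropped from the model",
            UserWarning,
            stacklevel=3,
        )
    else:
        cols.append(sib)
        names.append("older_siblings")
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankError("design matrix is rank-deficient (collinear covariates)")
    return design, names


def fit_linear_ari(
    table: pd.DataFrame, metric: str, outcome_year: int = 4
) -> list[EffectEstimate]:
    """OLS of cumulative ARI at ``outcome_year`` on the standardized metric.

    Returns effect estimates (additional infections per 1 SD of the
    metric, and for the older-sibling indicator) with Wald 95% CIs.
    """
    if len(table) < 3:
        raise InsufficientDataError(
            f"linear fit needs at least 3 subjects, got {len(table)}"
        )
    y = table[_outcome_column(table, outcome_year)].to_numpy(dtype=float)
    design, names = _design(table, metric)
    res = sm.OLS(y, design).fit()
    out = []
    for i, name in enumerate(names):
        if name == "intercept":
            continue
        se = res.bse[i]
        out.append(
            EffectEstimate(
                term=name,
                estimate=float(res.params[i]),
                ci_low=float(res.params[i] - _Z * se),
                ci_high=float(res.params[i] + _Z * se),
                scale="additional_infections",
            )
        )
    return out


def fit_poisson_ari(
    table: pd.DataFrame, metric: str, interval_ends: list[int] = (1, 2, 3, 4)
) -> dict[int, list[EffectEstimate]]:
    """Poisson fits of cumulative ARI at each interval end.

    Relative risks are exponentiated coefficients with exponentiated Wald
    95% CIs; one fit per interval. Overdispersion is not modelled, but
    the Pearson dispersion is logged for information.
    """
    if len(table) < 3:
        raise InsufficientDataError(
            f"Poisson fit needs at least 3 subjects, got {len(table)}"
        )
    results: dict[int, list[EffectEstimate]] = {}
    for year in interval_ends:
        y = table[_outcome_column(table, year)].to_numpy(dtype=float)
        if np.any(y < 0):
            raise ValidationError(f"negative counts in year {year}")
        if np.all(y == 0):
            raise FitError(f"all counts are zero for interval ending year {year}")
        design, names = _design(table, metric)
        try:
            res = sm.GLM(y, design, family=sm.families.Poisson()).fit()
        except Exception as exc:  # perfect separation, singularities, ...
            raise FitError(f"Poisson fit failed for year {year}: {exc}") from exc
        if not res.converged:
            raise FitError(f"Poisson fit did not converge for year {year}")
        dispersion = res.pearson_chi2 / res.df_resid if res.df_resid > 0 else np.nan
        logger.info(
            "poisson year %d metric %s: Pearson dispersion %.3f (quasi-Poisson scale)",
            year,
            metric,
            dispersion,
        )
        effects = []
        for i, name in enumerate(names):
            if name == "intercept":
                continue
            se = res.bse[i]
            effects.append(
                EffectEstimate(
                    term=name,
                    estimate=float(np.exp(res.params[i])),
                    ci_low=float(np.exp(res.params[i] - _Z * se)),
                    ci_high=float(np.exp(res.params[i] + _Z * se)),
                    scale="relative_risk",
                )
            )
        results[year] = effects
    return results


def metric_ari_r2(table: pd.DataFrame, metric: str, outcome_year: int = 4) -> float:
    """Squared Pearson correlation between a metric and cumulative ARI."""
    y = table[_outcome_column(table, outcome_year)].to_numpy(dtype=float)
    x = table[metric].to_numpy(dtype=float)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateInputError("correlation undefined for constant vectors")
    return float(np.corrcoef(x, y)[0, 1] ** 2)
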