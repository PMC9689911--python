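"""Ecological regression of population disease rates on expected PRS and
hormone / vitamin-D covariates.

These are ordinary least-squares fits across population-level aggregates —
typically four to six points, one per (super)population, with equal weights.
With so few points R-squared is fragile and confidence intervals are wide;
the report exists to *rank* candidate predictors (genetic score vs DHT:T
ratio vs vitamin D), not to establish effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from prscape.errors import DegenerateModelError

EPI_COLUMNS = ["population", "incidence", "mortality", "dht_t_ratio", "vit_d"]


@dataclass
class RegressionFit:
    """Simple OLS fit y = intercept + slope * x with its R-squared."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residuals: pd.Series
    predictor: str = "x"
    response: str = "y"


def fit_linear(
    x: pd.Series, y: pd.Series, predictor: str = "x", response: str = "y"
) -> RegressionFit:
    """OLS fit of ``y`` on ``x`` over the populations where both are present.

    Requires at least 3 complete points, a non-constant predictor and a
    non-constant response (SS_tot > 0); violations raise
    :class:`DegenerateModelError`.
    """
    x = pd.Series(x).astype(float)
    y = pd.Series(y).astype(float)
    both = x.notna() & y.notna()
    x, y = x[both], y[both]
    if len(x) < 3:
        raise DegenerateModelError(f"need >= 3 points, got {len(x)}")
    if np.ptp(x.to_numpy()) == 0:
        raise DegenerateModelError(f"degenerate predictor: {predictor} is constant")
    if np.ptp(y.to_numpy()) == 0:
        raise DegenerateModelError(f"degenerate response: {response} is constant")
    res = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n=int(res.nobs),
        residuals=pd.Series(res.resid, index=x.index),
        predictor=predictor,
        response=response,
    )


def predict(fit: RegressionFit, x_new: float | np.ndarray) -> float | np.ndarray:
    """Predicted rate at a new predictor value (places a held-out population,
    e.g. KOR, on the fitted line)."""
    out = fit.intercept + fit.slope * np.asarray(x_new, dtype=float)
    return float(out) if out.ndim == 0 else out


def read_epidemiology(path: str | Path) -> pd.DataFrame:
    """Read a population epidemiology TSV (population, incidence, mortality,
    optional dht_t_ratio and vit_d), indexed by population code."""
    df = pd.read_csv(path, sep="\t", dtype={"population": str})
    missing = {"population", "incidence", "mortality"} - set(df.columns)
    if missing:
        raise DegenerateModelError(f"epidemiology table missing columns {sorted(missing)}")
    for col in ("dht_t_ratio", "vit_d"):
        if col not in df.columns:
            df[col] = np.nan
    if (df[["incidence", "mortality"]] < 0).any().any():
        raise DegenerateModelError("rates must be non-negative")
    return df.set_index("population")


def covariate_report(
    epi: pd.DataFrame, prs_by_pop: Mapping[str, float]
) -> tuple[pd.DataFrame, list[str]]:
    """Fit every (predictor, response) pair and rank predictors by R-squared.

    Predictors: expected PRS, DHT:T ratio, vitamin D; responses: incidence
    and mortality. A covariate observed in fewer than 3 populations is
    skipped with a note. Returns the tidy report (sorted within each
    response by descending R-squared) and the notes.
    """
    predictors = {"PRS": pd.Series(prs_by_pop, dtype=float)}
    for col, label in (("dht_t_ratio", "DHT:T"), ("vit_d", "VitD")):
        if col in epi.columns:
            predictors[label] = epi[col].astype(float)

    rows, notes = [], []
    for label, x in predictors.items():
        for response in ("incidence", "mortality"):
            y = epi[response].astype(float)
            aligned_x = x.reindex(epi.index)
            if (aligned_x.notna() & y.notna()).sum() < 3:
                notes.append(f"{label} vs {response}: fewer than 3 populations, skipped")
                continue
            try:
                fit = fit_linear(aligned_x, y, predictor=label, response=response)
            except DegenerateModelError as exc:
                notes.append(f"{label} vs {response}: {exc}")
                continue
            rows.append(
                {
                    "predictor": label,
                    "response": response,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                }
            )
    report = pd.DataFrame(
        rows, columns=["predictor", "response", "slope", "intercept", "r_squared", "n"]
    )
    report = report.sort_values(
        ["response", "r_squared"], ascending=[True, False]
    ).reset_index(drop=True)
    return report, notes


def plot_fit(
    fit: RegressionFit,
    x: pd.Series,
    y: pd.Series,
    path: str | Path,
    holdout: Mapping[str, tuple[float, float | None]] | None = None,
) -> None:
    """Scatter of populations with the fitted line (gray dashed).

    ``holdout`` maps population -> (x, observed y or None); each held-out
    population is drawn as a filled circle at its predicted rate and, when
    observed, an open diamond at its actual rate.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    both = pd.Series(x).notna() & pd.Series(y).notna()
    x, y = pd.Series(x)[both], pd.Series(y)[both]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, color="black", zorder=3)
    for pop, xi, yi in zip(x.index, x, y):
        ax.annotate(str(pop), (xi, yi), textcoords="offset points", xytext=(4, 4))
    grid = np.linspace(float(x.min()), float(x.max()), 10)
    ax.plot(grid, fit.intercept + fit.slope * grid, "--", color="gray", zorder=2)
    if holdout:
        for pop, (xi, observed) in holdout.items():
            ax.scatter([xi], [predict(fit, xi)], color="tab:blue", zorder=4)
            ax.annotate(f"{pop} (predicted)", (xi, predict(fit, xi)),
                        textcoords="offset points", xytext=(4, -10))
            if observed is not None:
                ax.scatter([xi], [observed], facecolors="none",
                           edgecolors="tab:blue", marker="D", zorder=4)
    ax.set_xlabel(fit.predictor)
    ax.set_ylabel(f"{fit.response} (per 100,000)")
    ax.set_title(f"$R^2$ = {fit.r_squared:.3f} (n = {fit.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
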