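"""Staggered difference-in-differences estimation and loss accounting.

The economic effect of infestation is estimated by a two-way fixed-effects
panel regression

    Y_it = alpha + beta * D_it + theta' W_it + mu_i + gamma_t + eps_it

where D_it switches to 1 when district i is first recorded infested
(absorbing, staggered across districts), W_it are control covariates, and
mu_i / gamma_t are district and year intercepts. When an exposure column is
supplied (the count of treated host cells in the district), the treatment
regressor becomes D_it * exposure_i so that beta is a *per-cell* annual
effect — the treatment-intensity design appropriate when districts differ in
infested area. Standard errors are cluster-robust by district by default.

Counterfactual (uninfested) output is Y_it - beta * treatment, and the annual
loss series is the deflator-adjusted gap between counterfactual and observed
output summed over districts.

Plain TWFE is used deliberately, matching the study design; no staggered-
adoption heterogeneity correction (Callaway-Sant'Anna etc.) is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .errors import IdentificationError, InputError
from .synth import SpreadSchedule

logger = logging.getLogger(__name__)


@dataclass
class DIDFit:
    """Estimated two-way fixed-effects DID model for one sector outcome."""

    alpha: float
    beta: float
    se: float
    tstat: float
    pvalue: float
    conf_int: tuple[float, float]
    theta: dict[str, float]
    unit_effects: pd.Series
    year_effects: pd.Series
    residuals: np.ndarray
    n_obs: int
    n_units: int
    n_years: int
    cov_type: str = "cluster"
    treatment_col: str = "D"

    def summary_row(self) -> dict:
        """One row in the conventional regression-table layout."""
        return {"Estimate": self.beta, "Std. Error": self.se,
                "t Value": self.tstat, "Pr(>|t|)": self.pvalue}


def build_panel(outputs: pd.DataFrame, schedule: SpreadSchedule,
                controls: pd.DataFrame | None = None,
                exposure: Mapping[int, float] | None = None) -> pd.DataFrame:
    """Assemble PanelObservation rows from outputs and a spread schedule.

    ``outputs`` must have columns unit, year, sector, value (or y). D_it is 1
    from the unit's first infestation year onward. ``controls`` (optional) is
    merged on (unit, year); ``exposure`` attaches the per-unit treated-cell
    count used for intensity fits.
    """
    df = outputs.rename(columns={"value": "y"}).copy()
    required = {"unit", "year", "sector", "y"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"outputs missing columns {sorted(missing)}")
    sched = schedule.first_infestation_year
    unknown = set(df["unit"]) - set(sched)
    if unknown:
        raise InputError(f"units missing from schedule: {sorted(unknown)}")
    fy = df["unit"].map(
        lambda u: np.nan if sched[u] is None else float(sched[u])
    ).astype(float)
    df["D"] = (df["year"] >= fy).fillna(False).astype(int)  # NaN -> never
    if exposure is not None:
        df["exposure"] = df["unit"].map(exposure)
    if controls is not None:
        df = df.merge(controls, on=["unit", "year"], how="left")
    return df


class StaggeredDID(BaseEstimator):
    """Two-way fixed-effects DID estimator on a long panel DataFrame.

    Parameters
    ----------
    controls : sequence of str
        Names of control-covariate columns (theta coefficients).
    exposure_col : str or None
        If given, the treatment regressor is D * exposure and beta is
        per exposure unit (per treated cell); otherwise D enters binary.
    cov_type : {'cluster', 'HC1'}
        Cluster-robust by unit (default) or heteroskedasticity-robust SEs.

    ``fit(panel)`` expects columns unit, year, y, D (plus controls/exposure);
    fitted attributes: ``result_`` (a :class:`DIDFit`), ``beta_``, ``se_``.
    """

    def __init__(self, controls: Sequence[str] = (),
                 exposure_col: str | None = None,
                 cov_type: str = "cluster"):
        self.controls = controls
        self.exposure_col = exposure_col
        self.cov_type = cov_type

    def fit(self, panel: pd.DataFrame, y_col: str = "y"):
        df = panel.reset_index(drop=True)
        for col in ("unit", "year", y_col, "D"):
            if col not in df.columns:
                raise InputError(f"panel missing column {col!r}")
        if df.duplicated(["unit", "year"]).any():
            raise InputError("duplicate (unit, year) observations")
        units = pd.Categorical(df["unit"])
        years = pd.Categorical(df["year"])
        if len(units.categories) < 2 or len(years.categories) < 2:
            raise IdentificationError("need at least 2 units and 2 years")
        d = df["D"].to_numpy(dtype=float)
        if d.min() < 0 or d.max() > 1 or not np.isin(d, (0.0, 1.0)).all():
            raise InputError("D must be binary")
        if d.sum() == 0 or d.sum() == len(d):
            raise IdentificationError(
                "panel needs both treated and untreated observations")

        treat = d.copy()
        if self.exposure_col is not None:
            treat = d * df[self.exposure_col].to_numpy(dtype=float)

        # design: intercept | treatment | controls | unit dummies | year dummies
        blocks = [np.ones((len(df), 1)), treat[:, None]]
        names = ["const", "treatment"]
        kept_controls = []
        for c in self.controls:
            col = df[c].to_numpy(dtype=float)[:, None]
            cand = np.hstack(blocks + [col])
            if np.linalg.matrix_rank(cand) <= np.linalg.matrix_rank(
                    np.hstack(blocks)):
                logger.warning("dropping collinear control %r", c)
                continue
            blocks.append(col)
            names.append(c)
            kept_controls.append(c)
        unit_d = pd.get_dummies(units, drop_first=True, dtype=float)
        year_d = pd.get_dummies(years, drop_first=True, dtype=float)
        blocks += [unit_d.to_numpy(), year_d.to_numpy()]
        names += [f"unit_{c}" for c in unit_d.columns]
        names += [f"year_{c}" for c in year_d.columns]
        X = np.hstack(blocks)
        y = df[y_col].to_numpy(dtype=float)

        if self.cov_type == "cluster":
            fitted = sm.OLS(y, X).fit(
                cov_type="cluster", cov_kwds={"groups": units.codes})
        elif self.cov_type in {"HC1", "HC0", "HC2", "HC3"}:
            fitted = sm.OLS(y, X).fit(cov_type=self.cov_type)
        else:
            raise InputError(f"unknown cov_type {self.cov_type!r}")

        params = pd.Series(fitted.params, index=names)
        bse = pd.Series(fitted.bse, index=names)
        ci = fitted.conf_int()
        # recover fixed effects, centered so that both sum to zero and the
        # intercept absorbs their means
        mu_raw = pd.Series(0.0, index=units.categories, dtype=float)
        for c in unit_d.columns:
            mu_raw[c] = params[f"unit_{c}"]
        ga_raw = pd.Series(0.0, index=years.categories, dtype=float)
        for c in year_d.columns:
            ga_raw[c] = params[f"year_{c}"]
        alpha = float(params["const"] + mu_raw.mean() + ga_raw.mean())
        mu = mu_raw - mu_raw.mean()
        gamma = ga_raw - ga_raw.mean()

        k = names.index("treatment")
        self.result_ = DIDFit(
            alpha=alpha,
            beta=float(params["treatment"]),
            se=float(bse["treatment"]),
            tstat=float(fitted.tvalues[k]),
            pvalue=float(fitted.pvalues[k]),
            conf_int=(float(ci[k][0]), float(ci[k][1])),
            theta={c: float(params[c]) for c in kept_controls},
            unit_effects=mu,
            year_effects=gamma,
            residuals=np.asarray(fitted.resid),
            n_obs=len(df),
            n_units=len(units.categories),
            n_years=len(years.categories),
            cov_type=self.cov_type,
            treatment_col="treatment",
        )
        self.beta_ = self.result_.beta
        self.se_ = self.result_.se
        self.treatment_ = treat
        return self

    def predict_counterfactual(self, panel: pd.DataFrame,
                               y_col: str = "y") -> np.ndarray:
        """Counterfactual (never-treated) outcome: Y - beta * treatment."""
        d = panel["D"].to_numpy(dtype=float)
        treat = d
        if self.exposure_col is not None:
            treat = d * panel[self.exposure_col].to_numpy(dtype=float)
        return panel[y_col].to_numpy(dtype=float) - self.beta_ * treat


def fit_staggered_did(panel: pd.DataFrame, controls: Sequence[str] = (),
                      exposure_col: str | None = None,
                      cov_type: str = "cluster",
                      y_col: str = "y") -> DIDFit:
    """Fit the two-way fixed-effects DID model; see :class:`StaggeredDID`."""
    est = StaggeredDID(controls=controls, exposure_col=exposure_col,
                       cov_type=cov_type).fit(panel, y_col=y_col)
    return est.result_


def fit_by_sector(panel: pd.DataFrame, controls: Sequence[str] = (),
                  exposure_col: str | None = None,
                  cov_type: str = "cluster") -> dict[str, DIDFit]:
    """One DID fit per sector outcome in a long (unit, year, sector) panel."""
    return {str(s): fit_staggered_did(grp, controls, exposure_col, cov_type)
            for s, grp in panel.groupby("sector")}


def counterfactual_outputs(fit: DIDFit, panel: pd.DataFrame,
                           exposure_col: str | None = None,
                           y_col: str = "y") -> pd.DataFrame:
    """Attach counterfactual output Y_hat(D=0) = Y - beta * treatment.

    Untreated observations keep their observed value exactly.
    """
    df = panel.copy()
    d = df["D"].to_numpy(dtype=float)
    treat = d if exposure_col is None else (
        d * df[exposure_col].to_numpy(dtype=float))
    df["counterfactual"] = df[y_col].to_numpy(dtype=float) - fit.beta * treat
    return df


def annual_losses(panel_cf: pd.DataFrame,
                  deflator: Mapping[int, float] | None = None,
                  y_col: str = "y") -> pd.DataFrame:
    """Annual deflator-adjusted loss series per sector.

    loss_t = sum_i (counterfactual_it - observed_it) / deflator(t). With beta
    negative (output suppressed by infestation) losses are positive. Returns
    year x sector rows with observed, counterfactual, loss and cumulative
    loss columns.
    """
    if "counterfactual" not in panel_cf.columns:
        raise InputError("panel lacks a counterfactual column; run "
                         "counterfactual_outputs first")
    years = sorted(panel_cf["year"].unique())
    if deflator is not None:
        missing = [t for t in years if int(t) not in deflator]
        if missing:
            raise InputError(f"deflator missing years {missing}")
        if any(deflator[int(t)] <= 0 for t in years):
            raise InputError("deflator indices must be positive")
    group_cols = ["year", "sector"] if "sector" in panel_cf.columns else ["year"]
    agg = (panel_cf.groupby(group_cols)[[y_col, "counterfactual"]]
           .sum().reset_index()
           .rename(columns={y_col: "observed"}))
    defl = agg["year"].map(lambda t: deflator[int(t)] if deflator else 1.0)
    agg["loss"] = (agg["counterfactual"] - agg["observed"]) / defl
    sort_cols = (["sector", "year"] if "sector" in agg.columns else ["year"])
    agg = agg.sort_values(sort_cols).reset_index(drop=True)
    if "sector" in agg.columns:
        agg["cumulative_loss"] = agg.groupby("sector")["loss"].cumsum()
    else:
        agg["cumulative_loss"] = agg["loss"].cumsum()
    return agg
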