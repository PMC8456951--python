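"""Per-season multivariate regression of ilr coordinates on the environment.

The D−1 ilr coordinates of each sample are regressed jointly on
environmental covariates (temperature, weekly averaged light, nutrients)
within each season.  Variables enter by forward selection: at every step
the candidate whose partial Wilks' Λ — det(E_full)/det(E_reduced) for the
model with versus without that variable — has the smallest F-approximation
p-value is added while p < alpha.  Fitted coefficient rows are mapped back
to the simplex with the inverse ilr, where a slope composition reads as
the perturbation applied per unit increase of its covariate (the uniform
composition 1/D means "no effect").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .balances import SBP, ilr_inverse
from .geometry import Composition, CompositionMatrix, center
from .preprocess import SEASONS, assign_season

__all__ = [
    "ENV_COLUMNS",
    "StepRecord",
    "RegressionFit",
    "FittedSeries",
    "weekly_average_light",
    "fit_multivariate",
    "wilks_lambda",
    "rao_f",
    "forward_select",
    "fit_season_models",
    "backtransform_params",
    "predict_composition",
    "predict_series",
    "monthly_center",
]

logger = logging.getLogger(__name__)

#: Canonical covariate column names (units: °C; MJ m⁻² d⁻¹; μM for nutrients).
ENV_COLUMNS = (
    "temperature",
    "weekly_light",
    "nitrate_nitrite",
    "phosphate",
    "ammonium",
    "silicate",
)


def weekly_average_light(daily_light: pd.Series, sample_date) -> tuple[float, int]:
    """Mean incident radiation over the 7 days before a sampling date.

    The window runs from ``date − 7`` through ``date − 1`` (the sampling
    day itself is excluded).  Missing days are tolerated: the mean runs
    over the available days and their count is returned so callers can
    flag thin windows (fewer than 4 of 7 days); an empty window yields
    NaN.
    """
    d = pd.Timestamp(sample_date).normalize()
    idx = pd.to_datetime(daily_light.index)
    mask = (idx >= d - pd.Timedelta(days=7)) & (idx <= d - pd.Timedelta(days=1))
    window = daily_light[mask].dropna()
    if len(window) == 0:
        return float("nan"), 0
    if len(window) < 4:
        logger.warning("weekly light window before %s has only %d day(s)",
                       d.date(), len(window))
    return float(window.mean()), int(len(window))


def _design(Xp: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(Xp)), Xp.to_numpy(dtype=float)])


def _check_design(Xp: pd.DataFrame) -> None:
    if Xp.isna().any().any():
        bad = list(Xp.columns[Xp.isna().any()])
        raise ValueError(f"missing covariate values in column(s): {bad}")
    M = _design(Xp)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # name the offending columns by incremental rank growth
        culprits = []
        r = 1
        for j, col in enumerate(Xp.columns):
            r_new = np.linalg.matrix_rank(M[:, : j + 2])
            if r_new == r:
                culprits.append(col)
            r = r_new
        raise ValueError(f"rank-deficient design; collinear column(s): {culprits}")


def fit_multivariate(
    Y: pd.DataFrame, Xp: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Least-squares multivariate linear model of Y (n×p) on Xp (n×q).

    An intercept is always included.  Returns the (q+1)×p coefficient
    frame, the residual sums-of-squares-and-cross-products matrix E, and
    the residual degrees of freedom n − q − 1.
    """
    n, p = Y.shape
    q = Xp.shape[1]
    if n <= q + p:
        raise ValueError(
            f"too few samples (n={n}) for q={q} predictors and p={p} responses"
        )
    _check_design(Xp)
    M = _design(Xp)
    Yv = Y.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(M, Yv, rcond=None)
    resid = Yv - M @ beta
    E = resid.T @ resid
    coef = pd.DataFrame(
        beta, index=["intercept", *Xp.columns], columns=list(Y.columns)
    )
    return coef, E, n - q - 1


@dataclass(frozen=True)
class StepRecord:
    """One hypothesis test: Wilks' Λ with its F approximation."""

    variable: str
    wilks_lambda: float
    F: float
    df1: int
    df2: float
    p_value: float
    method: str = "partial"


def wilks_lambda(
    E_full: np.ndarray, E_reduced: np.ndarray, p: int, nu_E: int
) -> StepRecord:
    """Partial Wilks' Λ test for a single added predictor.

    Λ = det(E_full) / det(E_reduced); for one added variable the exact
    transform F = ((1 − Λ)/Λ) · (ν_E − p + 1)/p follows an
    F(p, ν_E − p + 1) distribution, where ν_E is the residual df of the
    full model and p the number of responses.
    """
    if nu_E <= p - 1:
        raise ValueError("insufficient residual degrees of freedom")
    sign_f, logdet_f = np.linalg.slogdet(E_full)
    sign_r, logdet_r = np.linalg.slogdet(E_reduced)
    if sign_r <= 0:
        raise ValueError("singular reduced-model SSCP matrix")
    # a singular full-model E means a perfect fit: lambda = 0
    lam = float(np.exp(logdet_f - logdet_r)) if sign_f > 0 else 0.0
    lam = min(lam, 1.0)
    df1, df2 = p, nu_E - p + 1
    if lam == 1.0:
        F = 0.0
    elif lam == 0.0:
        F = float("inf")
    else:
        F = (1.0 - lam) / lam * df2 / df1
    pval = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return StepRecord("", lam, float(F), df1, float(df2), pval)


def rao_f(lam: float, p: int, q: int, nu_E: int) -> StepRecord:
    """Rao's F approximation for an overall Wilks' Λ with q hypothesis df."""
    pq = p * q
    denom = p * p + q * q - 5
    t = np.sqrt((pq * pq - 4) / denom) if denom > 0 else 1.0
    w = nu_E + q - (p + q + 1) / 2.0
    df2 = w * t - (pq - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    if lam_t == 0.0:
        F = float("inf")
    elif lam_t == 1.0:
        F = 0.0
    else:
        F = (1.0 - lam_t) / lam_t * df2 / pq
    pval = float(stats.f.sf(F, pq, df2)) if np.isfinite(F) else 0.0
    return StepRecord("full model", float(lam), float(F), pq, float(df2), pval, "rao")


@dataclass
class RegressionFit:
    """A fitted per-season model with its selection bookkeeping."""

    season: str
    selected: list[str]
    coef: pd.DataFrame  # (q+1) × (D−1), index: intercept + variables
    E: np.ndarray
    n: int
    residual_df: int
    steps: list[StepRecord] = field(default_factory=list)
    overall: StepRecord | None = None
    alpha: float = 0.05
    not_selected: list[StepRecord] = field(default_factory=list)

    def to_report(self, sbp: SBP | None = None) -> dict:
        """JSON-ready summary; includes simplex parameters when given an SBP."""
        rep = {
            "season": self.season,
            "n": self.n,
            "alpha": self.alpha,
            "selected": list(self.selected),
            "overall": None
            if self.overall is None
            else {
                "wilks_lambda": self.overall.wilks_lambda,
                "F": self.overall.F,
                "df": [self.overall.df1, self.overall.df2],
                "p_value": self.overall.p_value,
                "method": self.overall.method,
            },
            "steps": [
                {
                    "variable": s.variable,
                    "wilks_lambda": s.wilks_lambda,
                    "F": s.F,
                    "df": [s.df1, s.df2],
                    "p_value": s.p_value,
                }
                for s in self.steps
            ],
            "coefficients": {
                row: dict(vals) for row, vals in self.coef.round(6).iterrows()
            },
            "nearly_significant": [
                {"variable": s.variable, "wilks_lambda": s.wilks_lambda,
                 "p_value": s.p_value}
                for s in self.not_selected
            ],
        }
        if sbp is not None:
            params = backtransform_params(self, sbp)
            rep["parameter_compositions"] = {
                row: dict(vals) for row, vals in params.round(4).iterrows()
            }
        return rep


def forward_select(
    Y: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    season: str = "",
) -> RegressionFit:
    """Forward stepwise selection by partial Wilks' Λ.

    Starting from the intercept-only model, each round tests every
    remaining candidate via its partial Λ against the current model and
    admits the one with the smallest p-value while p < alpha.  The
    per-step records reproduce the "added significance" bookkeeping of a
    stepwise MANOVA table; the overall test of the final model uses
    Rao's F approximation (labelled in the report).
    """
    n, p = Y.shape
    Yv = Y.to_numpy(dtype=float)
    Yc = Yv - Yv.mean(axis=0)
    E0 = Yc.T @ Yc  # intercept-only error SSCP
    selected: list[str] = []
    E_red = E0
    steps: list[StepRecord] = []
    not_selected: list[StepRecord] = []
    remaining = list(candidates.columns)
    while remaining:
        trial: list[StepRecord] = []
        fits = {}
        for var in remaining:
            Xp = candidates[selected + [var]]
            try:
                coef, E_full, nu_E = fit_multivariate(Y, Xp)
                # E_red singular means the current model already fits
                # perfectly; no further candidate can be assessed
                rec = wilks_lambda(E_full, E_red, p, nu_E)
            except ValueError:
                continue
            rec = StepRecord(var, rec.wilks_lambda, rec.F, rec.df1, rec.df2,
                             rec.p_value)
            trial.append(rec)
            fits[var] = (coef, E_full)
        if not trial:
            break
        best = min(trial, key=lambda r: (r.p_value, remaining.index(r.variable)))
        if best.p_value < alpha:
            selected.append(best.variable)
            remaining.remove(best.variable)
            E_red = fits[best.variable][1]
            steps.append(best)
        else:
            # record the nearest misses so "nearly significant" covariates
            # (e.g. silicate, ammonium) surface in the report
            not_selected = sorted(trial, key=lambda r: r.p_value)[:2]
            break

    if selected:
        coef, E, nu_E = fit_multivariate(Y, candidates[selected])
        try:
            overall_lam_rec = wilks_lambda(E, E0, p, nu_E)
            overall = rao_f(overall_lam_rec.wilks_lambda, p, len(selected), nu_E)
        except ValueError:  # degenerate (e.g. noiseless) response matrix
            overall = None
    else:
        coef = pd.DataFrame(
            Yv.mean(axis=0)[None, :], index=["intercept"], columns=list(Y.columns)
        )
        E, nu_E = E0, n - 1
        overall = None
    return RegressionFit(
        season=season,
        selected=selected,
        coef=coef,
        E=E,
        n=n,
        residual_df=nu_E,
        steps=steps,
        overall=overall,
        alpha=alpha,
        not_selected=not_selected,
    )


def fit_season_models(
    Y: pd.DataFrame,
    env: pd.DataFrame,
    dates: pd.Series,
    alpha: float = 0.05,
    variables: Sequence[str] | None = None,
) -> dict[str, RegressionFit]:
    """Fit one model per season.

    With ``variables`` given (e.g. ``["temperature"]``) the listed
    covariates are fitted directly as a restricted model — no selection;
    otherwise forward selection runs over all complete env columns.
    Samples with a missing value in any candidate covariate are dropped
    from that season's fit (logged).
    """
    fits: dict[str, RegressionFit] = {}
    seasons = pd.Series([assign_season(d) for d in dates], index=dates.index)
    cols = list(variables) if variables is not None else list(env.columns)
    for season in SEASONS:
        ids = seasons.index[seasons == season]
        ids = [i for i in ids if i in Y.index and i in env.index]
        Xs = env.loc[ids, cols]
        complete = ~Xs.isna().any(axis=1)
        if (~complete).any():
            logger.info("season %s: dropping %d sample(s) with missing covariates",
                        season, int((~complete).sum()))
        ids = list(Xs.index[complete])
        if len(ids) == 0:
            logger.warning("season %s: no usable samples", season)
            continue
        Ys, Xs = Y.loc[ids], Xs.loc[ids]
        if variables is not None:
            coef, E, nu_E = fit_multivariate(Ys, Xs)
            Yc = Ys.to_numpy() - Ys.to_numpy().mean(axis=0)
            try:
                lam = wilks_lambda(E, Yc.T @ Yc, Y.shape[1], nu_E)
                overall = rao_f(lam.wilks_lambda, Y.shape[1], Xs.shape[1], nu_E)
            except ValueError:  # degenerate (e.g. noiseless) response matrix
                overall = None
            fits[season] = RegressionFit(
                season=season, selected=list(Xs.columns), coef=coef, E=E,
                n=len(ids), residual_df=nu_E, steps=[], overall=overall,
                alpha=alpha,
            )
        else:
            fits[season] = forward_select(Ys, Xs, alpha=alpha, season=season)
    return fits


def backtransform_params(fit: RegressionFit, sbp: SBP) -> pd.DataFrame:
    """Map each coefficient row to the simplex with the inverse ilr.

    The intercept row becomes the expected composition at zero covariates;
    each slope row becomes the perturbation applied per unit increase of
    its covariate.  A zero row maps to the uniform composition.
    """
    comps = ilr_inverse(fit.coef.to_numpy(dtype=float), sbp)
    return pd.DataFrame(comps, index=fit.coef.index, columns=list(sbp.labels))


def predict_composition(
    fit: RegressionFit, env_row: Mapping[str, float], sbp: SBP
) -> Composition:
    """Fitted composition at one covariate setting."""
    y = fit.coef.loc["intercept"].to_numpy(dtype=float).copy()
    for var in fit.selected:
        y += fit.coef.loc[var].to_numpy(dtype=float) * float(env_row[var])
    return ilr_inverse(y, sbp)


@dataclass
class FittedSeries:
    """Per-sample fitted compositions plus ilr-space residual norms."""

    compositions: pd.DataFrame  # n × D, rows sum to 1
    residual_norms: pd.Series  # NaN where no observation was supplied
    skipped: list[str]


def predict_series(
    fits: Mapping[str, RegressionFit],
    env: pd.DataFrame,
    dates: pd.Series,
    sbp: SBP,
    observed: pd.DataFrame | None = None,
) -> FittedSeries:
    """Apply each sample's season model across a time series.

    Samples whose season has no fit or whose selected covariates are
    missing are skipped (and listed).  When observed ilr coordinates are
    supplied, residual norms (Aitchison distance between fit and
    observation) are reported.
    """
    rows, ids, resid = [], [], []
    skipped: list[str] = []
    for sid in env.index:
        season = assign_season(dates.loc[sid])
        fit = fits.get(season)
        if fit is None:
            skipped.append(sid)
            continue
        vals = env.loc[sid, fit.selected] if fit.selected else pd.Series(dtype=float)
        if fit.selected and vals.isna().any():
            logger.info("skipping %s: missing covariate for season model", sid)
            skipped.append(sid)
            continue
        yhat = fit.coef.loc["intercept"].to_numpy(dtype=float).copy()
        for var in fit.selected:
            yhat += fit.coef.loc[var].to_numpy(dtype=float) * float(vals[var])
        rows.append(ilr_inverse(yhat, sbp).parts)
        ids.append(sid)
        if observed is not None and sid in observed.index:
            resid.append(
                float(np.linalg.norm(observed.loc[sid].to_numpy(dtype=float) - yhat))
            )
        else:
            resid.append(float("nan"))
    comp = pd.DataFrame(rows, index=ids, columns=list(sbp.labels))
    return FittedSeries(comp, pd.Series(resid, index=ids), skipped)


def monthly_center(X: CompositionMatrix) -> pd.DataFrame:
    """Center composition of the samples of each calendar month (across years)."""
    months = X.dates.dt.month
    out = {}
    for m in range(1, 13):
        ids = X.data.index[months == m]
        if len(ids) == 0:
            logger.info("no samples in month %d", m)
            continue
        sub = CompositionMatrix(X.data.loc[ids], X.dates.loc[ids])
        out[m] = center(sub).parts
    return pd.DataFrame(out, index=list(X.labels)).T
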