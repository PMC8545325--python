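"""Longitudinal statistics on filtered miRNA-mRNA pairs.

Short time courses make correlation and regression statistics unstable, so
every operation here runs a time-point guard first: fewer than three time
points is a hard error, fewer than five a warning (the analysis proceeds
but estimates may be overestimated).

Conventions, fixed and tested:

* Cross-correlation: ccf(l) = sum_t (x_t - xbar)(y_{t+l} - ybar) / (T sx sy)
  with full-series means and population (divisor-T) standard deviations —
  the classical sample CCF.  Under this normalization ccf(0) equals the
  Pearson correlation exactly, because the T in the divisor cancels the T
  in the population sds.  A positive lag means the mRNA series trails
  (is shifted later than) the miRNA series.
* Pair odds ratio: a single-predictor OLS of mRNA on miRNA values; the
  odds ratio is exp(slope) with Wald 95% CI exp(slope +/- 1.96 SE).  This
  treats the regression coefficient as a log-odds-style effect size for
  the pair — an unusual but deliberate convention for ranking pair
  strength; it is not a probability model.
* Splines are natural cubic interpolants (they pass through the points).
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

MIN_TIME_POINTS_ERROR = 3  # below this: hard error
MIN_TIME_POINTS_WARN = 5  # below this: warning, analysis proceeds

OK, WARN, ERROR = "ok", "warn", "error"


class TimePointError(ValueError):
    """Raised when a series has too few time points for longitudinal stats."""


class TimePointWarning(UserWarning):
    pass


class PairAnalysisError(ValueError):
    pass


def guard_time_points(T: int) -> str:
    """Classify a time-course length: 'error' (<3), 'warn' (<5) or 'ok'."""
    if T < MIN_TIME_POINTS_ERROR:
        return ERROR
    if T < MIN_TIME_POINTS_WARN:
        return WARN
    return OK


def _enforce_guard(T: int, where: str) -> str:
    state = guard_time_points(T)
    if state == ERROR:
        raise TimePointError(
            f"{where}: {T} time points detected; at least {MIN_TIME_POINTS_ERROR} required"
        )
    if state == WARN:
        msg = (
            f"{where}: only {T} time points; statistics from fewer than "
            f"{MIN_TIME_POINTS_WARN} time points may be overestimated"
        )
        logger.warning(msg)
        _warnings.warn(msg, TimePointWarning, stacklevel=3)
    return state


@dataclass(frozen=True)
class PairSeries:
    """One miRNA-mRNA pair's aligned value vectors over the time course."""

    mirna_label: str
    mrna_label: str
    x: np.ndarray  # miRNA values
    y: np.ndarray  # mRNA values
    time_points: tuple[str, ...] = ()
    scaled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise PairAnalysisError("x and y must be 1-D vectors of equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise PairAnalysisError("pair series must be finite")

    @property
    def T(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary for pair / multi-predictor longitudinal regression."""

    response_label: str
    predictor_labels: tuple[str, ...]
    coefficients: pd.DataFrame  # index: const + predictors; columns: coef, se
    r_squared: float
    p_value: float
    fitted_trajectory: np.ndarray
    odds_ratio: float | None = None
    ci95: tuple[float, float] | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def display(self) -> dict:
        """Rounded-to-2-decimals values for plot annotation."""
        out = {"R2": round(self.r_squared, 2), "p": round(self.p_value, 2)}
        if self.odds_ratio is not None:
            out["OR"] = round(self.odds_ratio, 2)
            out["CI95"] = (round(self.ci95[0], 2), round(self.ci95[1], 2))
        return out


def cross_correlation(pair: PairSeries, max_lag: int) -> pd.DataFrame:
    """Sample CCF of the pair over lags -max_lag..+max_lag.

    Positive lag: the mRNA series (y) trails the miRNA series (x); the
    lag-l term pairs x_t with y_{t+l}.  Normalization: full-series means
    and population sds with divisor T, so ccf(0) is exactly Pearson r.
    """
    _enforce_guard(pair.T, "cross_correlation")
    T = pair.T
    if max_lag > T - 2:
        raise PairAnalysisError(f"max_lag must be <= T-2 = {T - 2}, got {max_lag}")
    x, y = pair.x, pair.y
    sx, sy = x.std(), y.std()  # population convention
    if sx == 0 or sy == 0:
        raise PairAnalysisError("zero-variance series; cross-correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    rows = []
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            s = float(np.sum(xc[: T - lag] * yc[lag:]))
        else:
            s = float(np.sum(xc[-lag:] * yc[: T + lag]))
        rows.append({"lag": lag, "ccf": s / (T * sx * sy)})
    return pd.DataFrame(rows)


def scaled_spline_series(pair: PairSeries, points: int = 100, out=None) -> dict:
    """Standardize both series and interpolate with natural cubic splines.

    Returns the uniform evaluation grid, both interpolated curves, and the
    unscaled-data Pearson correlation both raw and rounded to 2 decimals
    for plot annotation.  The splines interpolate: evaluated at the
    original time points they reproduce the standardized data exactly.
    """
    _enforce_guard(pair.T, "scaled_spline_series")
    t = np.arange(pair.T, dtype=float)
    corr = float(np.corrcoef(pair.x, pair.y)[0, 1])

    def scale(v):
        return (v - v.mean()) / v.std()

    xs, ys = scale(pair.x), scale(pair.y)
    grid = np.linspace(t[0], t[-1], points)
    cx = CubicSpline(t, xs, bc_type="natural")
    cy = CubicSpline(t, ys, bc_type="natural")
    result = {
        "grid": grid,
        "mirna_curve": cx(grid),
        "mrna_curve": cy(grid),
        "mirna_scaled": xs,
        "mrna_scaled": ys,
        "correlation": corr,
        "annotation": f"{corr:.2f}",
    }
    if out is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(grid, result["mirna_curve"], color="#1f77b4", label=pair.mirna_label)
        ax.plot(grid, result["mrna_curve"], color="#d62728", label=pair.mrna_label)
        ax.plot(t, xs, "o", color="#1f77b4")
        ax.plot(t, ys, "o", color="#d62728")
        if pair.time_points:
            ax.set_xticks(t, pair.time_points)
        ax.set_ylabel("scaled value")
        ax.legend()
        ax.set_title(f"correlation = {result['annotation']}")
        fig.tight_layout()
        fig.savefig(out, dpi=100)
        plt.close(fig)
    return result


def regress_multi(
    response: np.ndarray,
    predictors: dict[str, np.ndarray],
    response_label: str = "response",
) -> RegressionFit:
    """OLS of one gene's trajectory on any number of its binding partners.

    Intercept included; reports R-squared, the overall F-test p-value, the
    coefficient table and the fitted trajectory.  Exactly collinear
    predictors are a hard error naming the offending pair.
    """
    y = np.asarray(response, dtype=float)
    T = len(y)
    _enforce_guard(T, "regress_multi")
    names = list(predictors)
    if not names:
        raise PairAnalysisError("at least one predictor is required")
    if len(names) > T - 2:
        raise PairAnalysisError(
            f"{len(names)} predictors with {T} time points leaves no degrees of freedom"
        )
    X = np.column_stack([np.asarray(predictors[n], dtype=float) for n in names])
    if X.shape[0] != T:
        raise PairAnalysisError("predictor length does not match response length")
    # pairwise exact-collinearity check with an informative message
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            xi, xj = X[:, i], X[:, j]
            if np.std(xi) > 0 and np.std(xj) > 0:
                r = np.corrcoef(xi, xj)[0, 1]
                if abs(r) > 1 - 1e-12:
                    raise PairAnalysisError(
                        f"predictors {names[i]!r} and {names[j]!r} are collinear"
                    )
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise PairAnalysisError("design matrix is rank-deficient (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    coefs = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse}, index=["const", *names]
    )
    p_value = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    return RegressionFit(
        response_label=response_label,
        predictor_labels=tuple(names),
        coefficients=coefs,
        r_squared=float(fit.rsquared),
        p_value=p_value,
        fitted_trajectory=np.asarray(fit.fittedvalues),
    )


def pair_odds_ratio(pair: PairSeries) -> RegressionFit:
    """Single-pair OLS of mRNA on miRNA with odds ratio and Wald 95% CI.

    OR = exp(slope); CI = exp(slope -/+ 1.96 SE).  A perfect fit has SE 0,
    so the CI collapses to the OR itself; the fit is flagged "exact fit".
    Values are rounded to 2 decimals only at display time.
    """
    _enforce_guard(pair.T, "pair_odds_ratio")
    if pair.x.std() == 0:
        raise PairAnalysisError("zero-variance miRNA series; regression undefined")
    design = sm.add_constant(pair.x)
    fit = sm.OLS(pair.y, design).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    flags: tuple[str, ...] = ()
    if not np.isfinite(se) or se == 0 or fit.rsquared > 1 - 1e-12:
        se = 0.0 if not np.isfinite(se) else se
        flags = ("exact fit",)
    odds_ratio = float(np.exp(slope))
    ci = (float(np.exp(slope - 1.96 * se)), float(np.exp(slope + 1.96 * se)))
    coefs = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse}, index=["const", pair.mirna_label]
    )
    p_value = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    return RegressionFit(
        response_label=pair.mrna_label,
        predictor_labels=(pair.mirna_label,),
        coefficients=coefs,
        r_squared=float(fit.rsquared),
        p_value=p_value,
        fitted_trajectory=np.asarray(fit.fittedvalues),
        odds_ratio=odds_ratio,
        ci95=ci,
        flags=flags,
    )


def order_pairs_heatmap(source, de=None, value: str = "log2fc", out=None) -> dict:
    """Interacting pairs sorted by descending correlation, plus heatmap data.

    ``source`` is an InteractionMatrix or InteractionNetwork.  Ties break
    by (miRNA, mRNA) lexicographic order.  When ``de`` is given, the
    returned matrix holds each pair's concatenated miRNA/mRNA trajectories
    for rendering.
    """
    pairs = []
    if hasattr(source, "edges"):  # network
        for m, g, d in source.edges:
            pairs.append((m, g, float(d["corr"])))
    else:  # matrix
        for m in source.mirnas:
            for g in source.mrnas:
                c = source.corr.loc[m, g]
                if pd.notna(c):
                    pairs.append((m, g, float(c)))
    if not pairs:
        logger.warning("no pairs to order")
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    heat = None
    if de is not None and pairs:
        rows = {}
        for m, g, c in pairs:
            xm = de.trajectory(m, "miRNA", value)
            xg = de.trajectory(g, "mRNA", value)
            rows[f"{m}~{g}"] = np.concatenate([xm, xg])
        cols = [f"miRNA:{tp}" for tp in de.time_points] + [f"mRNA:{tp}" for tp in de.time_points]
        heat = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        if out is not None:
            fig, ax = plt.subplots(figsize=(6, 0.3 * len(rows) + 1.5))
            im = ax.imshow(heat.to_numpy(), aspect="auto", cmap="RdBu_r")
            ax.set_yticks(range(len(heat.index)), heat.index, fontsize=6)
            ax.set_xticks(range(len(cols)), cols, fontsize=6, rotation=90)
            fig.colorbar(im, ax=ax)
            fig.tight_layout()
            fig.savefig(out, dpi=100)
            plt.close(fig)
    return {"order": pairs, "heatmap": heat}
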