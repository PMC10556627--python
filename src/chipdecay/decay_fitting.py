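"""Per-peak binding-decay fitting for nuclear-depletion ChIP time courses.

The model is the three-parameter asymptotic exponential

    y(t) = yf + (y0 - yf) * exp(-exp(lrc) * t)

with ``y0`` the signal at t = 0, ``yf`` the asymptote as t -> infinity, and
``lrc`` the natural log of the apparent off-rate k_off (per minute). The
apparent residence time is 1/k_off minutes. Rate identifiability is judged by
a two-sided Wald test of lrc against 0; peaks passing the test at a chosen
level form the genome-wide analysis set.

The parameterization deliberately anchors t = 0: scaling the response scales
y0 and yf and leaves lrc and its p-value unchanged, but shifting times is NOT
an invariance of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import ValidationError

__all__ = [
    "DecaySeries",
    "DecayFit",
    "asymp_model_eval",
    "initialize_fit",
    "fit_decay",
    "wald_pvalue",
    "filter_fits",
    "residence_time",
    "decay_f_test",
    "fit_peak_matrix",
    "grid_search_rss",
]

_EXP_CLIP = 700.0  # exp argument bound; beyond this the decay term is numerically 0/inf


class DecaySeries:
    """Time-course observations for one peak, pooled over replicates.

    Requires >= 4 observations spanning >= 3 distinct times (3 parameters plus
    one residual degree of freedom) and nonnegative signal.
    """

    __slots__ = ("peak_id", "t", "y")

    def __init__(self, peak_id: str, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValidationError(f"{peak_id}: t and y must be 1-D and congruent")
        if len(t) < 4:
            raise ValidationError(f"{peak_id}: need >= 4 observations, got {len(t)}")
        if len(np.unique(t)) < 3:
            raise ValidationError(f"{peak_id}: need >= 3 distinct time points")
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise ValidationError(f"{peak_id}: times must be finite and >= 0")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValidationError(f"{peak_id}: signal must be finite and >= 0")
        self.peak_id = peak_id
        self.t = t
        self.y = y

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class DecayFit:
    """Fit summary for one peak.

    ``yf`` holds the unconstrained optimum (kept for RSS comparisons); the
    reporting layer clamps negative asymptotes to 0 via ``yf_report``.
    """

    peak_id: str
    y0: float
    yf: float
    lrc: float
    se_y0: float
    se_yf: float
    se_lrc: float
    p_lrc: float
    converged: bool
    rss: float
    df: int

    @property
    def koff(self) -> float:
        return math.exp(self.lrc)

    @property
    def residence_time(self) -> float:
        return residence_time(self)

    @property
    def yf_report(self) -> float:
        return max(self.yf, 0.0)


def asymp_model_eval(y0, yf, lrc, t):
    """yf + (y0 - yf) * exp(-exp(lrc) * t); vectorized over ``t``."""
    t = np.asarray(t, dtype=float)
    k = math.exp(min(lrc, _EXP_CLIP))
    return yf + (y0 - yf) * np.exp(-np.minimum(k * t, _EXP_CLIP))


def initialize_fit(series: DecaySeries) -> tuple[float, float, float]:
    """Self-start surrogate: moment-style starting values for (y0, yf, lrc).

    yf0 = min observed signal (floored at 0); y00 = mean signal at the earliest
    time; lrc0 from OLS of log(y - yf0*(1-eps)) on t over points above yf0.
    Falls back to lrc0 = log(1/median time) when fewer than 2 usable points
    remain or the log-linear slope is nonnegative.
    """
    t, y = series.t, series.y
    yf0 = max(float(np.min(y)), 0.0)
    t_min = float(np.min(t))
    y00 = float(np.mean(y[t == t_min]))
    eps = 0.01
    floor = yf0 * (1.0 - eps)
    usable = y > yf0
    lrc0 = None
    if int(usable.sum()) >= 2:
        tt, yy = t[usable], y[usable]
        z = np.log(np.maximum(yy - floor, 1e-300))
        tbar, zbar = tt.mean(), z.mean()
        denom = float(np.sum((tt - tbar) ** 2))
        if denom > 0:
            slope = float(np.sum((tt - tbar) * (z - zbar)) / denom)
            if slope < 0:
                lrc0 = math.log(-slope)
    if lrc0 is None:
        med_t = float(np.median(t))
        lrc0 = math.log(1.0 / med_t) if med_t > 0 else 0.0
    if y00 <= yf0:
        y00 = yf0 + max(yf0, 1.0)  # increasing/flat series: arbitrary positive amplitude
    return y00, yf0, lrc0


def _profiled_start(series: DecaySeries, n_grid: int = 25) -> tuple[float, float, float]:
    """Best start from profiling the rate: for fixed k the model is linear in
    (y0, yf), so each grid point costs one 2x2 least-squares solve."""
    t, y = series.t, series.y
    best = None
    for lrc in np.linspace(math.log(1e-3), math.log(10.0), n_grid):
        decay = np.exp(-np.minimum(math.exp(lrc) * t, _EXP_CLIP))
        design = np.column_stack([decay, 1.0 - decay])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ coef) ** 2))
        if best is None or rss < best[0]:
            best = (rss, float(coef[0]), float(coef[1]), float(lrc))
    return best[1], best[2], best[3]


def _residuals(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    y0, yf, lrc = params
    return y - asymp_model_eval(y0, yf, lrc, t)


def _jacobian(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    y0, yf, lrc = params
    k = math.exp(min(lrc, _EXP_CLIP))
    decay = np.exp(-np.minimum(k * t, _EXP_CLIP))
    # Jacobian of the residual y - model
    d_y0 = -decay
    d_yf = -(1.0 - decay)
    d_lrc = (y0 - yf) * t * k * decay
    return np.column_stack([d_y0, d_yf, d_lrc])


def fit_decay(series: DecaySeries) -> DecayFit:
    """Levenberg-Marquardt least-squares fit of the asymptotic exponential.

    Non-convergence (optimizer failure, singular covariance, non-finite
    parameters) is reported via ``converged=False``, never an exception;
    precondition violations on the series itself raise ``ValidationError``
    at construction.
    """
    t, y = series.t, series.y
    n = len(t)
    df = n - 3
    # two starts — the moment-style self-start and the rate-profiled grid
    # optimum — guard against local minima; keep the lower-RSS solution
    starts = [np.array(initialize_fit(series), dtype=float),
              np.array(_profiled_start(series), dtype=float)]
    res = None
    for x0 in starts:
        try:
            cand = optimize.least_squares(
                _residuals, x0, jac=_jacobian, args=(t, y),
                method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200 * 3,
            )
        except Exception:
            continue
        if res is None or float(np.sum(cand.fun**2)) < float(np.sum(res.fun**2)):
            res = cand
    if res is None:
        x0 = starts[0]
        return DecayFit(series.peak_id, *x0, np.inf, np.inf, np.inf,
                        np.nan, False, float(np.sum(_residuals(x0, t, y) ** 2)), df)
    y0, yf, lrc = (float(v) for v in res.x)
    rss = float(np.sum(res.fun**2))
    converged = bool(res.success) and all(map(math.isfinite, (y0, yf, lrc)))
    se_y0 = se_yf = se_lrc = np.inf
    if converged and df > 0:
        jtj = res.jac.T @ res.jac
        try:
            cov = (rss / df) * np.linalg.inv(jtj)
            diag = np.diag(cov)
            if np.all(np.isfinite(diag)) and np.all(diag >= 0):
                se_y0, se_yf, se_lrc = (float(v) for v in np.sqrt(diag))
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
    # near-singular Jacobians (flat data) produce absurd standard errors; treat
    # a rate whose log is uncertain by more than ~1e6 as non-identifiable
    if converged and (not math.isfinite(se_lrc) or se_lrc > 1e6):
        converged = False
    fit = DecayFit(series.peak_id, y0, yf, lrc, se_y0, se_yf, se_lrc,
                   np.nan, converged, rss, df)
    if converged:
        fit = replace(fit, p_lrc=wald_pvalue(fit))
    return fit


def wald_pvalue(fit: DecayFit) -> float:
    """Two-sided t-test of lrc against 0 with the fit's residual df.

    se_lrc = 0 (an exact fit) is the degenerate limit: p = 0 unless lrc is
    exactly 0, in which case p = 1.
    """
    if not (math.isfinite(fit.se_lrc) and fit.se_lrc >= 0):
        raise ValidationError(f"{fit.peak_id}: p-value undefined without a finite se(lrc)")
    if fit.se_lrc == 0.0:
        return 1.0 if fit.lrc == 0.0 else 0.0
    tstat = fit.lrc / fit.se_lrc
    return float(2.0 * stats.t.sf(abs(tstat), fit.df))


def filter_fits(
    fits: list[DecayFit], alpha: float = 0.05, require_positive_amplitude: bool = False
) -> list[DecayFit]:
    """Retain converged fits with p(lrc) < alpha (and k_off > 0); order preserved.

    ``require_positive_amplitude`` additionally demands y0 > yf (a genuine
    decay), off by default.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    kept = []
    for fit in fits:
        if not fit.converged:
            continue
        if not (math.isfinite(fit.p_lrc) and fit.p_lrc < alpha):
            continue
        if fit.koff <= 0:
            continue
        if require_positive_amplitude and not fit.y0 > fit.yf:
            continue
        kept.append(fit)
    return kept


def residence_time(fit: DecayFit) -> float:
    """Apparent residence time 1/k_off in minutes."""
    koff = math.exp(fit.lrc)
    if koff <= 0:
        raise ValidationError(f"{fit.peak_id}: k_off must be > 0")
    return 1.0 / koff


def decay_f_test(series: DecaySeries, fit: DecayFit) -> float:
    """Model-comparison F-test p (decay vs constant mean); optional alternative column."""
    rss0 = float(np.sum((series.y - series.y.mean()) ** 2))
    df1, df2 = 2, fit.df
    if fit.df <= 0 or fit.rss <= 0:
        return float("nan")
    f = ((rss0 - fit.rss) / df1) / (fit.rss / df2)
    if f < 0:
        return 1.0
    return float(stats.f.sf(f, df1, df2))


def grid_search_rss(
    series: DecaySeries,
    n: int = 100,
    lrc_range: tuple[float, float] = (math.log(0.001), math.log(10.0)),
) -> float:
    """Brute-force minimum RSS over an n^3 grid; independent benchmark for the fitter.

    Grid: y0 in [0, 2*max y], yf in [0, max y], lrc in ``lrc_range``.
    """
    t, y = series.t, series.y
    ymax = float(np.max(y))
    y0g = np.linspace(0.0, 2.0 * ymax, n)
    yfg = np.linspace(0.0, ymax, n)
    lrcg = np.linspace(lrc_range[0], lrc_range[1], n)
    decay = np.exp(-np.exp(lrcg)[:, None] * t[None, :])  # (n_lrc, n_t)
    best = np.inf
    for dec in decay:  # loop over lrc to bound memory
        # model = yf + (y0-yf)*dec  ->  (n_y0, n_yf, n_t)
        pred = (
            yfg[None, :, None] * (1.0 - dec[None, None, :])
            + y0g[:, None, None] * dec[None, None, :]
        )
        rss = np.sum((y[None, None, :] - pred) ** 2, axis=2)
        m = float(rss.min())
        if m < best:
            best = m
    return best


def fit_peak_matrix(
    normalized: pd.DataFrame,
    samples: list,
    mode: str = "pooled",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every row of a normalized peak x sample matrix; return the fit table.

    ``mode='pooled'`` pools replicates as independent observations into one fit
    per peak. ``mode='per-replicate'`` fits each replicate separately and
    reports the mean residence time across replicate fits (with its SE); the
    Wald filter then applies to the pooled columns which are also computed.
    """
    if mode not in ("pooled", "per-replicate"):
        raise ValueError(f"unknown fit mode {mode!r}")
    sample_by_id = {s.sample_id: s for s in samples}
    missing = [c for c in normalized.columns if c not in sample_by_id]
    if missing:
        raise ValidationError(f"sample sheet lacks matrix column(s) {missing}")
    times = np.array([sample_by_id[c].time for c in normalized.columns])
    reps = np.array([sample_by_id[c].replicate for c in normalized.columns])

    rows = []
    for peak_id, row in normalized.iterrows():
        yvals = row.to_numpy(dtype=float)
        series = DecaySeries(str(peak_id), times, yvals)
        fit = fit_decay(series)
        rec = {
            "peak_id": str(peak_id),
            "y0": fit.y0,
            "yf": fit.yf_report,
            "lrc": fit.lrc,
            "koff_per_min": fit.koff,
            "residence_min": 1.0 / fit.koff if fit.koff > 0 else np.nan,
            "se_lrc": fit.se_lrc,
            "p_lrc": fit.p_lrc,
            "rss": fit.rss,
            "df": fit.df,
            "converged": fit.converged,
        }
        if mode == "per-replicate":
            rep_tau = []
            for rep in np.unique(reps):
                mask = reps == rep
                if mask.sum() >= 4 and len(np.unique(times[mask])) >= 3:
                    rfit = fit_decay(DecaySeries(f"{peak_id}/{rep}", times[mask], yvals[mask]))
                    if rfit.converged:
                        rep_tau.append(rfit.residence_time)
            if rep_tau:
                rec["residence_min"] = float(np.mean(rep_tau))
                rec["se_residence"] = (
                    float(np.std(rep_tau, ddof=1) / math.sqrt(len(rep_tau)))
                    if len(rep_tau) > 1 else np.nan
                )
                rec["n_replicate_fits"] = len(rep_tau)
        rows.append(rec)
    table = pd.DataFrame(rows).set_index("peak_id")
    retained = (
        table["converged"]
        & np.isfinite(table["p_lrc"])
        & (table["p_lrc"] < alpha)
        & (table["koff_per_min"] > 0)
    )
    table["retained"] = retained
    return table
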