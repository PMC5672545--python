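"""Concentration-response model fitting and point-of-departure estimation.

Four candidate models are fit to each selected dose/response series by
Gaussian maximum likelihood (least squares) on the log10-dose scale:

* constant:   f(x) = mu
* hill3:      f(x) = tp / (1 + 10^((ga - x) * gw))            (floor = 0)
* gainloss:   f(x) = tp * gain-sigmoid * loss-sigmoid          (floor = 0)
* hill4:      f(x) = floor + (top - floor) / (1 + 10^((ec50 - x) * slope))

The floor-0 models are fit to both y and -y so down-regulation is handled by
sign-flipping; the better sign is kept and recorded as the direction.  The
winner is the converged fit with the smallest AIC (k counts the residual
scale sigma: constant 2, hill3 4, hill4 5, gainloss 6).  The POD is the
lowest dose at which the winning curve departs one control-SD (the baseline
standard deviation, BSD) from the control mean, located by bracketing and
bisection on the log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .trend_flags import ROUTE_MANUAL, ROUTE_POD_MAX, DoseResponseSeries

MODEL_NAMES = ("constant", "hill3", "hill4", "gainloss")

# free parameters per model, residual sigma included
N_PARAMS = {"constant": 2, "hill3": 4, "hill4": 5, "gainloss": 6}

# deterministic tie-break order after parameter count
_MODEL_ORDER = {"constant": 0, "hill3": 1, "hill4": 2, "gainloss": 3}

_SLOPE_BOUNDS = (0.3, 8.0)


def constant_curve(x, mu):
    return np.full_like(np.asarray(x, dtype=float), mu)


def hill3_curve(x, tp, ga, gw):
    x = np.asarray(x, dtype=float)
    return tp / (1.0 + 10.0 ** ((ga - x) * gw))


def gainloss_curve(x, tp, ga, gw, la, lw):
    x = np.asarray(x, dtype=float)
    gain = 1.0 / (1.0 + 10.0 ** ((ga - x) * gw))
    loss = 1.0 / (1.0 + 10.0 ** ((x - la) * lw))
    return tp * gain * loss


def hill4_curve(x, floor, top, ec50, slope):
    x = np.asarray(x, dtype=float)
    return floor + (top - floor) / (1.0 + 10.0 ** ((ec50 - x) * slope))


def model_curves(name: str, params: dict[str, float], x) -> np.ndarray:
    """Evaluate a named model at log10 doses ``x``."""
    if name == "constant":
        return constant_curve(x, params["mu"])
    if name == "hill3":
        return hill3_curve(x, params["tp"], params["ga"], params["gw"])
    if name == "gainloss":
        return gainloss_curve(
            x, params["tp"], params["ga"], params["gw"], params["la"], params["lw"]
        )
    if name == "hill4":
        return hill4_curve(x, params["floor"], params["top"], params["ec50"], params["slope"])
    raise ValueError(f"unknown model {name!r}")


@dataclass
class ModelFit:
    model: str
    params: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    direction: str = "up"  # up | down
    sse: float = float("nan")
    degenerate: bool = False

    def predict(self, x) -> np.ndarray:
        y = model_curves(self.model, self.params, x)
        return -y if self.direction == "down" and self.model in ("hill3", "gainloss") else y


@dataclass
class PODResult:
    gene: str
    chemical: str
    model: str
    direction: str
    pod_log10uM: float
    pod_uM: float
    bsd: float
    basis: str  # curve_crossing | max_dose_no_trend | max_dose_no_crossing
    extrapolated: bool = False


_LN10 = math.log(10.0)


def _hill3_jac(x, tp, ga, gw):
    u = 10.0 ** ((ga - x) * gw)
    g = 1.0 / (1.0 + u)
    du = u * _LN10 * g * g
    return np.column_stack([g, -tp * du * gw, -tp * du * (ga - x)])


def _gainloss_jac(x, tp, ga, gw, la, lw):
    u = 10.0 ** ((ga - x) * gw)
    v = 10.0 ** ((x - la) * lw)
    g = 1.0 / (1.0 + u)
    h = 1.0 / (1.0 + v)
    dg = u * _LN10 * g * g
    dh = v * _LN10 * h * h
    return np.column_stack(
        [
            g * h,
            -tp * h * dg * gw,
            -tp * h * dg * (ga - x),
            tp * g * dh * lw,
            -tp * g * dh * (x - la),
        ]
    )


def _hill4_jac(x, floor, top, ec50, slope):
    u = 10.0 ** ((ec50 - x) * slope)
    g = 1.0 / (1.0 + u)
    du = u * _LN10 * g * g
    amp = top - floor
    return np.column_stack([1.0 - g, g, -amp * du * slope, -amp * du * (ec50 - x)])


def _gaussian_loglik(sse: float, n: int) -> float:
    sigma2 = max(sse / n, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _fit_ls(residual_fn, starts, bounds, jac=None) -> tuple[np.ndarray | None, float]:
    """Deterministic multi-start bounded least squares; best SSE wins."""
    best_theta, best_sse = None, np.inf
    lo, hi = bounds
    for theta0 in starts:
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = least_squares(
                residual_fn,
                theta0,
                jac=jac if jac is not None else "2-point",
                bounds=bounds,
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if res.success and sse < best_sse - 1e-15:
            best_theta, best_sse = res.x, sse
    return best_theta, best_sse


def _dose_quartiles(x: np.ndarray) -> list[float]:
    return [float(np.quantile(np.unique(x), q)) for q in (0.25, 0.5, 0.75)]


def fit_model(series: DoseResponseSeries, name: str) -> ModelFit:
    """Fit one named model to a series by bounded multi-start least squares.

    Floor-0 models (hill3, gainloss) are fit against both y and -y; the sign
    with the smaller SSE is kept and reported as the response direction.
    """
    x = series.dose
    y = series.response
    n = y.size
    if name == "constant":
        mu = float(y.mean())
        sse = float(((y - mu) ** 2).sum())
        ll = _gaussian_loglik(sse, n)
        return ModelFit("constant", {"mu": mu}, ll, 2 * N_PARAMS[name] - 2 * ll, True, "up", sse)

    lo_x, hi_x = float(x.min()) - 1.0, float(x.max()) + 1.0
    ga_starts = _dose_quartiles(x)
    gw_starts = [0.5, 1.0, 4.0]
    max_amp = float(np.abs(y).max())
    tp_hi = max(1.2 * max_amp, 1e-6)

    if name in ("hill3", "gainloss"):
        best = None
        for sign, direction in ((1.0, "up"), (-1.0, "down")):
            ys = sign * y
            tp0s = [max(ys.max(), 1e-3)]
            if name == "hill3":
                bounds = (np.array([0.0, lo_x, _SLOPE_BOUNDS[0]]),
                          np.array([tp_hi, hi_x, _SLOPE_BOUNDS[1]]))
                starts = [
                    np.array([tp0, ga, gw])
                    for tp0 in tp0s
                    for ga in ga_starts
                    for gw in gw_starts
                ]
                fn = lambda th, ys=ys: hill3_curve(x, *th) - ys
                jac = lambda th: _hill3_jac(x, *th)
            else:
                bounds = (
                    np.array([0.0, lo_x, _SLOPE_BOUNDS[0], lo_x, _SLOPE_BOUNDS[0]]),
                    np.array([tp_hi, hi_x, _SLOPE_BOUNDS[1], hi_x, _SLOPE_BOUNDS[1]]),
                )
                starts = [
                    np.array([tp0, ga, gw, hi_x - 0.5, gw])
                    for tp0 in tp0s
                    for ga in ga_starts
                    for gw in gw_starts
                ]
                fn = lambda th, ys=ys: gainloss_curve(x, *th) - ys
                jac = lambda th: _gainloss_jac(x, *th)
            theta, sse = _fit_ls(fn, starts, bounds, jac)
            if theta is not None and (best is None or sse < best[2]):
                best = (direction, theta, sse)
        if best is None:
            return ModelFit(name, {}, -np.inf, np.inf, False)
        direction, theta, sse = best
        ll = _gaussian_loglik(sse, n)
        if name == "hill3":
            params = {"tp": theta[0], "ga": theta[1], "gw": theta[2]}
            degenerate = False
        else:
            params = {"tp": theta[0], "ga": theta[1], "gw": theta[2], "la": theta[3], "lw": theta[4]}
            degenerate = params["la"] < params["ga"]
        return ModelFit(
            name, {k: float(v) for k, v in params.items()},
            ll, 2 * N_PARAMS[name] - 2 * ll, True, direction, sse, degenerate,
        )

    if name == "hill4":
        amp = max(float(np.ptp(y)), 1e-6)
        bounds = (
            np.array([-1.2 * max_amp - 1e-6, -1.2 * max_amp - 1e-6, lo_x, _SLOPE_BOUNDS[0]]),
            np.array([1.2 * max_amp + 1e-6, 1.2 * max_amp + 1e-6, hi_x, _SLOPE_BOUNDS[1]]),
        )
        ctrl_level = float(y[series.is_control].mean()) if series.is_control.any() else 0.0
        hi_level = float(y[x == x.max()].mean())
        starts = [
            np.array([ctrl_level, hi_level if hi_level != ctrl_level else ctrl_level + amp, ga, gw])
            for ga in ga_starts
            for gw in gw_starts
        ]
        starts += [np.array([ctrl_level, ctrl_level - amp, ga, 1.0]) for ga in ga_starts]
        fn = lambda th: hill4_curve(x, *th) - y
        theta, sse = _fit_ls(fn, starts, bounds, lambda th: _hill4_jac(x, *th))
        if theta is None:
            return ModelFit(name, {}, -np.inf, np.inf, False)
        ll = _gaussian_loglik(sse, n)
        params = {"floor": float(theta[0]), "top": float(theta[1]),
                  "ec50": float(theta[2]), "slope": float(theta[3])}
        direction = "up" if params["top"] >= params["floor"] else "down"
        return ModelFit(name, params, ll, 2 * N_PARAMS[name] - 2 * ll, True, direction, sse)

    raise ValueError(f"unknown model {name!r}")


def fit_all_models(series: DoseResponseSeries, models=MODEL_NAMES) -> dict[str, ModelFit]:
    return {name: fit_model(series, name) for name in models}


def select_model(fits: dict[str, ModelFit]) -> ModelFit:
    """Winner = smallest AIC among converged fits; ties break to fewer
    parameters, then to a fixed model order.  All-unconverged falls back to
    a zero constant."""
    converged = [f for f in fits.values() if f.converged]
    if not converged:
        return ModelFit("constant", {"mu": 0.0}, -np.inf, np.inf, True)
    return min(
        converged,
        key=lambda f: (round(f.aic, 10), N_PARAMS[f.model], _MODEL_ORDER[f.model]),
    )


def pod_from_fit(
    fit: ModelFit,
    series: DoseResponseSeries,
    bsd_multiplier: float = 1.0,
    tol: float = 1e-6,
) -> PODResult:
    """POD: lowest log10 dose where |f(x)| reaches the baseline deviation.

    BSD = ``bsd_multiplier`` x control SD.  The search bracket runs from the
    vehicle pseudo-dose to the maximum tested dose; the crossing is located
    by sign-change bracketing plus bisection to ``tol`` on the log10 scale.
    No crossing (including a constant winner) puts the POD at the maximum
    dose; a crossing below the lowest tested dose is flagged extrapolated.
    """
    bsd = bsd_multiplier * series.control_sd
    x_max = series.max_dose
    lowest_tested = float(series.dose[~series.is_control].min())

    def make(pod, basis, extrapolated=False):
        return PODResult(
            series.gene, series.chemical, fit.model, fit.direction,
            float(pod), float(10.0 ** pod), float(bsd), basis, extrapolated,
        )

    if fit.model == "constant" or bsd <= 0:
        return make(x_max, "max_dose_no_crossing")

    def g(x):
        return float(np.abs(fit.predict(np.array([x])))[0]) - bsd

    x0 = series.pseudo_dose
    if g(x0) >= 0:  # already beyond BSD at the control pseudo-dose
        return make(x0, "curve_crossing", extrapolated=True)
    grid = np.linspace(x0, x_max, 513)
    vals = np.array([g(v) for v in grid])
    crossing = np.flatnonzero((vals[:-1] < 0) & (vals[1:] >= 0))
    if crossing.size == 0:
        return make(x_max, "max_dose_no_crossing")
    i = int(crossing[0])
    pod = brentq(g, grid[i], grid[i + 1], xtol=tol)
    return make(pod, "curve_crossing", extrapolated=pod < lowest_tested)


def pod_max_dose(series: DoseResponseSeries, bsd_multiplier: float = 1.0) -> PODResult:
    """POD assigned at the maximum tested dose for no-trend series."""
    return PODResult(
        series.gene, series.chemical, "none", "none",
        series.max_dose, float(10.0 ** series.max_dose),
        float(bsd_multiplier * series.control_sd), "max_dose_no_trend",
    )


def hill3_pod_closed_form(tp: float, ga: float, gw: float, bsd: float) -> float | None:
    """Analytic hill3 BSD crossing: ga - log10(tp/bsd - 1)/gw (None when the
    curve never reaches the BSD)."""
    if abs(tp) <= bsd or bsd <= 0:
        return None
    return ga - math.log10(abs(tp) / bsd - 1.0) / gw


def pod_summary(pods: list[PODResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chemical POD distribution summaries and winner-model frequencies."""
    df = pd.DataFrame(
        {
            "chemical": [p.chemical for p in pods],
            "model": [p.model for p in pods],
            "pod_log10uM": [p.pod_log10uM for p in pods],
            "basis": [p.basis for p in pods],
        }
    )
    dist = (
        df.groupby("chemical")["pod_log10uM"]
        .agg(n="size", mean="mean", median="median", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    fitted = df[df["basis"] == "curve_crossing"]
    freq = (
        fitted.groupby(["chemical", "model"]).size().rename("n_wins").reset_index()
        if len(fitted)
        else pd.DataFrame(columns=["chemical", "model", "n_wins"])
    )
    return dist, freq


def fit_series(
    series: DoseResponseSeries,
    route_label: str,
    bsd_multiplier: float = 1.0,
    models=MODEL_NAMES,
) -> tuple[dict[str, ModelFit] | None, PODResult]:
    """Fit + select + POD for one routed series.

    Series routed NO-TREND skip fitting and take the maximum dose as POD;
    manual-review series are reported without a fit or a POD.
    """
    if route_label == ROUTE_POD_MAX:
        return None, pod_max_dose(series, bsd_multiplier)
    if route_label == ROUTE_MANUAL:
        return None, PODResult(
            series.gene, series.chemical, "none", "none",
            float("nan"), float("nan"),
            float(bsd_multiplier * series.control_sd), "manual_review",
        )
    fits = fit_all_models(series, models)
    winner = select_model(fits)
    return fits, pod_from_fit(winner, series, bsd_multiplier)
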