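"""Tonic/phasic decomposition of calibration traces and saturation fits.

A staircase calibration (consecutive substrate steps in the bath) elicits,
per step, a steady-state (tonic) plateau and often a transient overshoot
(phasic peak) that precedes it.  The tonic plateau-vs-O2 curve follows
apparent Michaelis-Menten saturation; cumulative phasic amplitudes are
fitted with the Hill equation, whose coefficient n captures the
cooperative-looking O2-baseline dependence of the transients.

Analytical figures of merit (sensitivity, limit of detection, T50/T90
response times) follow the usual amperometric conventions: sensitivity from
a linear regression over the first three analyte additions, LOD as the
concentration equivalent to three baseline standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .sensor import SimTrace


class FitError(RuntimeError):
    """Nonlinear fit did not converge or produced unusable estimates."""


@dataclass
class StepResponses:
    """Per-step decomposition of a staircase calibration (units of the trace)."""

    o2_baseline: np.ndarray        # cumulative bulk O2 after each step (uM)
    tonic: np.ndarray              # plateau minus pre-calibration baseline
    phasic: np.ndarray             # peak minus own plateau, floored at 0
    cumulative_phasic: np.ndarray  # running sum of phasic amplitudes
    t50_decay: np.ndarray          # s, peak -> halfway to plateau
    t90_rise: np.ndarray           # s, onset -> 90 % of peak
    plateaus: np.ndarray           # absolute plateau values
    baseline: float                # pre-calibration baseline level

    def __len__(self) -> int:
        return self.tonic.size


@dataclass
class MMFit:
    km: float
    imax: float
    rmse: float
    ci: dict = field(default_factory=dict)


@dataclass
class HillFit:
    k05: float
    n: float
    imax: float
    rmse: float
    ci: dict = field(default_factory=dict)


def _window_slices(t: np.ndarray, step_times: np.ndarray):
    if np.any(np.diff(step_times) <= 0):
        raise ValueError("step_times must be strictly increasing")
    edges = np.concatenate([step_times, [t[-1] + (t[1] - t[0])]])
    idx = np.searchsorted(t, edges)
    return [(idx[k], idx[k + 1]) for k in range(len(step_times))]


def _onset_index(y: np.ndarray, level: float, thr: float) -> int | None:
    """First sustained (two-sample) crossing above level + thr."""
    above = y > level + thr
    hits = np.flatnonzero(above[:-1] & above[1:])
    return int(hits[0]) if hits.size else None


def extract_step_responses(t: np.ndarray, y: np.ndarray,
                           step_times: np.ndarray,
                           o2_baseline: np.ndarray | None = None,
                           baseline: float | None = None,
                           plateau_frac: float = 0.1,
                           pre_sd_window: float = 5.0) -> StepResponses:
    """Decompose a staircase trace into per-step tonic and phasic responses.

    Tonic response = plateau (mean of the final ``plateau_frac`` of the step
    window) minus the pre-calibration baseline, i.e. cumulative with respect
    to the staircase.  Phasic response = within-window maximum minus that
    step's plateau.  Response onset per step is the first sustained
    departure > 3 SD above the local pre-step level (mirroring the LOD
    convention); T90 rise and T50 decay are measured from onset/peak.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    step_times = np.asarray(step_times, float)
    dt = float(np.median(np.diff(t)))
    wins = _window_slices(t, step_times)
    for i0, i1 in wins:
        if int(plateau_frac * (i1 - i0)) < 1:
            raise ValueError("step window shorter than the plateau fraction")

    if baseline is None:
        pre = y[t < step_times[0]]
        baseline = float(pre.mean()) if pre.size else 0.0

    n = len(wins)
    tonic = np.empty(n)
    phasic = np.empty(n)
    t50 = np.full(n, np.nan)
    t90 = np.full(n, np.nan)
    plateaus = np.empty(n)

    for k, (i0, i1) in enumerate(wins):
        w = y[i0:i1]
        tw = t[i0:i1]
        m = max(1, int(round(plateau_frac * w.size)))
        plateau = float(w[-m:].mean())
        plateaus[k] = plateau
        tonic[k] = plateau - baseline
        ipk = int(np.argmax(w))
        peak = float(w[ipk])
        # earliest index wins at ties by argmax convention; floor rounding fuzz
        phasic[k] = max(0.0, peak - plateau)
        if phasic[k] < 1e-12 * max(1.0, abs(peak)):
            phasic[k] = 0.0

        pre_mask = (t >= step_times[k] - 1.0) & (t < step_times[k])
        level = float(y[pre_mask].mean()) if pre_mask.any() else baseline
        sd_mask = (t >= step_times[k] - pre_sd_window) & (t < step_times[k])
        sd = float(y[sd_mask].std()) if sd_mask.sum() > 1 else 0.0
        thr = max(3.0 * sd, 1e-9 * max(1.0, np.abs(y).max()))

        ion = _onset_index(w, level, thr)
        if ion is not None and peak > level:
            target = level + 0.9 * (peak - level)
            reach = np.flatnonzero(w[ion:] >= target)
            if reach.size:
                t90[k] = tw[ion + reach[0]] - tw[ion]
        if phasic[k] > 0:
            half = (peak + plateau) / 2.0
            drop = np.flatnonzero(w[ipk:] <= half)
            if drop.size:
                t50[k] = drop[0] * dt

    if o2_baseline is None:
        o2_baseline = np.full(n, np.nan)
    return StepResponses(np.asarray(o2_baseline, float), tonic, phasic,
                         np.cumsum(phasic), t50, t90, plateaus, float(baseline))


def step_responses_from_trace(trace: SimTrace, **kwargs) -> StepResponses:
    """Decompose a :class:`~choxamp.sensor.SimTrace`, reading the cumulative
    bulk-O2 level of each step from the trace's own schedule."""
    o2b = np.array([trace.bulk_o2[np.searchsorted(trace.t, ts) + 1]
                    for ts in trace.step_times])
    return extract_step_responses(trace.t, trace.current, trace.step_times,
                                  o2_baseline=o2b, **kwargs)


def _run_fit(model: lmfit.Model, x, y, params) -> lmfit.model.ModelResult:
    try:
        res = model.fit(y, params, x=x)
    except Exception as exc:  # lmfit propagates numerics as various types
        raise FitError(f"fit raised {exc!r}") from exc
    if not res.success:
        raise FitError(f"fit did not converge: {res.message}")
    return res


def _ci(res: lmfit.model.ModelResult, names) -> dict:
    out = {}
    for name in names:
        p = res.params[name]
        if p.stderr is None or not np.isfinite(p.stderr):
            out[name] = (np.nan, np.nan)
        else:
            out[name] = (p.value - 1.96 * p.stderr, p.value + 1.96 * p.stderr)
    return out


def michaelis_menten(x, imax, km):
    return imax * x / (km + x)


def hill(x, imax, k05, n):
    xn = np.power(np.clip(x, 0, None), n)
    return imax * xn / (k05**n + xn)


def fit_michaelis_menten(x: np.ndarray, y: np.ndarray) -> MMFit:
    """Least-squares Michaelis-Menten fit y = Imax*x/(Km+x), covariance CIs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    ymax = float(y.max())
    half = np.interp(ymax / 2.0, y, x) if ymax > 0 else x[0]
    model = lmfit.Model(michaelis_menten)
    params = model.make_params(imax=dict(value=max(ymax, 1e-12), min=1e-12),
                               km=dict(value=max(half, x[0] / 10, 1e-6), min=1e-9))
    res = _run_fit(model, x, y, params)
    rmse = float(np.sqrt(np.mean(res.residual**2)))
    return MMFit(km=res.params["km"].value, imax=res.params["imax"].value,
                 rmse=rmse, ci=_ci(res, ("km", "imax")))


def fit_hill(x: np.ndarray, y: np.ndarray) -> HillFit:
    """Least-squares Hill fit y = Imax*x^n/(K05^n + x^n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    ymax = float(y.max())
    half = np.interp(ymax / 2.0, y, x) if ymax > 0 else x[0]
    model = lmfit.Model(hill)
    params = model.make_params(
        imax=dict(value=max(ymax, 1e-12), min=1e-12),
        k05=dict(value=max(half, 1e-6), min=1e-9),
        n=dict(value=1.5, min=0.05, max=10.0),
    )
    res = _run_fit(model, x, y, params)
    rmse = float(np.sqrt(np.mean(res.residual**2)))
    return HillFit(k05=res.params["k05"].value, n=res.params["n"].value,
                   imax=res.params["imax"].value, rmse=rmse,
                   ci=_ci(res, ("k05", "n", "imax")))


def analytic_figures(t: np.ndarray, y: np.ndarray,
                     addition_times: np.ndarray, conc_step: float,
                     plateau_frac: float = 0.1) -> dict:
    """Sensitivity, LOD and T50/T90 response times of a calibration trace.

    Sensitivity is the regression slope of plateau response vs cumulative
    concentration over the first three additions; LOD = 3*SD(baseline) /
    sensitivity; T50/T90 run from response onset (first sustained departure
    > 3 SD above the local baseline) to 50 %/90 % of the first step's
    maximum.  Zero sensitivity leaves the LOD undefined (NaN).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    addition_times = np.asarray(addition_times, float)
    if addition_times.size < 3:
        raise ValueError("need at least three analyte additions")
    base_mask = t < addition_times[0]
    if not base_mask.any():
        raise ValueError("trace lacks a pre-addition baseline segment")
    baseline = float(y[base_mask].mean())
    base_sd = float(y[base_mask].std())

    sr = extract_step_responses(t, y, addition_times, baseline=baseline,
                                plateau_frac=plateau_frac)
    conc = conc_step * np.arange(1, 4)
    slope = stats.linregress(conc, sr.tonic[:3]).slope
    sensitivity = float(slope)
    lod = 3.0 * base_sd / sensitivity if sensitivity > 0 else np.nan

    # T50/T90 on the first addition
    i0, i1 = _window_slices(t, addition_times)[0]
    w, tw = y[i0:i1], t[i0:i1]
    thr = max(3.0 * base_sd, 1e-9 * max(1.0, np.abs(y).max()))
    ion = _onset_index(w, baseline, thr)
    t50 = t90 = np.nan
    if ion is not None:
        peak = float(w.max())
        for frac, store in ((0.5, "t50"), (0.9, "t90")):
            target = baseline + frac * (peak - baseline)
            reach = np.flatnonzero(w[ion:] >= target)
            if reach.size:
                val = tw[ion + reach[0]] - tw[ion]
                if store == "t50":
                    t50 = float(val)
                else:
                    t90 = float(val)
    return {"sensitivity": sensitivity, "lod": float(lod),
            "t50": float(t50), "t90": float(t90), "baseline_sd": base_sd}
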