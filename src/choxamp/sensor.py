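"""Reaction-diffusion model of an enzyme-coated amperometric microelectrode.

The sensing element is a metal disc (radius ``radius`` um, from a 17 um wire)
covered by a spherical enzyme-loaded coating shell of thickness ``thickness``.
Choline and O2 diffuse in from the bulk, react with immobilised choline
oxidase (six-state ping-pong cycle, :mod:`choxamp.kinetics`) and the H2O2
produced is oxidised at the electrode; the recorded current is proportional
to the H2O2 flux into the electrode surface,

    I = 2 F (pi re^2) * D_H2O2_eff * dH2O2/dr |_(r=re),

two electrons per H2O2 molecule.  The radial coordinate is measured from the
centre of the equivalent sphere, inner boundary at re, outer at re + R, which
keeps the spherical operator regular while matching hemispherical diffusion
to a disc-scale site.

Internal unit system: uM - um - s; currents in pA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .kinetics import ENZYME_STATES, KineticConstants

FARADAY = 96485.33212  # C/mol

# pA per (um^2 * um^2/s * uM/um): 2*F*pi * 1e-21 mol/(uM um^3) * 1e12 pA/A
CURRENT_PA_FACTOR = 2.0 * FARADAY * math.pi * 1e-9


class NumericsError(RuntimeError):
    """Raised when the explicit scheme produces unusable numbers."""


@dataclass(frozen=True)
class CoatingSpec:
    """Geometry and transport properties of the enzyme coating.

    ``radius`` is the electrode radius (half the 17 um wire diameter by
    default); diffusion coefficients are free-solution values (um^2/s) that
    enter the PDE multiplied by the crowding hindrance factor ``alpha``.
    ``e0`` is the total immobilised enzyme concentration (uM).
    """

    thickness: float               # um
    e0: float = 263.0              # uM, estimated coating enzyme concentration
    radius: float = 8.5            # um
    d_ch: float = 1197.0           # um^2/s
    d_o2: float = 2500.0           # um^2/s
    d_h2o2: float = 1830.0         # um^2/s
    alpha: float = 0.8             # dimensionless, in (0, 1]

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("coating thickness must be positive")
        if self.e0 < 0:
            raise ValueError("enzyme concentration must be non-negative")
        if not self.radius > 0:
            raise ValueError("electrode radius must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("hindrance factor alpha must be in (0, 1]")
        for name in ("d_ch", "d_o2", "d_h2o2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"diffusion coefficient {name} must be positive")

    @property
    def d_ch_eff(self) -> float:
        return self.alpha * self.d_ch

    @property
    def d_o2_eff(self) -> float:
        return self.alpha * self.d_o2

    @property
    def d_h2o2_eff(self) -> float:
        return self.alpha * self.d_h2o2


@dataclass(frozen=True)
class GridSpec:
    """Finite-difference discretisation: dr in um, dt in s."""

    dr: float = 1.0
    dt: float = 1e-4
    snapshot_interval: float = 0.1  # s, cadence for stored profiles

    def __post_init__(self) -> None:
        if not (self.dr > 0 and self.dt > 0 and self.snapshot_interval > 0):
            raise ValueError("dr, dt and snapshot_interval must be positive")

    def stability_number(self, coating: CoatingSpec) -> float:
        """alpha * max(D) * dt / dr^2 of the explicit scheme (must be <= 0.5)."""
        dmax = max(coating.d_ch, coating.d_o2, coating.d_h2o2)
        return coating.alpha * dmax * self.dt / self.dr**2

    def check(self, coating: CoatingSpec) -> None:
        s = self.stability_number(coating)
        if s > 0.5:
            raise NumericsError(
                f"explicit-scheme stability number {s:.3f} exceeds 0.5 "
                f"(dt={self.dt}, dr={self.dr}); refine dt or coarsen dr"
            )
        if coating.thickness < 2 * self.dr:
            raise ValueError("coating thickness must be at least 2*dr")


@dataclass(frozen=True)
class BulkProtocol:
    """Piecewise-constant bulk concentrations.

    ``times[k]`` is the start of segment k (``times[0] == 0``) during which
    bulk Ch/O2 equal ``ch[k]``/``o2[k]``; the run ends at ``t_end``.
    ``step_times`` are the bulk-change events after the initial segment.
    """

    times: np.ndarray
    ch: np.ndarray
    o2: np.ndarray
    t_end: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "ch", np.asarray(self.ch, float))
        object.__setattr__(self, "o2", np.asarray(self.o2, float))
        if self.times[0] != 0:
            raise ValueError("first segment must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("segment times must be strictly increasing")
        if len(self.times) != len(self.ch) or len(self.times) != len(self.o2):
            raise ValueError("times, ch and o2 must have equal length")
        if np.any(self.ch < 0) or np.any(self.o2 < 0):
            raise ValueError("bulk concentrations must be non-negative")
        if self.t_end <= self.times[-1]:
            raise ValueError("t_end must exceed the last segment start")

    @property
    def step_times(self) -> np.ndarray:
        return self.times[1:]

    def bulk_at(self, t: float) -> tuple[float, float]:
        k = int(np.searchsorted(self.times, t, side="right") - 1)
        return float(self.ch[k]), float(self.o2[k])

    # -- canonical protocols --------------------------------------------
    @classmethod
    def standard_calibration(cls, ch: float = 5.0, o2_step: float = 5.0,
                             o2_max: float = 30.0, hold: float = 60.0,
                             pre_hold: float = 300.0) -> "BulkProtocol":
        """Constant bulk Ch with O2 incremented in equal steps from zero.

        An initial anoxic segment of ``pre_hold`` s lets Ch equilibrate into
        the coating (the experimental analogue is the N2-purged baseline).
        """
        n = int(round(o2_max / o2_step))
        times = np.concatenate([[0.0], pre_hold + hold * np.arange(n)])
        o2 = np.concatenate([[0.0], o2_step * np.arange(1, n + 1)])
        chs = np.full(n + 1, ch)
        return cls(times, chs, o2, t_end=float(pre_hold + hold * n))

    @classmethod
    def constant(cls, ch: float, o2: float, duration: float) -> "BulkProtocol":
        return cls(np.array([0.0]), np.array([ch]), np.array([o2]), duration)


@dataclass
class FieldState:
    """Radial concentration profiles at one instant (all uM)."""

    r: np.ndarray
    ch: np.ndarray
    o2: np.ndarray
    h2o2: np.ndarray
    enzymes: np.ndarray  # shape (6, n) ordered as kinetics.ENZYME_STATES
    t: float = 0.0

    def __getattr__(self, name):
        if name in ENZYME_STATES:
            return self.enzymes[ENZYME_STATES.index(name)]
        raise AttributeError(name)

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    def total_enzyme(self) -> np.ndarray:
        return self.enzymes.sum(axis=0)

    def copy(self) -> "FieldState":
        return FieldState(self.r.copy(), self.ch.copy(), self.o2.copy(),
                          self.h2o2.copy(), self.enzymes.copy(), self.t)


@dataclass
class SimTrace:
    """Simulated electrode current and bulk schedule at the output rate."""

    t: np.ndarray
    current: np.ndarray          # pA
    bulk_ch: np.ndarray          # uM
    bulk_o2: np.ndarray          # uM
    surface_ch: np.ndarray       # uM at the inner node
    surface_o2: np.ndarray       # uM at the inner node
    step_times: np.ndarray
    snapshots: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def output_dt(self) -> float:
        return float(self.t[1] - self.t[0])


def init_state(coating: CoatingSpec, grid: GridSpec,
               kinetics: KineticConstants | None = None) -> FieldState:
    """Initial state of a calibration: no substrates or product in the
    coating, all enzyme free at e0."""
    grid.check(coating)
    n = int(round(coating.thickness / grid.dr)) + 1
    r = coating.radius + grid.dr * np.arange(n)
    enz = np.zeros((6, n))
    enz[0] = coating.e0
    return FieldState(r, np.zeros(n), np.zeros(n), np.zeros(n), enz, 0.0)


def _geometry(state: FieldState):
    r = state.r
    dr = state.dr
    rp2 = (r + dr / 2.0) ** 2
    rm2 = (r - dr / 2.0) ** 2
    inv_r2dr2 = 1.0 / (r**2 * dr**2)
    return rp2, rm2, inv_r2dr2


def _advance_inplace(state: FieldState, bulk, coating: CoatingSpec,
                     grid: GridSpec, kinetics: KineticConstants,
                     n_sub: int) -> None:
    ch_b, o2_b = bulk
    if ch_b < 0 or o2_b < 0:
        raise ValueError("bulk concentrations must be non-negative")
    rp2, rm2, inv_r2dr2 = _geometry(state)
    kf, kr, k1, k2, k3, k4, k5 = kinetics.as_uM_tuple()
    neg_tol = 1e-9 * max(1.0, ch_b, o2_b, coating.e0)
    status = _kernel.advance(
        state.ch, state.o2, state.h2o2, state.enzymes,
        rp2, rm2, inv_r2dr2, grid.dt, n_sub,
        coating.d_ch_eff, coating.d_o2_eff, coating.d_h2o2_eff,
        kf, kr, k1, k2, k3, k4, k5, ch_b, o2_b, neg_tol,
    )
    if status != 0:
        raise NumericsError(
            f"negative concentration beyond tolerance at t~{state.t:.4f} s; "
            "the explicit scheme is unstable for these parameters"
        )
    state.t += n_sub * grid.dt


def step_state(state: FieldState, bulk, coating: CoatingSpec, grid: GridSpec,
               kinetics: KineticConstants) -> FieldState:
    """One explicit forward-Euler update; returns a new state."""
    grid.check(coating)
    out = state.copy()
    _advance_inplace(out, bulk, coating, grid, kinetics, 1)
    return out


def electrode_current(state: FieldState, coating: CoatingSpec,
                      kinetics: KineticConstants | None = None,
                      gradient: str = "spherical") -> float:
    """Electrode current (pA) from the H2O2 flux at the inner boundary.

    With H2O2 pinned to zero at the electrode the gradient is estimated from
    the first interior node.  ``gradient="spherical"`` (default) reconstructs
    the surface flux from the scheme's own conservative face flux,

        re^2 J(re) = (re + dr/2)^2 D (H1 - H0)/dr + re^2 q0 dr/2,

    where the second term (present when ``kinetics`` is supplied) restores
    the H2O2 produced between the electrode and the first flux face, which
    in steady state is oxidised at the electrode; this estimator is
    second-order convergent in dr.  ``gradient="two_point"`` is the plain
    one-sided difference re^2 D (H1 - H0)/dr.
    """
    if state.r.size < 2:
        raise ValueError("state needs at least two grid nodes")
    dr = state.dr
    a = coating.radius
    d = coating.d_h2o2_eff
    g = (state.h2o2[1] - state.h2o2[0]) / dr
    if gradient == "spherical":
        flux_a2 = (a + dr / 2.0) ** 2 * d * g
        if kinetics is not None:
            from .kinetics import h2o2_production

            q0 = float(h2o2_production(state.enzymes[:, :1], state.o2[0],
                                       kinetics)[0])
            flux_a2 += a**2 * q0 * dr / 2.0
        return CURRENT_PA_FACTOR * flux_a2
    if gradient != "two_point":
        raise ValueError("gradient must be 'spherical' or 'two_point'")
    return CURRENT_PA_FACTOR * a**2 * d * g


def h2o2_flux_balance(state: FieldState, coating: CoatingSpec,
                      kinetics: KineticConstants) -> dict:
    """Steady-state H2O2 budget: interior production vs boundary fluxes.

    Uses the scheme's own conservative half-node face fluxes, so at a
    discrete steady state production and efflux agree to discretisation
    error.  All quantities in mol-equivalent uM*um^3/s (4*pi shell).
    """
    from .kinetics import h2o2_production

    r, dr, h = state.r, state.dr, state.h2o2
    q = h2o2_production(state.enzymes, state.o2, kinetics)
    prod = float(np.sum(4 * np.pi * r[1:-1] ** 2 * q[1:-1] * dr))
    d = coating.d_h2o2_eff
    f_in = 4 * np.pi * (r[0] + dr / 2) ** 2 * d * (h[1] - h[0]) / dr
    f_out = 4 * np.pi * (r[-1] - dr / 2) ** 2 * d * (h[-2] - h[-1]) / dr
    rel_err = abs(prod - f_in - f_out) / prod if prod > 0 else 0.0
    return {"production": prod, "flux_inner": float(f_in),
            "flux_outer": float(f_out), "rel_err": float(rel_err)}


def _plateau(y: np.ndarray, dt: float, frac: float = 0.1):
    """Mean over the final ``frac`` of a hold window plus the relative slope
    (1/s) there, used to flag unsettled plateaus."""
    m = max(2, int(round(frac * y.size)))
    seg = y[-m:]
    value = float(seg.mean())
    tt = dt * np.arange(m)
    slope = float(np.polyfit(tt, seg, 1)[0])
    rel_slope = slope / value if value != 0 else 0.0
    return value, rel_slope


def run_protocol(protocol: BulkProtocol, coating: CoatingSpec, grid: GridSpec,
                 kinetics: KineticConstants, output_dt: float = 0.01,
                 keep_snapshots: bool = True, plateau_warn: bool = True,
                 state: FieldState | None = None,
                 gradient: str = "spherical") -> SimTrace:
    """Advance the PDE over the full bulk schedule.

    Current and inner-node concentrations are recorded every ``output_dt``;
    full profiles are stored every ``grid.snapshot_interval``.  A warning
    (not an error) is issued when the current has not plateaued within a
    hold window (relative slope > 0.1 %/s over its final 10 %).
    """
    grid.check(coating)
    n_sub = int(round(output_dt / grid.dt))
    if n_sub < 1 or abs(n_sub * grid.dt - output_dt) > 1e-9:
        raise ValueError("output_dt must be a multiple of grid.dt")
    if state is None:
        state = init_state(coating, grid, kinetics)
    n_out = int(round(protocol.t_end / output_dt))
    snap_every = max(1, int(round(grid.snapshot_interval / output_dt)))

    t = output_dt * np.arange(1, n_out + 1)
    current = np.empty(n_out)
    bulk_ch = np.empty(n_out)
    bulk_o2 = np.empty(n_out)
    s_ch = np.empty(n_out)
    s_o2 = np.empty(n_out)
    snapshots: list[FieldState] = [state.copy()] if keep_snapshots else []

    for m in range(n_out):
        bulk = protocol.bulk_at(t[m] - output_dt / 2)
        _advance_inplace(state, bulk, coating, grid, kinetics, n_sub)
        current[m] = electrode_current(state, coating, kinetics, gradient=gradient)
        bulk_ch[m], bulk_o2[m] = bulk
        s_ch[m] = state.ch[0]
        s_o2[m] = state.o2[0]
        if keep_snapshots and (m + 1) % snap_every == 0:
            snapshots.append(state.copy())

    if plateau_warn:
        edges = np.concatenate([protocol.times, [protocol.t_end]])
        for k in range(len(protocol.times)):
            i0 = int(round(edges[k] / output_dt))
            i1 = int(round(edges[k + 1] / output_dt))
            if i1 - i0 < 20:
                continue
            value, rel_slope = _plateau(current[i0:i1], output_dt)
            if value > 0 and abs(rel_slope) > 1e-3:
                warnings.warn(
                    f"current not plateaued in segment starting at "
                    f"{edges[k]:.1f} s (relative slope {rel_slope:.2e}/s)",
                    RuntimeWarning, stacklevel=2,
                )

    params = {
        "coating": vars(coating).copy() if not hasattr(coating, "__dataclass_fields__")
        else {f: getattr(coating, f) for f in coating.__dataclass_fields__},
        "grid": {f: getattr(grid, f) for f in grid.__dataclass_fields__},
        "kinetics": {f: getattr(kinetics, f) for f in kinetics.__dataclass_fields__},
        "gradient": gradient,
    }
    return SimTrace(t, current, bulk_ch, bulk_o2, s_ch, s_o2,
                    protocol.step_times.copy(), snapshots, params)


def run_until_saturation(coating: CoatingSpec, grid: GridSpec,
                         kinetics: KineticConstants, ch: float = 5.0,
                         o2_step: float = 1.0, hold: float = 60.0,
                         pre_hold: float = 300.0, sat_frac: float = 0.01,
                         max_steps: int = 80, output_dt: float = 0.01,
                         gradient: str = "spherical") -> SimTrace:
    """O2 staircase in ``o2_step`` increments until the tonic plateau gain of
    a further step falls below ``sat_frac`` of the maximum reached so far."""
    grid.check(coating)
    n_sub = int(round(output_dt / grid.dt))
    state = init_state(coating, grid, kinetics)

    chunks_t: list[np.ndarray] = []
    chunks: dict[str, list[np.ndarray]] = {k: [] for k in
                                           ("current", "bulk_ch", "bulk_o2", "s_ch", "s_o2")}
    step_times: list[float] = []
    t0 = 0.0

    def run_hold(o2_bulk: float, duration: float) -> float:
        nonlocal t0
        n_out = int(round(duration / output_dt))
        cur = np.empty(n_out)
        sch = np.empty(n_out)
        so2 = np.empty(n_out)
        for m in range(n_out):
            _advance_inplace(state, (ch, o2_bulk), coating, grid, kinetics, n_sub)
            cur[m] = electrode_current(state, coating, kinetics, gradient=gradient)
            sch[m] = state.ch[0]
            so2[m] = state.o2[0]
        chunks_t.append(t0 + output_dt * np.arange(1, n_out + 1))
        chunks["current"].append(cur)
        chunks["bulk_ch"].append(np.full(n_out, ch))
        chunks["bulk_o2"].append(np.full(n_out, o2_bulk))
        chunks["s_ch"].append(sch)
        chunks["s_o2"].append(so2)
        t0 += duration
        return _plateau(cur, output_dt)[0]

    run_hold(0.0, pre_hold)
    plateaus = []
    for k in range(1, max_steps + 1):
        step_times.append(t0)
        p = run_hold(k * o2_step, hold)
        plateaus.append(p)
        if len(plateaus) >= 2:
            gain = plateaus[-1] - plateaus[-2]
            imax = max(plateaus)
            if imax > 0 and gain < sat_frac * imax:
                break
    else:
        warnings.warn("saturation endpoint not reached within max_steps",
                      RuntimeWarning, stacklevel=2)

    params = {"ch": ch, "o2_step": o2_step, "hold": hold, "pre_hold": pre_hold,
              "sat_frac": sat_frac, "gradient": gradient}
    return SimTrace(
        np.concatenate(chunks_t), np.concatenate(chunks["current"]),
        np.concatenate(chunks["bulk_ch"]), np.concatenate(chunks["bulk_o2"]),
        np.concatenate(chunks["s_ch"]), np.concatenate(chunks["s_o2"]),
        np.asarray(step_times), [], params,
    )


def compute_delta_o2(trace: SimTrace, lag: float = 0.3) -> np.ndarray:
    """Initial rise of O2 at the electrode surface after each bulk step:
    surface O2 at (step time + lag) minus its value at the step time."""
    if trace.surface_o2 is None or trace.surface_o2.size == 0:
        raise ValueError("trace carries no surface-O2 record")
    if trace.output_dt > 0.1 + 1e-12:
        raise ValueError(
            f"surface record cadence {trace.output_dt} s too coarse for a "
            f"{lag} s lag (need <= 0.1 s)"
        )
    out = np.empty(trace.step_times.size)
    for k, ts in enumerate(trace.step_times):
        if ts + lag > trace.t[-1] + 1e-9:
            raise ValueError(f"no surface record bracketing step at {ts} s")
        v0 = np.interp(ts, trace.t, trace.surface_o2)
        v1 = np.interp(ts + lag, trace.t, trace.surface_o2)
        out[k] = v1 - v0
    return out
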