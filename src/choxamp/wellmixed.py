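"""Well-mixed (zero-dimensional) limit of the coated-sensor kinetics.

Ignoring diffusion and clamping both substrates to their bulk values, the
six enzyme states evolve as ordinary differential equations.  This model is
the fast-diffusion limit of the full reaction-diffusion sensor and is used
as an independent cross-check: in a thin coating with strongly up-scaled
diffusivities the PDE plateau current must approach the well-mixed
prediction.

The volumetric H2O2 production rate p (uM/s) is converted to an equivalent
electrode current through the analytic steady diffusion profile of a
uniform source in the shell [a, b] with H2O2 = 0 at both boundaries,

    c(r) = -p r^2 / (6 D) + C1 + C2 / r,
    dc/dr|_a = p (b - a)(b + 2a) / (6 D a),

so I = 2 F (pi a^2) D dc/dr|_a = 2 F pi a p (b - a)(b + 2a) / 6 —
independent of D, as any steady-state flux split must be.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import KineticConstants
from .sensor import CURRENT_PA_FACTOR, CoatingSpec


class WellMixedModel:
    """ODE model of the six enzyme states with clamped substrates."""

    def __init__(self, kinetics: KineticConstants, coating: CoatingSpec):
        self.kinetics = kinetics
        self.coating = coating

    # -- dynamics --------------------------------------------------------
    def rhs(self, y: np.ndarray, ch: float, o2: float) -> np.ndarray:
        kf, kr, k1, k2, k3, k4, k5 = self.kinetics.as_uM_tuple()
        e, ech, erba, eoba, ergb, eogb = y
        bind, unbind = kf * e * ch, kr * ech
        r1, r2 = k1 * ech, k2 * erba * o2
        r3, r4, r5 = k3 * eoba, k4 * ergb * o2, k5 * eogb
        return np.array([
            -bind + unbind + r5,
            bind - unbind - r1,
            r1 - r2,
            r2 - r3,
            r3 - r4,
            r4 - r5,
        ])

    def integrate(self, ch: float, o2: float, t_end: float,
                  y0: np.ndarray | None = None, rtol: float = 1e-10,
                  atol: float = 1e-12) -> np.ndarray:
        """Enzyme state after ``t_end`` s at clamped substrates (stiff solver)."""
        if y0 is None:
            y0 = np.zeros(6)
            y0[0] = self.coating.e0
        sol = solve_ivp(lambda t, y: self.rhs(y, ch, o2), (0.0, t_end), y0,
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return sol.y[:, -1]

    def steady_state(self, ch: float, o2: float) -> np.ndarray:
        """Stationary enzyme distribution by direct linear solve.

        At clamped substrates the stationarity conditions are linear in the
        six enzyme states; five rate balances plus mass conservation give a
        unique solution whenever the cycle can turn over (ch, o2 > 0).
        """
        e0 = self.coating.e0
        if ch <= 0 or o2 <= 0:
            # cycle blocked: mass piles into EredBA (if Ch present) or stays free
            y = np.zeros(6)
            y[2 if ch > 0 else 0] = e0
            return y
        kf, kr, k1, k2, k3, k4, k5 = self.kinetics.as_uM_tuple()
        a = np.zeros((6, 6))
        a[0] = [kf * ch, -(kr + k1), 0, 0, 0, 0]       # d ECh = 0
        a[1] = [0, k1, -k2 * o2, 0, 0, 0]              # d EredBA = 0
        a[2] = [0, 0, k2 * o2, -k3, 0, 0]              # d EoxBA = 0
        a[3] = [0, 0, 0, k3, -k4 * o2, 0]              # d EredGB = 0
        a[4] = [0, 0, 0, 0, k4 * o2, -k5]              # d EoxGB = 0
        a[5] = [1, 1, 1, 1, 1, 1]                      # conservation
        b = np.zeros(6)
        b[5] = e0
        return np.linalg.solve(a, b)

    # -- observables -----------------------------------------------------
    def production_rate(self, y: np.ndarray, o2: float) -> float:
        """Volumetric H2O2 production (uM/s) of enzyme state ``y``."""
        kin = self.kinetics
        return float((kin.k2_uM * y[2] + kin.k4_uM * y[4]) * o2)

    def equivalent_current(self, production: float) -> float:
        """pA equivalent of a uniform volumetric source in the coating shell."""
        a = self.coating.radius
        b = a + self.coating.thickness
        # I = 2 F pi a^2 D c'(a); a^2 * c'(a) * D = p a (b-a)(b+2a)/6
        return CURRENT_PA_FACTOR * production * a * (b - a) * (b + 2 * a) / 6.0

    def plateau_current(self, ch: float, o2: float) -> float:
        """Steady-state equivalent current at clamped bulk substrates."""
        y = self.steady_state(ch, o2)
        return self.equivalent_current(self.production_rate(y, o2))

    def turnover_per_enzyme(self, ch: float, o2: float) -> float:
        """Catalytic cycles per second per enzyme at steady state
        (H2O2 production / 2, two molecules per cycle)."""
        y = self.steady_state(ch, o2)
        return self.production_rate(y, o2) / (2.0 * self.coating.e0)
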