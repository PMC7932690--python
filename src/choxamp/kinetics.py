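"""Two-substrate choline-oxidase kinetics.

Choline oxidase (ChOx) converts choline (Ch) + O2 to betaine aldehyde /
glycine betaine + H2O2 through a ping-pong cycle of the FAD prosthetic
group.  Six enzyme states are tracked:

    E + Ch  <-> ECh            (kf / kr, binding equilibrium)
    ECh      -> EredBA         (k1, first reductive chemical step)
    EredBA + O2 -> EoxBA + H2O2  (k2)
    EoxBA    -> EredGB         (k3, second chemical step)
    EredGB + O2 -> EoxGB + H2O2  (k4)
    EoxGB    -> E + GB         (k5, product release)

Free betaine-aldehyde and glycine-betaine pools are not tracked: their
kinetics do not feed back onto any tracked species or onto the sensor
current.

Units: bimolecular constants are stored as published (M^-1 s^-1) and
converted to the package-internal uM-um-s system (1 M^-1 s^-1 =
1e-6 uM^-1 s^-1) where consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: index order of the enzyme-state axis used throughout the package
ENZYME_STATES = ("E", "ECh", "EredBA", "EoxBA", "EredGB", "EoxGB")


@dataclass(frozen=True)
class KineticConstants:
    """Rate constants of the ChOx catalytic cycle.

    Defaults are the literature values used for the biosensor model:
    kf 2e6 M^-1 s^-1, kr 580 s^-1, k1 93 s^-1, k2 8.64e4 M^-1 s^-1,
    k3 135 s^-1, k4 5.34e4 M^-1 s^-1, k5 200 s^-1.
    """

    kf: float = 2.0e6   # M^-1 s^-1, Ch binding
    kr: float = 580.0   # s^-1, Ch unbinding
    k1: float = 93.0    # s^-1, FAD reduction (Ch -> betaine aldehyde)
    k2: float = 8.64e4  # M^-1 s^-1, first O2 oxidation (H2O2 release)
    k3: float = 135.0   # s^-1, FAD reduction by betaine aldehyde
    k4: float = 5.34e4  # M^-1 s^-1, second O2 oxidation (H2O2 release)
    k5: float = 200.0   # s^-1, glycine betaine release

    def __post_init__(self) -> None:
        for name in ("kf", "kr", "k1", "k2", "k3", "k4", "k5"):
            if not getattr(self, name) > 0:
                raise ValueError(f"kinetic constant {name} must be strictly positive")

    # -- uM-unit views (internal unit system is uM-um-s) -----------------
    @property
    def kf_uM(self) -> float:
        """Binding rate in uM^-1 s^-1."""
        return self.kf * 1e-6

    @property
    def k2_uM(self) -> float:
        return self.k2 * 1e-6

    @property
    def k4_uM(self) -> float:
        return self.k4 * 1e-6

    def as_uM_tuple(self) -> tuple[float, ...]:
        """(kf, kr, k1, k2, k3, k4, k5) with bimolecular rates in uM^-1 s^-1."""
        return (self.kf_uM, self.kr, self.k1, self.k2_uM, self.k3, self.k4_uM, self.k5)


def reaction_rates(enz: np.ndarray, ch, o2, kin: KineticConstants):
    """Elementary reaction fluxes for enzyme states ``enz`` (shape (6, ...)).

    Returns the tuple (bind, unbind, r1, r2, r3, r4, r5) in uM/s, evaluated
    with concentrations in uM.
    """
    kf, kr, k1, k2, k3, k4, k5 = kin.as_uM_tuple()
    e, ech, erba, eoba, ergb, eogb = enz
    bind = kf * e * ch
    unbind = kr * ech
    r1 = k1 * ech
    r2 = k2 * erba * o2
    r3 = k3 * eoba
    r4 = k4 * ergb * o2
    r5 = k5 * eogb
    return bind, unbind, r1, r2, r3, r4, r5


def enzyme_derivatives(enz: np.ndarray, ch, o2, kin: KineticConstants) -> np.ndarray:
    """d/dt of the six enzyme states (sums to zero exactly: mass conservation)."""
    bind, unbind, r1, r2, r3, r4, r5 = reaction_rates(enz, ch, o2, kin)
    return np.stack(
        [
            -bind + unbind + r5,
            bind - unbind - r1,
            r1 - r2,
            r2 - r3,
            r3 - r4,
            r4 - r5,
        ]
    )


def h2o2_production(enz: np.ndarray, o2, kin: KineticConstants):
    """Volumetric H2O2 production rate (uM/s): (k2*EredBA + k4*EredGB) * O2."""
    return (kin.k2_uM * enz[2] + kin.k4_uM * enz[4]) * o2
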