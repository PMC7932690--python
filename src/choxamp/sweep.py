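"""Coating-parameter sweeps of the simulated sensor's O2 dependence.

For each (thickness, enzyme concentration) cell a fine-step O2 staircase is
run until tonic saturation and summarised by: the apparent Michaelis
constant of the tonic response (KmO2app), the normalised maximal phasic
response (highest phasic peak / maximal cumulative tonic response Imax),
and the tonic saturation level at which that maximal phasic peak occurs.
Raising either enzyme loading axis lowers KmO2app and amplifies the phasic
peaks — the two components of O2 dependence are mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import fit_michaelis_menten, step_responses_from_trace
from .kinetics import KineticConstants
from .sensor import CoatingSpec, GridSpec, run_until_saturation


@dataclass
class SweepCell:
    thickness: float
    e0: float
    km_app: float
    norm_max_phasic: float
    saturation_at_max_phasic: float
    imax: float
    n_steps: int


@dataclass
class SweepResult:
    thicknesses: np.ndarray
    enzyme_concs: np.ndarray
    km_app: np.ndarray                     # (n_thick, n_e0)
    norm_max_phasic: np.ndarray
    saturation_at_max_phasic: np.ndarray
    cells: list = field(default_factory=list)
    errors: list = field(default_factory=list)  # (thickness, e0, message)


def summarize_calibration(trace) -> dict:
    """Tonic KmO2app, normalised max phasic and its tonic-saturation level
    from a fine-step staircase trace."""
    sr = step_responses_from_trace(trace)
    mm = fit_michaelis_menten(sr.o2_baseline, sr.tonic)
    imax = float(sr.tonic.max())
    k = int(np.argmax(sr.phasic))
    return {
        "km_app": float(mm.km),
        "imax": imax,
        "norm_max_phasic": float(sr.phasic[k] / imax) if imax > 0 else np.nan,
        "saturation_at_max_phasic": float(sr.tonic[k] / imax) if imax > 0 else np.nan,
        "responses": sr,
        "mm_fit": mm,
    }


def sweep_coatings(thicknesses, enzyme_concs,
                   kinetics: KineticConstants | None = None,
                   coating_base: CoatingSpec | None = None,
                   grid: GridSpec | None = None,
                   **protocol_kwargs) -> SweepResult:
    """Run the fine-step saturation protocol over a coating-parameter grid.

    Individual cell failures are recorded in ``errors`` (NaN in the maps)
    and the sweep continues.  ``protocol_kwargs`` are forwarded to
    :func:`choxamp.sensor.run_until_saturation`.
    """
    thicknesses = np.asarray(thicknesses, float)
    enzyme_concs = np.asarray(enzyme_concs, float)
    if thicknesses.size < 2 or enzyme_concs.size < 2:
        raise ValueError("need at least 2 values per sweep axis")
    kinetics = kinetics or KineticConstants()
    coating_base = coating_base or CoatingSpec(thickness=float(thicknesses[0]))
    grid = grid or GridSpec()

    shape = (thicknesses.size, enzyme_concs.size)
    km = np.full(shape, np.nan)
    nmp = np.full(shape, np.nan)
    sat = np.full(shape, np.nan)
    cells: list[SweepCell] = []
    errors: list[tuple] = []

    for i, thick in enumerate(thicknesses):
        for j, e0 in enumerate(enzyme_concs):
            coating = replace(coating_base, thickness=float(thick), e0=float(e0))
            try:
                trace = run_until_saturation(coating, grid, kinetics,
                                             **protocol_kwargs)
                s = summarize_calibration(trace)
            except Exception as exc:
                errors.append((float(thick), float(e0), repr(exc)))
                continue
            km[i, j] = s["km_app"]
            nmp[i, j] = s["norm_max_phasic"]
            sat[i, j] = s["saturation_at_max_phasic"]
            cells.append(SweepCell(float(thick), float(e0), s["km_app"],
                                   s["norm_max_phasic"],
                                   s["saturation_at_max_phasic"],
                                   s["imax"], len(s["responses"])))
    return SweepResult(thicknesses, enzyme_concs, km, nmp, sat, cells, errors)
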