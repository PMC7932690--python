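"""Synthetic-data generators with machine-readable ground truth.

Every input the analysis chain consumes can be produced here with exactly
known structure: staircase calibration traces, four-channel tetrode
amperometry with a common-mode LFP-like artifact passed through per-channel
transfer functions, slow O2/COA components with a selectable coupling rule,
interferent (dopamine) events, ripple-bearing LFP and locomotion speed
traces.  Generators are deterministic under a fixed seed and return a
``truth`` dict alongside the data; downstream recovery tests read ground
truth only from that record.

The artifact model is a sum of narrowband Gaussian processes spanning
1-20 Hz with 1/f amplitude weighting — it resembles LFP pick-up
statistically without claiming physiological realism.  The "phasic"
COA-from-O2 coupling is a two-path model: a (optionally saturating) slow
path plus a fast derivative path that vanishes for slow inputs; it
reproduces the in vivo signatures of a non-steady-state O2 dependence
(negative-lag drift, amplitude-ratio decay with O2 rise time) with exactly
known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .calibration import hill as hill_curve
from .calibration import michaelis_menten as mm_curve
from .cleaning import MultiChannelRecording
from .events import _bandpass

#: Ch sensitivities per site type, pA/uM (tetrode-site population means)
CH_SENSITIVITY = {"AuPt_mPD": 2.45, "AuPt": 2.54, "Au_mPD": 0.27, "Au": 0.25}
#: dopamine sensitivities per site type, pA/uM
DA_SENSITIVITY = {"AuPt_mPD": 0.15, "AuPt": 7.48, "Au_mPD": 0.13, "Au": 8.24}


def _alpha_bump(t: np.ndarray, onset: float, amplitude: float, tau: float):
    """Alpha-function transient peaking ``tau`` s after onset with unit peak."""
    x = np.clip((t - onset) / tau, 0.0, 60.0)
    w = x * np.exp(1.0 - x)
    return amplitude * w


def band_limited_noise(rng, n: int, fs: float, f_lo: float = 1.0,
                       f_hi: float = 20.0, sd: float = 1.0) -> np.ndarray:
    """Gaussian noise confined to [f_lo, f_hi] with 1/f amplitude weighting,
    scaled to standard deviation ``sd``."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(f)
    band = (f >= f_lo) & (f <= f_hi)
    amp[band] = f_lo / f[band]
    x = np.fft.irfft(spec * amp, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _apply_channel_transfer(source: np.ndarray, fs: float, gain: float,
                            delay: float) -> np.ndarray:
    """Linear per-channel pick-up: scale plus constant delay (phase ramp)."""
    spec = np.fft.rfft(source)
    f = np.fft.rfftfreq(len(source), 1.0 / fs)
    return np.fft.irfft(spec * gain * np.exp(-2j * np.pi * f * delay),
                        n=len(source))


# ---------------------------------------------------------------------------
# calibration traces
# ---------------------------------------------------------------------------

def gen_calibration_trace(model: str = "mm", params: dict | None = None,
                          conc_step: float = 5.0, n_steps: int = 6,
                          hold: float = 60.0, baseline: float = 30.0,
                          fs: float = 10.0, noise_sd: float = 0.0,
                          phasic_amps=None, phasic_tau: float = 2.0,
                          rise_tau: float = 0.0, seed: int | None = 0):
    """Staircase calibration from a known saturation model.

    Plateaus follow ``model`` ("mm": Imax*x/(Km+x) with params km/imax;
    "hill": params k05/n/imax) at the cumulative concentration after each
    step; optional per-step decaying-exponential phasic transients of known
    amplitude and white noise are added.  Step edges fall exactly on
    samples, so with ``rise_tau=0`` the injected phasic amplitudes are
    recovered exactly by peak-minus-plateau extraction.

    Returns ``(t, y, step_times, truth)``.
    """
    params = dict(params or ({"km": 0.97, "imax": 13.2} if model == "mm"
                             else {"k05": 8.6, "n": 2.31, "imax": 22.4}))
    rng = np.random.default_rng(seed)
    n = int(round((baseline + n_steps * hold) * fs))
    t = np.arange(n) / fs
    step_times = baseline + hold * np.arange(n_steps)
    conc = conc_step * np.arange(1, n_steps + 1)
    if model == "mm":
        plateaus = mm_curve(conc, params["imax"], params["km"])
    elif model == "hill":
        plateaus = hill_curve(conc, params["imax"], params["k05"], params["n"])
    else:
        raise ValueError("model must be 'mm' or 'hill'")

    y = np.zeros(n)
    prev = 0.0
    for ts, plat in zip(step_times, plateaus):
        inc = plat - prev
        if rise_tau > 0:
            y += np.where(t >= ts, inc * (1 - np.exp(-(t - ts) / rise_tau)), 0.0)
        else:
            y += np.where(t >= ts, inc, 0.0)
        prev = plat
    if phasic_amps is not None:
        for ts, amp in zip(step_times, phasic_amps):
            y += np.where(t >= ts, amp * np.exp(-(t - ts) / phasic_tau), 0.0)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, n)
    truth = {"model": model, "params": params, "conc_step": conc_step,
             "plateaus": plateaus, "phasic_amps": phasic_amps,
             "phasic_tau": phasic_tau, "noise_sd": noise_sd, "seed": seed}
    return t, y, step_times, truth


# ---------------------------------------------------------------------------
# slow O2/COA components and coupling rules
# ---------------------------------------------------------------------------

def apply_coupling(o2: np.ndarray, fs: float, coupling: tuple) -> np.ndarray:
    """COA trace (uM Ch-equivalent) from an O2 trace under a coupling rule.

    ``coupling`` is ("linear", {"gain"}), ("saturating", {"vmax","km"}) or
    ("phasic", {"ks","kf","delay","km"}) — slow path ks (delayed, optionally
    saturating with half-constant km) plus fast derivative path kf (s).
    """
    kind, p = coupling
    if kind == "linear":
        return p["gain"] * o2
    if kind == "saturating":
        return p["vmax"] * o2 / (p["km"] + o2)
    if kind == "phasic":
        slow = o2 if not p.get("km") else o2 / (1.0 + o2 / p["km"])
        shift = int(round(p.get("delay", 0.0) * fs))
        if shift:
            slow = np.concatenate([np.full(shift, slow[0]), slow[:-shift]])
        fast = p["kf"] * np.gradient(o2, 1.0 / fs)
        return p["ks"] * slow + fast
    raise ValueError(f"unknown coupling kind {kind!r}")


def gen_o2_events(rng, duration: float, t_start: float = 200.0,
                  t_stop: float | None = None, n_events: int = 16,
                  rise_range=(1.0, 12.0), amp_per_rise: float = 0.6,
                  amp_jitter: float = 0.1):
    """Schedule O2 transients with rise times log-spaced over ``rise_range``
    and amplitude approximately proportional to rise time."""
    t_stop = duration - 40.0 if t_stop is None else t_stop
    onsets = np.linspace(t_start, t_stop, n_events)
    rises = np.exp(rng.permutation(np.linspace(np.log(rise_range[0]),
                                               np.log(rise_range[1]), n_events)))
    amps = amp_per_rise * rises * (1.0 + amp_jitter * rng.uniform(-1, 1, n_events))
    return [{"onset": float(o), "amplitude": float(a), "rise": float(r)}
            for o, a, r in zip(onsets, amps, rises)]


def gen_slow_signals(duration: float, fs: float, o2_events,
                     coupling=("linear", {"gain": 0.5}),
                     coa_events=(), noise_sd: float = 0.0,
                     seed: int | None = 0):
    """O2 and COA component traces (uM) from scheduled transients plus the
    coupling rule; independent COA (cholinergic) events can be superposed.

    Returns ``(t, o2, coa, truth)``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    o2 = np.zeros(n)
    for ev in o2_events:
        o2 += _alpha_bump(t, ev["onset"], ev["amplitude"], ev["rise"])
    coa = apply_coupling(o2, fs, coupling)
    for ev in coa_events:
        coa += _alpha_bump(t, ev["onset"], ev["amplitude"], ev["rise"])
    if noise_sd > 0:
        o2 = o2 + rng.normal(0, noise_sd, n)
        coa = coa + rng.normal(0, noise_sd, n)
    truth = {"o2_events": list(o2_events), "coa_events": list(coa_events),
             "coupling": [coupling[0], dict(coupling[1])],
             "noise_sd": noise_sd, "seed": seed}
    return t, o2, coa, truth


# ---------------------------------------------------------------------------
# four-channel recordings
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """Full parameterisation of a synthetic four-channel recording."""

    duration: float = 600.0
    fs: float = 1000.0
    seed: int = 0
    # common-mode artifact and per-channel pick-up mismatch; the band reaches
    # below 0.3 Hz-adjacent frequencies so the |T| extrapolation has a real
    # artifact trend to follow, as for LFP pick-up
    artifact_band: tuple = (0.3, 20.0)
    artifact_sd: float = 50.0          # pA on the source process
    channel_gains: dict = field(default_factory=lambda: {
        "AuPt_mPD": 1.00, "AuPt": 1.10, "Au_mPD": 0.90, "Au": 1.05})
    channel_delays: dict = field(default_factory=lambda: {
        "AuPt_mPD": 0.000, "AuPt": 0.002, "Au_mPD": 0.004, "Au": 0.003})
    # site sensitivities
    ch_sensitivity: dict = field(default_factory=lambda: dict(CH_SENSITIVITY))
    da_sensitivity: dict = field(default_factory=lambda: dict(DA_SENSITIVITY))
    o2_sensitivity: float = 2.0        # pA/uM on the -0.2 V site
    noise_sd: float = 0.5              # pA white noise per channel
    # programmed chemistry
    o2_mode: bool = True               # Au held at -0.2 V (O2 measurement)
    o2_events: list | None = None      # None -> auto schedule
    coa_events: list = field(default_factory=list)
    da_events: list = field(default_factory=list)
    coupling: tuple = ("phasic", {"ks": 0.3, "kf": 1.0, "delay": 0.3, "km": None})
    # ripple bursts embedded in the common-mode source
    ripple_times: list = field(default_factory=list)
    ripple_amp: float = 10.0
    ripple_freq: float = 150.0
    ripple_cycles: int = 8
    # artifact-rich, analyte-poor epochs for transfer estimation
    reference_windows: list = field(default_factory=lambda: [(5.0, 185.0)])

    @classmethod
    def standard(cls, seed: int = 0) -> "ScenarioSpec":
        """The default in vivo-like scenario used by the acceptance checks."""
        return cls(seed=seed)


def gen_multichannel_recording(spec: ScenarioSpec):
    """Generate a four-channel recording per ``spec``.

    channel = per-channel artifact + sensitivity-weighted chemistry + noise;
    COA appears on +0.6 V channels weighted by Ch sensitivity, O2 only on
    the -0.2 V Au site, dopamine per site DA sensitivity (suppressed by
    m-PD).  Returns ``(MultiChannelRecording, truth)`` with every component
    stored separately in the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    source = band_limited_noise(rng, n, spec.fs, *spec.artifact_band,
                                sd=spec.artifact_sd)
    for tc in spec.ripple_times:
        sigma = spec.ripple_cycles / spec.ripple_freq / 6.0
        source += (spec.ripple_amp * np.exp(-0.5 * ((t - tc) / sigma) ** 2)
                   * np.sin(2 * np.pi * spec.ripple_freq * (t - tc)))

    o2_events = spec.o2_events
    if o2_events is None:
        ref_end = max(t1 for _, t1 in spec.reference_windows)
        o2_events = gen_o2_events(rng, spec.duration, t_start=ref_end + 20.0)
    _, o2, coa, slow_truth = gen_slow_signals(
        spec.duration, spec.fs, o2_events, spec.coupling, spec.coa_events,
        noise_sd=0.0, seed=spec.seed + 1)
    da = np.zeros(n)
    for ev in spec.da_events:
        da += _alpha_bump(t, ev["onset"], ev["amplitude"], ev["rise"])

    channels: dict[str, np.ndarray] = {}
    artifacts: dict[str, np.ndarray] = {}
    potentials: dict[str, float] = {}
    for site in ("AuPt_mPD", "AuPt", "Au_mPD", "Au"):
        art = _apply_channel_transfer(source, spec.fs,
                                      spec.channel_gains[site],
                                      spec.channel_delays[site])
        artifacts[site] = art
        chem = np.zeros(n)
        if site == "Au" and spec.o2_mode:
            chem += spec.o2_sensitivity * o2
            potentials[site] = -0.2
        else:
            chem += spec.ch_sensitivity[site] * coa
            chem += spec.da_sensitivity[site] * da
            potentials[site] = 0.6
        channels[site] = art + chem + rng.normal(0, spec.noise_sd, n)

    rec = MultiChannelRecording(spec.fs, channels, potentials,
                                meta={"scenario_seed": spec.seed,
                                      "reference_windows": list(spec.reference_windows)})
    truth = {
        "spec": asdict(spec),
        "o2": o2, "coa": coa, "da": da, "artifact_source": source,
        "artifacts": artifacts, "o2_events": o2_events,
        "slow": slow_truth,
        "reference_windows": list(spec.reference_windows),
        # true pairwise transfer (target over sentinel) for each default pair
        "pair_transfer": {
            name: {"gain": spec.channel_gains[tg] / spec.channel_gains[st],
                   "delay": spec.channel_delays[tg] - spec.channel_delays[st]}
            for name, (tg, st) in (("COA_mPD", ("AuPt_mPD", "Au_mPD")),
                                   ("COA_non_mPD", ("AuPt", "Au")),
                                   ("O2", ("Au", "Au_mPD")),
                                   ("NCC", ("Au", "Au_mPD")))
        },
    }
    return rec, truth


# ---------------------------------------------------------------------------
# LFP and speed
# ---------------------------------------------------------------------------

def gen_lfp_with_ripples(burst_times, duration: float, fs: float = 1000.0,
                         snr: float = 5.0, f0: float = 150.0,
                         n_cycles: int = 8, seed: int | None = 0):
    """Pink-noise LFP with Gaussian-windowed ripple bursts at known times.

    ``snr`` is the burst peak amplitude divided by the SD of the background
    noise within the 120-200 Hz detection band.  Returns ``(lfp, truth)``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.ones_like(f)
    amp[1:] = 1.0 / np.maximum(f[1:], 1.0)
    lfp = np.fft.irfft(spec * amp, n=n)
    lfp /= lfp.std()

    band_sd = _bandpass(lfp, fs, 120.0, 200.0).std()
    burst_amp = snr * band_sd
    # tapered-flat (Tukey) envelope: ripples hold amplitude over most cycles
    from scipy.signal.windows import tukey

    nb = int(round(n_cycles / f0 * fs))
    env = tukey(nb, 0.4)
    burst_times = np.asarray(burst_times, float)
    for tc in burst_times:
        i0 = int(round(tc * fs)) - nb // 2
        if i0 < 0 or i0 + nb > n:
            continue
        tt = t[i0:i0 + nb]
        lfp[i0:i0 + nb] += burst_amp * env * np.sin(2 * np.pi * f0 * (tt - tc))
    truth = {"burst_times": burst_times, "snr": snr, "f0": f0,
             "n_cycles": n_cycles, "burst_amp": float(burst_amp),
             "band_sd": float(band_sd), "seed": seed}
    return lfp, truth


def gen_speed_trace(bout_times, duration: float, fs: float = 1.0,
                    amp: float = 10.0, width: float = 10.0,
                    jitter_sd: float = 0.2, seed: int | None = 0):
    """Non-negative locomotion speed: baseline jitter plus Gaussian bouts of
    ``width`` s (SD = width/2.355, i.e. FWHM = width) at known times."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    speed = np.abs(rng.normal(0.0, jitter_sd, n))
    sigma = width / 2.355
    bout_times = np.asarray(bout_times, float)
    for tc in bout_times:
        speed += amp * np.exp(-0.5 * ((t - tc) / sigma) ** 2)
    truth = {"bout_times": bout_times, "amp": amp, "width": width,
             "jitter_sd": jitter_sd, "seed": seed}
    return speed, truth
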