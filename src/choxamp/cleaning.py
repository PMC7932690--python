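"""Frequency-domain common-mode rejection for multichannel amperometry.

LFP and movement pick-up appears on every tetrode site with slightly
different, frequency-dependent amplitude and phase (impedance mismatch).  A
complex per-frequency transfer coefficient T from the pseudo-sentinel to
the signal-carrying channel is estimated on artifact-rich, analyte-poor
reference epochs; the cleaned signal is then

    clean = iFFT( target(jw) - T(jw) * sentinel(jw) ),

computed in overlapping tapered windows with overlap-add.  |T| per bin is
sqrt of the power ratio between channels; the phase comes from the averaged
cross-spectrum, restricted to bins whose phase-locking value exceeds 0.9
(phase interpolated from neighbouring passing bins elsewhere).  Below
0.3 Hz the slow electrochemical signal itself contributes power to the
target channel, so |T| there is replaced by a linear extrapolation of the
trend fitted over the contiguous 0.3-1.0 Hz band.

Four differential outputs are supported: COA from the m-PD pair, COA from
the unpolymerised pair, O2 (Au site at -0.2 V vs the m-PD sentinel) and the
neurochemical-confounds signal NCC (Au at +0.6 V vs the m-PD sentinel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

SITE_TYPES = ("AuPt_mPD", "AuPt", "Au_mPD", "Au")

#: differential pairs: name -> (target site, sentinel site)
DEFAULT_PAIRING = {
    "COA_mPD": ("AuPt_mPD", "Au_mPD"),
    "COA_non_mPD": ("AuPt", "Au"),
    "O2": ("Au", "Au_mPD"),    # only when the Au site is held at -0.2 V
    "NCC": ("Au", "Au_mPD"),   # only when the Au site is held at +0.6 V
}


class CleaningError(RuntimeError):
    pass


@dataclass
class MultiChannelRecording:
    """Four amperometric current traces (pA) with per-site metadata."""

    fs: float
    channels: dict                  # site label -> np.ndarray
    potentials: dict = field(default_factory=dict)  # site label -> V vs Ag/AgCl
    aux: dict = field(default_factory=dict)         # e.g. {"speed": (fs, arr)}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lens = {len(v) for v in self.channels.values()}
        if len(lens) > 1:
            raise ValueError("channels must have equal length")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("site labels must be unique")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def o2_site(self) -> str | None:
        """Site measuring O2 (held near -0.2 V), if any."""
        for site, v in self.potentials.items():
            if v < 0:
                return site
        return None


@dataclass
class TransferFunction:
    """Per-frequency complex gain from sentinel to target channel."""

    freqs: np.ndarray
    gain: np.ndarray
    phase: np.ndarray               # rad, in (-pi, pi]
    plv: np.ndarray                 # phase-locking value per bin, [0, 1]
    extrapolated_mask: np.ndarray   # True where |T| was extrapolated (<0.3 Hz)
    nperseg: int = 0
    fs: float = 0.0
    meta: dict = field(default_factory=dict)

    def complex_gain(self) -> np.ndarray:
        return self.gain * np.exp(1j * self.phase)


@dataclass
class CleanedSignals:
    """Differential signals at full rate plus the low-passed/downsampled view."""

    fs: float
    full: dict                      # name -> full-rate cleaned trace
    fs_out: float
    out: dict                       # name -> 1 Hz low-passed, fs_out-sampled
    pairing: dict = field(default_factory=dict)


def _windowed_segments(x: np.ndarray, fs: float, windows, nperseg: int, hop: int):
    if windows is None:
        windows = [(0.0, len(x) / fs)]
    for t0, t1 in windows:
        i0 = max(0, int(round(t0 * fs)))
        i1 = min(len(x), int(round(t1 * fs)))
        for s in range(i0, i1 - nperseg + 1, hop):
            yield s


def estimate_transfer(rec: MultiChannelRecording, target: str, sentinel: str,
                      reference_windows=None, window_s: float = 20.0,
                      plv_threshold: float = 0.9, extrap_below: float = 0.3,
                      extrap_band: tuple = (0.3, 1.0),
                      min_duration: float = 60.0) -> TransferFunction:
    """Estimate T between one channel pair on artifact-rich reference epochs.

    Hann windows of ``window_s`` seconds, 50 % overlap.  Raises
    :class:`CleaningError` when no frequency bin reaches the phase-locking
    threshold (no coherent common mode) or the reference epochs are shorter
    than ``min_duration`` seconds.
    """
    fs = rec.fs
    x_t = np.asarray(rec.channels[target], float)
    x_s = np.asarray(rec.channels[sentinel], float)
    nperseg = int(round(window_s * fs))
    hop = nperseg // 2
    win = sps.get_window("hann", nperseg, fftbins=True)

    if reference_windows is not None:
        total = sum(t1 - t0 for t0, t1 in reference_windows)
    else:
        total = rec.duration
    if total < min_duration:
        raise CleaningError(
            f"reference epochs total {total:.1f} s < required {min_duration} s")

    starts = list(_windowed_segments(x_t, fs, reference_windows, nperseg, hop))
    if len(starts) < 2:
        raise CleaningError("need at least two spectral windows")

    nf = nperseg // 2 + 1
    p_t = np.zeros(nf)
    p_s = np.zeros(nf)
    cross = np.zeros(nf, complex)
    phasor = np.zeros(nf, complex)
    for s in starts:
        ft = np.fft.rfft(win * sps.detrend(x_t[s:s + nperseg], type="constant"))
        fsent = np.fft.rfft(win * sps.detrend(x_s[s:s + nperseg], type="constant"))
        p_t += np.abs(ft) ** 2
        p_s += np.abs(fsent) ** 2
        c = ft * np.conj(fsent)
        cross += c
        mag = np.abs(c)
        mag[mag == 0] = 1.0
        phasor += c / mag
    k = len(starts)
    plv = np.abs(phasor) / k

    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.sqrt(p_t / p_s)
    gain[~np.isfinite(gain)] = 0.0
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)

    passing = plv > plv_threshold
    if not passing.any():
        raise CleaningError(
            "no frequency bin exceeds the phase-locking threshold "
            f"{plv_threshold} (plv median {np.median(plv):.3f}, "
            f"max {plv.max():.3f}); channels share no coherent common mode")
    raw_phase = np.angle(cross)
    idx = np.flatnonzero(passing)
    unwrapped = np.unwrap(raw_phase[idx])
    phase = np.interp(np.arange(nf), idx, unwrapped)
    phase = np.angle(np.exp(1j * phase))  # wrap back to (-pi, pi]

    lo, hi = extrap_band
    band = (freqs >= lo) & (freqs <= hi)
    low = freqs < extrap_below
    if band.sum() >= 2:
        coef = np.polyfit(freqs[band], gain[band], 1)
        gain[low] = np.clip(np.polyval(coef, freqs[low]), 0.0, None)
    extrapolated = low.copy()

    return TransferFunction(freqs, gain, phase, plv, extrapolated,
                            nperseg=nperseg, fs=fs,
                            meta={"window_s": window_s, "n_windows": k,
                                  "plv_threshold": plv_threshold,
                                  "extrap_below": extrap_below,
                                  "extrap_band": list(extrap_band),
                                  "target": target, "sentinel": sentinel})


def _ola_subtract(x_t: np.ndarray, x_s: np.ndarray, tcomp: np.ndarray,
                  nperseg: int) -> np.ndarray:
    """Overlap-add frequency-domain subtraction target - T*sentinel.

    Periodic Hann analysis windows at 50 % overlap satisfy the COLA
    condition, so the windowed pieces resum to the full-rate signal.
    """
    hop = nperseg // 2
    win = sps.get_window("hann", nperseg, fftbins=True)
    n = len(x_t)
    pad = nperseg
    xt = np.pad(x_t, pad, mode="reflect")
    xs = np.pad(x_s, pad, mode="reflect")
    out = np.zeros(len(xt))
    for s in range(0, len(xt) - nperseg + 1, hop):
        ft = np.fft.rfft(win * xt[s:s + nperseg])
        fsent = np.fft.rfft(win * xs[s:s + nperseg])
        out[s:s + nperseg] += np.fft.irfft(ft - tcomp * fsent, n=nperseg)
    return out[pad:pad + n]


def lowpass_resample(x: np.ndarray, fs: float, cutoff: float = 1.0,
                     fs_out: float = 10.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass then integer decimation."""
    sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    ratio = fs / fs_out
    step = int(round(ratio))
    if abs(step - ratio) < 1e-9 and step >= 1:
        return y[::step]
    up = int(round(fs_out))
    down = int(round(fs))
    return sps.resample_poly(y, up, down)


def default_pairing(rec: MultiChannelRecording) -> dict:
    """Differential pairs available given the channels and applied voltages."""
    pairing = {}
    have = rec.channels.keys()
    if "AuPt_mPD" in have and "Au_mPD" in have:
        pairing["COA_mPD"] = ("AuPt_mPD", "Au_mPD")
    if "AuPt" in have and "Au" in have and rec.potentials.get("Au", 0.6) > 0:
        pairing["COA_non_mPD"] = ("AuPt", "Au")
    if "Au" in have and "Au_mPD" in have:
        name = "O2" if rec.potentials.get("Au", 0.6) < 0 else "NCC"
        pairing[name] = ("Au", "Au_mPD")
    return pairing


def apply_cleaning(rec: MultiChannelRecording, transfer, pairing=None,
                   cutoff: float = 1.0, fs_out: float = 10.0) -> CleanedSignals:
    """Apply Eq-style frequency-domain subtraction to every requested pair.

    ``transfer`` is a single :class:`TransferFunction` (used for all pairs)
    or a dict mapping pair name to its own estimate.  Outputs are kept at
    full rate and additionally low-passed at ``cutoff`` and resampled to
    ``fs_out`` (use ``fs_out=100`` for lag analyses).
    """
    if pairing is None:
        pairing = default_pairing(rec)
    full: dict[str, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for name, (target, sentinel) in pairing.items():
        for site in (target, sentinel):
            if site not in rec.channels:
                raise CleaningError(f"channel {site} required for {name} is missing")
        tf = transfer[name] if isinstance(transfer, dict) else transfer
        if tf.nperseg and abs(tf.fs - rec.fs) > 1e-9:
            raise CleaningError("transfer function estimated at a different fs")
        tcomp = tf.complex_gain()
        cleaned = _ola_subtract(np.asarray(rec.channels[target], float),
                                np.asarray(rec.channels[sentinel], float),
                                tcomp, tf.nperseg)
        full[name] = cleaned
        out[name] = lowpass_resample(cleaned, rec.fs, cutoff, fs_out)
    return CleanedSignals(rec.fs, full, fs_out, out, dict(pairing))


def clean_recording(rec: MultiChannelRecording, reference_windows=None,
                    pairing=None, cutoff: float = 1.0, fs_out: float = 10.0,
                    **transfer_kwargs) -> tuple[CleanedSignals, dict]:
    """Estimate a per-pair transfer function and clean all available pairs."""
    if pairing is None:
        pairing = default_pairing(rec)
    transfers = {
        name: estimate_transfer(rec, target, sentinel, reference_windows,
                                **transfer_kwargs)
        for name, (target, sentinel) in pairing.items()
    }
    cleaned = apply_cleaning(rec, transfers, pairing, cutoff, fs_out)
    return cleaned, transfers


def band_power(x: np.ndarray, fs: float, f_lo: float = 1.0, f_hi: float = 20.0,
               window_s: float = 20.0) -> float:
    """Median Welch PSD over [f_lo, f_hi] — the artifact-suppression metric."""
    nperseg = min(len(x), int(round(window_s * fs)))
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    return float(np.median(psd[band]))
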