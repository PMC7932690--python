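"""Detection of SWRs, locomotion bouts and multi-band O2/COA transients.

Sharp-wave/ripples (SWRs) are 120-200 Hz oscillatory bursts: the band-passed
trace is squared, smoothed with a 4.2 ms SD / 42 ms wide Gaussian kernel and
its square root used as the power envelope; supra-98th-percentile segments
with at least five cycles lasting under 200 ms count as ripples.

Slow O2 and COA transients of variable time-scale are captured by a bank of
one-octave band-pass filters [f/2, f] with corner frequency f swept over
0.05-0.5 Hz.  Per band, peaks above half the maximal peak amplitude are
kept, COA peaks are paired to the nearest O2 peak within 0.75/f, and the
band is summarised by the peak-amplitude slope (linear fit of COA vs O2),
the lag distribution (COA peak minus O2 peak), and the trough-to-peak rise
time of the median peak-aligned O2 transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps
from scipy import stats


@dataclass
class EventSet:
    kind: str
    times: np.ndarray                    # event peak times (s)
    onsets: np.ndarray                   # s
    amplitudes: np.ndarray               # signal units
    durations: np.ndarray                # s
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TransientPairSet:
    corner_freq: float                   # Hz, band is [f/2, f]
    o2_peak_times: np.ndarray
    o2_amplitudes: np.ndarray
    coa_peak_times: np.ndarray
    coa_amplitudes: np.ndarray
    lags: np.ndarray                     # s, COA peak - O2 peak
    rise_time: float                     # s, trough-to-peak of median O2 transient
    slope: float                         # COA-vs-O2 amplitude slope (NaN if <3 pairs)

    def __len__(self) -> int:
        return self.lags.size


@dataclass
class CorrMap:
    window_sizes: np.ndarray
    lags: np.ndarray
    corr: np.ndarray                     # (n_windows, n_lags) Spearman rho
    pval: np.ndarray
    significant: np.ndarray              # pval <= alpha mask


@dataclass
class TriggeredAverage:
    t: np.ndarray                        # s, relative to event
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_used: int
    n_dropped: int
    amplitude: float = np.nan            # peak minus onset value
    onset_time: float = np.nan
    peak_time: float = np.nan


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 3):
    sos = sps.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def ripple_band_envelope(x: np.ndarray, fs: float, band=(120.0, 200.0),
                         sigma_s: float = 0.0042, width_s: float = 0.042):
    """(band-passed trace, smoothed power envelope) for ripple detection."""
    bp = _bandpass(x, fs, band[0], band[1])
    sigma = sigma_s * fs
    truncate = (width_s / 2.0) / sigma_s  # kernel half-width in sigmas
    sm = ndimage.gaussian_filter1d(bp**2, sigma, truncate=truncate)
    return bp, np.sqrt(sm)


def detect_swr(x: np.ndarray, fs: float, band=(120.0, 200.0),
               percentile: float = 98.0, min_cycles: int = 5,
               max_duration: float = 0.2, mask: np.ndarray | None = None) -> EventSet:
    """Detect sharp-wave/ripples on a wide-band trace (fs >= 1 kHz).

    ``mask`` optionally restricts the percentile-threshold estimation epoch
    (e.g. to NREM); detection itself always runs on the whole input.
    """
    if fs < 1000.0:
        raise ValueError("sampling rate too low for the 120-200 Hz ripple band")
    bp, env = ripple_band_envelope(x, fs, band)
    ref = env if mask is None else env[mask]
    thr = np.percentile(ref, percentile)

    above = env > thr
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        stops = np.concatenate([stops, [len(env)]])

    times, onsets, amps, durs, cycles = [], [], [], [], []
    for i0, i1 in zip(starts, stops):
        dur = (i1 - i0) / fs
        seg = bp[i0:i1]
        n_cycles = np.count_nonzero(np.diff(np.signbit(seg))) / 2.0
        if n_cycles >= min_cycles and dur < max_duration:
            ipk = i0 + int(np.argmax(env[i0:i1]))
            times.append(ipk / fs)
            onsets.append(i0 / fs)
            amps.append(env[ipk])
            durs.append(dur)
            cycles.append(n_cycles)
    return EventSet("swr", np.array(times), np.array(onsets), np.array(amps),
                    np.array(durs), {"cycles": np.array(cycles),
                                     "threshold": float(thr)})


def detect_locomotion_bouts(speed: np.ndarray, fs: float, threshold: float,
                            band=(0.02, 0.2)) -> EventSet:
    """Locomotion bouts: peaks of the 0.02-0.2 Hz band-passed speed above
    ``threshold``; onset is the preceding upward zero-crossing."""
    bp = _bandpass(speed, fs, band[0], band[1], order=2)
    peaks, props = sps.find_peaks(bp, height=threshold)
    onsets = []
    for p in peaks:
        before = np.flatnonzero(bp[:p] <= 0)
        onsets.append((before[-1] + 1) / fs if before.size else 0.0)
    return EventSet("locomotion", peaks / fs, np.array(onsets),
                    props.get("peak_heights", np.empty(0)),
                    peaks / fs - np.array(onsets) if len(peaks) else np.empty(0),
                    {"band": list(band), "threshold": threshold})


def _half_max_peaks(x: np.ndarray, fs: float):
    """Local maxima retained if they exceed half of the maximal peak amplitude."""
    peaks, _ = sps.find_peaks(x)
    if peaks.size == 0:
        return peaks, np.empty(0)
    keep = x[peaks] > 0.5 * x[peaks].max()
    peaks = peaks[keep]
    return peaks, x[peaks]


def _median_aligned_rise(x: np.ndarray, fs: float, peak_idx: np.ndarray,
                         half_window: float) -> float:
    """Trough-to-peak time of the median peak-aligned transient."""
    hw = int(round(half_window * fs))
    segs = [x[p - hw:p + hw + 1] for p in peak_idx if p - hw >= 0 and p + hw < len(x)]
    if not segs:
        return np.nan
    med = np.median(np.vstack(segs), axis=0)
    centre = hw
    trough = int(np.argmin(med[:centre + 1]))
    return (centre - trough) / fs


def detect_transients_multiband(o2: np.ndarray, coa: np.ndarray, fs: float,
                                corner_freqs=(0.05, 0.1, 0.2, 0.35, 0.5),
                                pairing_factor: float = 0.75,
                                exclude: np.ndarray | None = None):
    """Band-resolved O2/COA transient pairing over [f/2, f] filter bank.

    ``exclude`` is an optional boolean mask (same length as the signals) of
    samples whose O2 peaks are discarded — e.g. windows around SWRs (-5..+1 s)
    and speed peaks (-14..+4 s) when selecting spontaneous events.
    Returns one :class:`TransientPairSet` per corner frequency.
    """
    results = []
    for f in corner_freqs:
        o2_bp = _bandpass(o2, fs, f / 2.0, f, order=2)
        coa_bp = _bandpass(coa, fs, f / 2.0, f, order=2)
        o2_pk, o2_amp = _half_max_peaks(o2_bp, fs)
        if exclude is not None and o2_pk.size:
            keep = ~exclude[o2_pk]
            o2_pk, o2_amp = o2_pk[keep], o2_amp[keep]
        coa_pk, coa_amp = _half_max_peaks(coa_bp, fs)

        max_lag = pairing_factor / f
        sel_coa, sel_o2 = [], []
        if o2_pk.size and coa_pk.size:
            for ci, cp in enumerate(coa_pk):
                j = int(np.argmin(np.abs(o2_pk - cp)))
                if abs(o2_pk[j] - cp) / fs <= max_lag:
                    sel_coa.append(ci)
                    sel_o2.append(j)
        sel_coa = np.asarray(sel_coa, int)
        sel_o2 = np.asarray(sel_o2, int)
        lags = (coa_pk[sel_coa] - o2_pk[sel_o2]) / fs if sel_coa.size else np.empty(0)
        a_o2 = o2_amp[sel_o2] if sel_o2.size else np.empty(0)
        a_coa = coa_amp[sel_coa] if sel_coa.size else np.empty(0)
        slope = np.nan
        if sel_coa.size >= 3:
            slope = float(np.polyfit(a_o2, a_coa, 1)[0])
        rise = _median_aligned_rise(o2_bp, fs, o2_pk[sel_o2] if sel_o2.size else o2_pk,
                                    half_window=1.0 / f)
        results.append(TransientPairSet(
            float(f), o2_pk[sel_o2] / fs if sel_o2.size else np.empty(0),
            a_o2, coa_pk[sel_coa] / fs if sel_coa.size else np.empty(0),
            a_coa, lags, float(rise), slope))
    return results


def exclusion_mask(n: int, fs: float, swr_times=None, speed_peak_times=None,
                   swr_window=(-5.0, 1.0), speed_window=(-14.0, 4.0)) -> np.ndarray:
    """Samples to exclude when selecting spontaneous O2 transients."""
    mask = np.zeros(n, bool)
    for times, (w0, w1) in ((swr_times, swr_window),
                            (speed_peak_times, speed_window)):
        if times is None:
            continue
        for t in np.atleast_1d(times):
            i0 = max(0, int(round((t + w0) * fs)))
            i1 = min(n, int(round((t + w1) * fs)))
            mask[i0:i1] = True
    return mask


def ripple_power_correlation(sig: np.ndarray, fs_sig: float,
                             power: np.ndarray, fs_pow: float,
                             swr_times: np.ndarray, window_sizes, lags,
                             baseline_lag: float = 1.0,
                             alpha: float = 0.05) -> CorrMap:
    """Rank correlation between integrated ripple power at SWR times and the
    signal change at each lag (relative to 1 s before the SWR).

    Ripple power is integrated by moving-average smoothing of ``power`` with
    each window size; cells with p > ``alpha`` are flagged non-significant.
    """
    swr_times = np.asarray(swr_times, float)
    if swr_times.size < 10:
        raise ValueError("need at least 10 events for the correlation map")
    window_sizes = np.asarray(window_sizes, float)
    lags = np.asarray(lags, float)
    corr = np.full((window_sizes.size, lags.size), np.nan)
    pval = np.ones_like(corr)

    t_sig = np.arange(len(sig)) / fs_sig
    base = np.interp(swr_times - baseline_lag, t_sig, sig)
    for i, w in enumerate(window_sizes):
        m = max(1, int(round(w * fs_pow)))
        smooth = np.convolve(power, np.ones(m) / m, mode="same")
        pw = np.interp(swr_times, np.arange(len(power)) / fs_pow, smooth)
        for j, lag in enumerate(lags):
            delta = np.interp(swr_times + lag, t_sig, sig) - base
            if np.ptp(delta) == 0 or np.ptp(pw) == 0:
                corr[i, j], pval[i, j] = 0.0, 1.0  # degenerate: no variation
                continue
            rho, p = stats.spearmanr(pw, delta)
            corr[i, j] = rho
            pval[i, j] = p
    return CorrMap(window_sizes, lags, corr, pval, pval <= alpha)


def event_triggered_average(x: np.ndarray, fs: float, event_times,
                            window=(-5.0, 10.0), mode: str = "mean",
                            n_boot: int = 200, ci: float = 0.95,
                            rng=None) -> TriggeredAverage:
    """Event-aligned average with bootstrap CI and derivative-based amplitude.

    Events whose window leaves the recording are dropped (counted).  The
    response amplitude is peak minus the value at the onset, where the onset
    is the largest-derivative point preceding the post-trigger peak — a
    reproducible stand-in for manual onset picking.
    """
    event_times = np.atleast_1d(np.asarray(event_times, float))
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    segs = []
    dropped = 0
    for t in event_times:
        c = int(round(t * fs))
        if c + i0 < 0 or c + i1 >= len(x):
            dropped += 1
            continue
        segs.append(x[c + i0:c + i1 + 1])
    tt = np.arange(i0, i1 + 1) / fs
    if not segs:
        empty = np.empty(0)
        return TriggeredAverage(empty, empty, empty, empty, 0, dropped)

    stack = np.vstack(segs)
    agg = np.mean if mode == "mean" else np.median
    centre = agg(stack, axis=0)

    rng = np.random.default_rng(rng)
    n = stack.shape[0]
    boots = np.empty((n_boot, stack.shape[1]))
    for b in range(n_boot):
        boots[b] = agg(stack[rng.integers(0, n, n)], axis=0)
    q = (1.0 - ci) / 2.0
    lo = np.quantile(boots, q, axis=0)
    hi = np.quantile(boots, 1.0 - q, axis=0)

    post = tt >= 0
    ipk = int(np.flatnonzero(post)[0] + np.argmax(centre[post]))
    deriv = np.gradient(centre, tt)
    ion = int(np.argmax(deriv[:ipk])) if ipk > 0 else 0
    return TriggeredAverage(tt, centre, lo, hi, n, dropped,
                            amplitude=float(centre[ipk] - centre[ion]),
                            onset_time=float(tt[ion]), peak_time=float(tt[ipk]))
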