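# Methods

## Sensor model

The sensing element is modelled as a spherical shell of enzyme-loaded
hydrogel between the electrode surface at radius `r_e` and the bath at
`r_e + R`.  The radial coordinate is measured from the centre of the
equivalent sphere with `r_e = 8.5 µm` (half the 17 µm wire diameter):
this keeps the spherical diffusion operator

    ∂S/∂t = D_S (1/r²) ∂/∂r (r² ∂S/∂r)

regular and matches hemispherical diffusion toward a disc-scale site.
Three species diffuse (choline, O2, H2O2) with effective diffusivities
`α·D_S` (`α = 0.8`, macromolecular-crowding hindrance; free-solution
`D_Ch = 1197`, `D_O2 = 2500`, `D_H2O2 = 1830 µm² s⁻¹`).  Six immobile
enzyme states follow the ping-pong cycle

    E + Ch ⇌ ECh → EredBA →(O2) EoxBA → EredGB →(O2) EoxGB → E

with rate constants `kf = 2×10⁶ M⁻¹s⁻¹`, `kr = 580`, `k1 = 93`,
`k2 = 8.64×10⁴ M⁻¹s⁻¹`, `k3 = 135`, `k4 = 5.34×10⁴ M⁻¹s⁻¹`,
`k5 = 200 s⁻¹`; both O2 oxidation steps release one H2O2.  Free betaine
aldehyde and glycine betaine are not tracked — their kinetics feed back
neither on the tracked species nor on the current.  Total enzyme defaults
to `E0 = 263 µM` (estimate from the coating mixture).

Boundary conditions: outer node Dirichlet at the bulk values for Ch and O2
and zero for H2O2 (washed away); inner node zero-flux for Ch and O2
(ghost-node reflection) and zero for H2O2 (instantly oxidised).  The
current is `I = 2F(πr_e²)·J_H2O2(r_e)`, two electrons per molecule, with
the area `πr_e²` taken for the disc site despite the spherical transport
geometry (the mismatch is a fixed multiplicative convention, irrelevant to
every trend studied here).

### Discretisation

Explicit forward Euler with the conservative half-node flux form of the
spherical Laplacian on a uniform grid (`dr = 1 µm`, `dt = 0.1 ms`;
stability number `α·max(D)·dt/dr² ≤ 0.5` enforced at state construction).
The reaction terms cancel exactly in the enzyme-state sum, so enzyme mass
is conserved to floating-point accumulation (< 1e-12 relative in
practice).  Negative concentrations beyond `1e-9 ×` the problem scale
abort the run rather than being clamped.

The surface H2O2 flux is reconstructed from the scheme's own conservative
face flux plus the source in the inner half-cell,

    r_e² J(r_e) = (r_e + dr/2)² D (H1 − H0)/dr + r_e² q0 dr/2,

which is second-order consistent.  A naive one-sided difference at the
surface is first-order in the spherical metric (the near-electrode profile
behaves as `C1 − C2/r`) and additionally discards the H2O2 generated
between the electrode and the first flux face; at `dr = 1 µm` those biases
reach 10–17 % for thin coatings and would defeat grid-refinement checks.
The naive estimator remains available as `gradient="two_point"`.

### Protocols

Calibrations mimic the bath experiment: constant 5 µM choline, O2 stepped
from zero.  Two canonical schedules: 5 µM steps to 30 µM, and an adaptive
1 µM staircase stopped when a further step raises the plateau by < 1 % of
the maximum so far ("tonic saturation").  Defaults chosen here, as package
conventions where the bath procedure does not dictate them:

* anoxic pre-equilibration 300 s (the experimental analogue, N2 purging
  with choline present, lasts tens of minutes; 300 s loads the reduced
  intermediates enough to reproduce the staircase phenomenology),
* hold per step 60 s; the tonic plateau is the mean over the final 10 % of
  the hold, flagged when its relative slope exceeds 0.1 %/s,
* profile snapshots every 0.1 s; surface concentrations recorded at
  100 Hz so the ΔO2-at-0.3 s diagnostic is well resolved.

### Well-mixed oracle

With substrates clamped and diffusion removed, the six enzyme states form
a linear ODE system whose stationary point is solved directly; a stiff
integrator provides the independent second route.  The volumetric H2O2
production `p` is converted to an equivalent current through the analytic
steady profile of a uniform source in the shell
(`I = 2Fπ·r_e·p·(b−r_e)(b+2r_e)/6`, independent of D).  In a thin coating
with diffusivities up-scaled 100× the PDE plateau matches this oracle to
< 1 %.

## Calibration analysis

Per step: tonic = plateau − pre-calibration baseline (cumulative across
the staircase); phasic = within-step maximum − that step's plateau,
floored at zero; onset = first sustained departure > 3 SD above the 5 s
pre-step baseline (the same convention as the LOD); T90 rise from onset to
90 % of peak, T50 decay from peak to halfway toward the plateau.  Ties in
the peak search resolve to the earliest sample.  The tonic curve is fitted
with Michaelis–Menten and the cumulative phasic curve with Hill
(lmfit least squares; CIs from the linearised covariance at the optimum).
The cumulative convention for phasic amplitudes is used because the
fitted phasic Imax exceeds the tonic Imax in representative calibrations,
consistent with a running sum.

Known limitation: at extreme loading the tonic curve degenerates to
linear-then-clip (every O2 molecule delivered is consumed until choline
depletion caps the rate).  A Michaelis–Menten fit summarises such a curve
with a *larger* Km even though its half-saturation O2 is lower, so the
fitted KmO2app is not monotone in enzyme concentration at the far corner
of parameter space; the canonical sweep (E0 = 70–280 µM, R = 10–30 µm)
stays within the regime where the MM summary is faithful.

## Common-mode rejection

Per channel pair (target, sentinel), spectra are averaged over
artifact-rich, analyte-poor reference epochs in 20 s Hann windows with
50 % overlap (resolves 0.05 Hz structure while averaging enough segments).
|T|(f) = sqrt(P_target/P_sentinel); phase(f) = angle of the averaged
cross-spectrum, accepted where the phase-locking value — the magnitude of
the mean unit cross-spectral phasor across windows — exceeds 0.9 and
interpolated from passing bins elsewhere.  Below 0.3 Hz the analyte itself
contributes power to the target channel, so |T| is replaced by a linear
fit over the contiguous 0.3–1.0 Hz band.  Cleaning applies
`target(jω) − T(jω)·sentinel(jω)` in the same windows with Hann
overlap-add (COLA at 50 % hop), then a zero-phase 4th-order Butterworth
low-pass at 1 Hz and decimation to 10 Hz (100 Hz variant for lag
analyses; zero-phase filtering avoids filter-induced lags).  Estimation
fails loudly, reporting the PLV distribution, when no bin passes the mask
(no coherent common mode).

## Event detection

* SWR: 120–200 Hz band-pass, squared, Gaussian-smoothed (SD 4.2 ms,
  kernel width 42 ms), square root as envelope; events are contiguous
  supra-98th-percentile segments with ≥ 5 cycles (band-pass zero-crossing
  pairs) lasting < 200 ms; event time at the envelope maximum.  The
  percentile's estimation epoch defaults to the whole input, with an
  optional mask.
* Locomotion: peaks of the 0.02–0.2 Hz band-passed 1 Hz speed above
  threshold; onset at the preceding upward zero crossing.
* Multi-band transients: one-octave band-passes [f/2, f], corner
  frequencies 0.05–0.5 Hz; peaks kept when above half the band's maximal
  peak amplitude (operationalised as a `find_peaks` height rule); COA
  peaks paired to the nearest O2 peak within 0.75/f; per band a linear
  COA-vs-O2 amplitude slope and the trough-to-peak rise time of the
  median peak-aligned O2 transient.  For spontaneous-event selection, O2
  peaks within −5…+1 s of SWRs or −14…+4 s of speed peaks can be masked
  out.
* Triggered averages: mean or median with bootstrap CIs; response
  amplitude = peak minus the value at the largest-derivative point
  preceding the peak — a reproducible replacement for manual onset
  picking (for a Gaussian transient this onset sits one SD before the
  peak, so the amplitude is `peak·(1 − e^{−1/2})` of the full excursion).
* Ripple-power correlation maps: Spearman correlation between
  moving-average-integrated ripple power at SWR times and the signal
  change at each lag relative to 1 s pre-event; cells with p > 0.05
  flagged, no multiplicity correction.

## Synthetic data

Generators are deterministic under a fixed seed and always emit a ground
truth record; recovery tests read truth only from it.  The common-mode
artifact is a sum of narrowband Gaussian processes spanning 0.3–20 Hz
with 1/f amplitude weighting — statistically LFP-like without claiming
physiology; the band extends below 0.3 Hz-adjacent frequencies so the |T|
extrapolation has a genuine trend to follow, as with real LFP pick-up.
Each channel receives the artifact through its own gain and delay,
chemistry weighted by site sensitivities (Ch ≈ 2.45/2.54/0.27/0.25 pA/µM
for the platinised/plain × m-PD/plain combinations; dopamine strongly
suppressed by m-PD), plus white noise.  The O2-measuring site (gold at
−0.2 V) carries the O2 component instead of COA.

COA-from-O2 coupling is selectable: linear, saturating, or a two-path
"phasic" form — a delayed (0.3 s), optionally saturating slow path plus a
derivative fast path that vanishes for slow inputs.  For narrowband
transients this yields an amplitude ratio `√(ks² + kf²ω²)` and a lead
`atan(kf·ω/ks)/ω` that grows with rise time, reproducing the in vivo
signatures (COA anticipating O2 and the amplitude ratio decaying as O2
rises more slowly) with exactly known parameters.  Scheduled O2 events use
alpha-function waveforms with rise times log-spaced over 1–12 s and
amplitudes proportional to rise time.  Ripple bursts are tapered-flat
(Tukey) 150 Hz packets whose SNR is defined against the in-band noise SD;
speed traces are non-negative jitter plus 10 s-wide Gaussian bouts.

## Problem sizes used in tests

The test-suite and the acceptance script use deliberately small problem
sizes chosen as the package's own verification conditions: two-step
staircases (20 s holds) for conservation/flux/grid checks, a 40 s
fast-diffusion run for the oracle comparison, the 3×3 canonical sweep
with default 60 s holds, 10 min of synthetic LFP with ~90 ripple bursts,
and 50 min equivalents of slow O2/COA signals (10 Hz) for the multi-band
analyses.  Passing these shows internal consistency and recovery on data
matching the generators' assumptions (stationary artifact mismatch,
white sensor noise, isolated transients); it does not certify behaviour
on real recordings with drift, non-stationary artifact coupling or
overlapping events.

## Other known limitations

One-dimensional radial geometry only (no membrane layers, electrode
double-layer or electron-transfer kinetics; no temperature/pH dependence
of the constants).  The transfer coefficient is time-invariant.  Detector
parameters mirror the conventions above rather than adapting to the
input.  The planar-vs-spherical ambiguity of the coating geometry is
resolved in favour of the spherical operator; sensitivity to that choice
can be probed by varying `radius` upward (the planar limit).
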