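# Methods

This note records the models the package implements, the choices made
where the procedures were genuinely open, and what the synthetic-data
tests do and do not establish about real data.

## Dose–response fitting

The four-parameter logistic `y = A + (B−A)/(1 + (C/x)^D)` is fitted by
bounded least squares with the midpoint parameterised as log10(C).  The
model is badly conditioned on a linear concentration scale: C trades off
against D over several orders of magnitude.  Bounds tie C to the observed
design (`[min x/100, max x·100]`) and D to `[0.1, 10]`; the optimiser is
restarted from three initial midpoints (quartiles of the log-concentration
range) and the best solution kept.  Replicates all enter the loss
individually; per-concentration means are used only to initialise the
asymptotes.  Standard errors come from the Gauss–Newton covariance
(`RSS/dof · (JᵀJ)⁻¹`), with a delta-method back-transform for C; fixed
parameters carry no standard error.  Flat response vectors are flagged as
non-converged rather than fitted.

Two constrained uses recur: modulation curves are fitted with the floor
fixed at zero (a compound with no effect leaves the GABA current
unchanged), and exposure–occupancy curves with the floor at zero *and*
slope fixed at 1 (one-site occupancy).  Whether binding curves should also
fix the ceiling at 100% is not settled; the default leaves B free, which
costs little precision on well-designed curves and is robust to incomplete
inhibition.

The Cheng–Prusoff correction `Ki = IC50/(1 + L/Kd)` uses the radioligand
concentration L and affinity Kd as explicit inputs.  Censored affinities
("no binding up to X") propagate into fold-selectivity tables as
lower-bound ratios flagged as censored.

## Ex vivo occupancy (rat arm)

The radioligand used for this receptor family is not perfectly
subtype-selective, so "non-displaceable" signal is estimated
pharmacologically: a cohort dosed with a saturating amount of a selective
blocker defines the plateau (off-target subtypes plus classical
nonspecific binding).  Specific binding is each animal's signal minus the
blocker-group mean; occupancy is `y = 100·(1 − S_drug/S̄_vehicle)`.  The
equation is implemented in this ratio form; a typeset variant that divides
only the subtrahend is dimensionally inconsistent.  Vehicle-group specific
binding is summarised by the arithmetic mean.  Negative specific binding
(possible under noise) is kept, flagged, and enters fits unclipped —
clipping would bias the exposure–occupancy curve.

Occupancy versus individual plasma concentration is fitted with the
slope-1 Hill model; the asymptote B is estimated rather than fixed at
100%, because with a partially selective radioligand the drug cannot
displace the off-target fraction and the curve saturates below 100%.
Whether to re-express occupancies relative to the fitted asymptote is a
flag (`rescale_to_asymptote`), default on for the rat arm and off for the
human arm, where BP_ND-based occupancy needs no such renormalisation.

## PET kinetics (human arm)

The simplified reference tissue model expresses a target-region
time–activity curve through a reference region devoid of specific
binding.  Fitting uses the basis-function approach: for each candidate
apparent efflux rate k2a the convolution basis `C_R ⊗ exp(−k2a t)` is
precomputed and the two remaining coefficients solve a weighted linear
least-squares problem; the k2a minimising the weighted RSS on a
100-point logarithmic grid over [0.006, 0.6] min⁻¹ wins and is refined by
a bounded scalar search between its grid neighbours.  A best fit at the
grid boundary and negative binding potentials are flagged, not hidden.
The exact regularisation of published basis-pursuit implementations is
not described in the sources available; the grid-search basis-function
method is implemented instead and labelled as such.

Continuous-time arithmetic treats the reference curve as piecewise linear
through frame-midpoint values, anchored at zero activity at injection;
the convolution with the exponential kernel is computed exactly per linear
segment (with series expansions where `k2a·Δt` is tiny, to avoid
catastrophic cancellation), and model frames are averages of the
continuous prediction over the frame interval.  The delivery term's frame
average is the measured reference frame value itself — a TAC frame *is*
the frame average of the underlying curve — which makes the degenerate
case (R1 = 1, BP_ND = 0) reproduce the reference exactly.  Frame weights
default to frame duration, the standard count-statistics proxy.  Occupancy
is the fractional reduction of BP_ND between baseline and post-dose scans;
the reference region defaults to the cerebellum and is configurable.

One caution for simulation studies: when `R1 − 1 = BP_ND` the coefficient
of the convolution basis is exactly zero and k2a is unidentifiable (the
target is a pure scaling of the reference).  The fitted BP_ND then happens
to equal R1 − 1 for any k2a.  Test parameter choices avoid this manifold.

## EEG spectral pipeline

Preprocessing: 0.5 Hz high-pass with a linear-phase FIR of `2·fs + 1`
taps applied by centred convolution (zero net phase), a 4th-order
Butterworth 49–51 Hz band-stop applied forward–backward, then average
re-referencing.  Operator-dependent artifact screening is replaced by an
automated amplitude rule: one-second segments whose peak-to-peak amplitude
exceeds 150 µV on any channel are excluded from all later spectral
windows, as are filter-edge regions.  This is adequate for
artifact-controlled synthetic data; it does not emulate ocular or muscle
artifact removal on real recordings.

Spectra: Morlet wavelets on 41 frequencies 2^(1+k/8), k = 0…40 (2–64 Hz),
with constant relative smoothing `q = f/σ_f = 5.83` — σ_f is the
spectral-domain Gaussian SD, the only reading consistent with half-octave
smoothing — and temporal SD `σ_t = 1/(2π σ_f)`.  The estimate at each
frequency is the mean squared wavelet coefficient over temporal windows
spanning the ±3σ_t support; windows extending past the edges or touching
rejected samples are dropped.  Coefficients are computed in the frequency
domain (one FFT per recording; per frequency, a band-limited kernel
product and a small inverse FFT of the coefficient envelope) and sampled
at least as densely as 3/4-overlapping windows; masked samples are zeroed
before the FFT, which is exact for the windowed estimator and prevents
large artifacts from leaking through the band-limited reconstruction.
Calibration makes the estimate a one-sided spectral density; multiplying
by `f·ln 2` converts per-Hz to per-log2(Hz) units, so white noise yields a
density proportional to f.

Alpha alignment: the individual alpha peak is the maximal channel-averaged
power on the grid within 7–12 Hz (a boundary maximum is flagged — the
automated stand-in for visual confirmation; an FFT variant with 1-s
windows zero-padded to 25 s is available).  Spectra are shifted in
log2-frequency by `log2(target) − log2(peak)` via linear interpolation,
with out-of-grid values set to NaN; the default target is 9.3 Hz.
Relative power normalises each channel to unit sum over the grid,
excluding NaN padding (the normalisation range is configurable; the full
2–64 Hz grid is the default).  Percent change is
`100·(drug − baseline)/baseline` after averaging recordings within
condition; the channel-resolved version is retained for topography tests.

## Randomization statistics

Cluster test: per-frequency paired t-tests, two-tailed, thresholded at
p < 0.01; maximal contiguous same-sign runs form clusters whose size (in
grid frequencies) is referred to the permutation distribution of the
largest cluster size.  The null is generated by sign-flipping the
within-subject condition differences — baseline and drug are
within-subject, so flipping paired differences is the exact exchangeable
scheme; all 2^n assignments are enumerated when that is cheaper than
Monte Carlo.  p-values are `(1 + #{null ≥ observed})/(n_perm + 1)`.
Cluster *mass* (summed |t|) is available as an alternative statistic.

Peak frequencies of effects: the peak of the group-mean effect spectrum in
log2-frequency, with parabolic interpolation between grid neighbours
(effect peaks rarely sit on the 1/8-octave grid), jackknifed into
pseudo-values `p_i = n·θ − (n−1)·θ₋ᵢ` that provide the SEM and support
t-tests between drugs (paired by default, assuming a crossover design).

Topography similarity: the statistic is the mean of the two within-drug
average pairwise Pearson correlations of subjects' band topographies minus
the between-drug average correlation (a difference, not a ratio — chosen
for symmetry and an obvious null at zero); significance by permuting drug
labels, one-sided.  Flat topographies have undefined correlations and are
excluded with a warning.

## Synthetic data: what it emulates, and what it does not

*Concentration–response*: exact Hill curves plus iid Gaussian noise.

*Autoradiography cohort*: per-region signal = non-displaceable plateau +
target density × (1 − occupancy) + Gaussian noise (default SD
18 fmol/mg ≈ 6% of the hippocampal vehicle signal), occupancy =
C/(EC50 + C) on total plasma with EC50 544 ng/mL, per-animal plasma
lognormal around the dose-group median (CV 30% — group means are reported
in practice, within-group spread is a stand-in), 4 animals per dose at
3/10/30/100 mg/kg plus vehicle and full-block groups.  Regional target
densities 304/192/25/38 fmol/mg (hippocampus, frontal cortex, striatum,
cerebellum).  The generator treats the blocker plateau as exactly the
non-target signal, so the generating exposure–occupancy curve saturates
at 100%; the partial-selectivity ceiling seen with real radioligands
(asymptotes near 77%) is *not* emulated — recovery tests therefore verify
estimation, not radioligand selectivity artefacts.

*PET*: the reference curve is a rise-and-wash difference of exponentials
(peak ≈ 23 kBq/mL near 2.4 min); target curves come from the same
`srtm_forward` operator the fitter assumes, so noise-free round-trips are
exact by construction and test the numerics, not model misspecification.
Frame noise is Gaussian with SD ∝ 1/√(frame duration).

*EEG*: channels mix a small set of latent 1/f^γ sources (unit-norm mixing
rows keep the per-channel background density exact, and shared sources
give realistic cross-channel correlation) plus a posterior-weighted alpha
source whose bump is Gaussian in log2-frequency — matching the pipeline's
log-frequency analysis — at a per-subject frequency drawn from
N(9.3, 0.87²) Hz (clipped to 7.5–11.5 Hz so the detector's search range
always applies).  Drug effects multiply the channel spectrum by
`1 + change·w_c·G(f)` with G Gaussian in log2-frequency; shaping is done
in the frequency domain with random phases, so recordings are stationary
Gaussian processes — real EEG's nonstationarity, artifacts and line noise
are not emulated.  Defaults: 12 subjects, 19-channel 10/20 montage,
256 Hz, 220 s per condition (the usable-data volume of a vigilance-
controlled resting session), background ≈ 12 µV RMS over 2–64 Hz, alpha
peak ≈ 6× background.  Signals are synthesised in single precision —
ample for EEG, which is digitised at 16 bits.

Null simulations for the cluster test draw per-subject spectra with
frequency-*correlated* noise (Gaussian-smoothed over ≈2 grid bins),
because the wavelet estimator smooths over half an octave and neighbouring
grid frequencies of real pipeline spectra are strongly correlated; with
independent noise the size-based cluster statistic is far more
conservative than it is on realistic spectra.

## Numerical and scale choices

Problem sizes in the test-suite simulations — 500 seeds for the EC50
recovery suites, 100 repetitions for EEG effect detection, 500 datasets
for type-I-error calibration, 200 noise realizations for SRTM bias — were
chosen to estimate medians and rates with comfortable margins while
keeping the default `pytest` run in the tens of minutes on one CPU.
Profile-likelihood intervals use the F-criterion
`RSS ≤ RSS_min·(1 + F(1, n−p, 0.95)/(n−p))` with bracketing on a log-EC50
grid; intervals that are open-ended or span more than a decade set the
`ci_unbounded` flag ("the design does not identify the EC50").  The
pipeline orchestrator derives per-stage sub-seeds by hashing
`(global seed, stage name)` so any stage can be re-run reproducibly in
isolation.

## Known limitations

- EDF files can be read (via mne) but synthetic EEG is written as CSV;
  EDF export would require an additional writer dependency.
- No population PK modelling, no arterial-input-function PET models, no
  voxelwise parametric imaging, no source localisation or connectivity.
- The amplitude-threshold artifact rule is not a substitute for
  operator/component-based cleaning on real recordings; gamma-band
  analyses of real clinical EEG would need dedicated muscle-artifact
  handling.
- Relative-power normalisation over the full grid makes band changes
  mildly interdependent (a genuine increase in one band depresses
  relative power elsewhere); this mirrors the analysis convention but
  should be kept in mind when reading change spectra.
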