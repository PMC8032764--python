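"""Synthetic data generators with known ground truth.

Four generators emulate the data classes the analysis pipeline consumes:

* Hill-shaped concentration-response tables with additive noise,
* an ex vivo autoradiography cohort (vehicle, full-block and dose groups)
  whose regional signal is a non-displaceable plateau plus a target-specific
  component scaled by the plasma-driven occupancy,
* baseline / post-dose PET studies whose target curves come from the SRTM
  forward model on a shared reference curve, with the post-dose binding
  potential reduced by the generating occupancy fraction,
* a multi-subject resting EEG study with 1/f^gamma background, subject-
  specific alpha peaks (~N(9.3, 0.87^2) Hz) and band-limited multiplicative
  drug effects, realised by shaping white noise in the frequency domain and
  mixing a small set of latent sources so channels are correlated.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .doseresponse import hill
from .eeg_spectra import CHANNELS_10_20, EEGRecording
from .pet_kinetics import (FrameSchedule, ScanMeta, SRTMParams,
                           TimeActivityCurve, default_90min_schedule,
                           srtm_forward, _fine_grid, _frame_average)

__all__ = [
    "HillTruth",
    "OccupancyCohortTruth",
    "PETStudyTruth",
    "PETStudy",
    "EEGEffect",
    "EEGStudyTruth",
    "EEGStudy",
    "channel_topography",
    "gen_conc_response",
    "gen_occupancy_cohort",
    "gen_pet_study",
    "gen_eeg_study",
]


# -- concentration-response ----------------------------------------------------

@dataclass(frozen=True)
class HillTruth:
    """Generating four-parameter logistic: floor, ceiling, midpoint, slope."""

    A: float
    B: float
    C: float  # nM
    D: float

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("midpoint C must be positive")
        if self.D == 0:
            raise ValueError("slope D must be non-zero")


def gen_conc_response(truth: HillTruth, concentrations, replicates=1,
                      noise_sd=0.0, seed=0) -> pd.DataFrame:
    """Replicated noisy observations of a Hill curve.

    Returns a tidy table with columns ``conc_nM, response, replicate``.
    """
    x = np.asarray(concentrations, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(replicates):
        y = hill(x, truth.A, truth.B, truth.C, truth.D)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=x.size)
        rows.append(pd.DataFrame(
            {"conc_nM": x, "response": y, "replicate": r}))
    return pd.concat(rows, ignore_index=True)


# -- autoradiography cohort ----------------------------------------------------

#: regional target-specific density and non-displaceable plateau (fmol/mg)
_DEFAULT_REGIONS = {
    "hippocampus": (304.0, 100.0),
    "frontal_cortex": (192.0, 80.0),
    "striatum": (25.0, 60.0),
    "cerebellum": (38.0, 50.0),
}


@dataclass(frozen=True)
class OccupancyCohortTruth:
    """Ground truth for a rat ex vivo occupancy cohort.

    Plasma levels are drawn per animal from a lognormal distribution around
    the dose-group median (individual exposure varies; only group summaries
    are usually reported).  Occupancy follows C/(EC50 + C) on total plasma.
    """

    doses_mg_kg: tuple = (3.0, 10.0, 30.0, 100.0)
    plasma_median_ng_ml: dict = field(
        default_factory=lambda: {3.0: 165.0, 10.0: 550.0,
                                 30.0: 1650.0, 100.0: 5500.0})
    plasma_cv: float = 0.30
    ec50_ng_ml: float = 544.0
    regions: dict = field(default_factory=lambda: dict(_DEFAULT_REGIONS))
    noise_sd_fmol_mg: float = 18.0
    n_per_dose: int = 4
    n_vehicle: int = 4
    n_blocker: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.ec50_ng_ml <= 0:
            raise ValueError("EC50 must be positive")
        for name, (dens, plateau) in self.regions.items():
            if dens < 0 or plateau < 0:
                raise ValueError(f"densities must be non-negative ({name})")


def gen_occupancy_cohort(truth: OccupancyCohortTruth) -> pd.DataFrame:
    """Cohort table: one row per animal and region.

    Columns: ``animal_id, treatment, dose_mg_kg, region, signal_fmol_mg,
    plasma_ng_ml``.  Treatments are ``vehicle``, ``blocker`` (full block:
    plateau only) and ``drug``.
    """
    if truth.n_vehicle < 1 or truth.n_blocker < 1:
        raise ValueError("vehicle and blocker groups must be non-empty "
                         "(quantification requires both)")
    if truth.n_per_dose < 1:
        raise ValueError("dose groups must be non-empty")
    rng = np.random.default_rng(truth.seed)
    sigma_ln = math.sqrt(math.log(1.0 + truth.plasma_cv ** 2))
    rows = []
    counter = 0

    def emit(treatment, dose, plasma, occ):
        nonlocal counter
        counter += 1
        aid = f"rat{counter:03d}"
        for region, (dens, plateau) in truth.regions.items():
            signal = plateau + dens * (1.0 - occ)
            if truth.noise_sd_fmol_mg > 0:
                signal += rng.normal(0.0, truth.noise_sd_fmol_mg)
            rows.append((aid, treatment, dose, region, signal, plasma))

    for _ in range(truth.n_vehicle):
        emit("vehicle", np.nan, np.nan, 0.0)
    for _ in range(truth.n_blocker):
        emit("blocker", np.nan, np.nan, 1.0)
    for dose in truth.doses_mg_kg:
        median = truth.plasma_median_ng_ml[dose]
        for _ in range(truth.n_per_dose):
            plasma = float(median * math.exp(rng.normal(0.0, sigma_ln)))
            occ = plasma / (truth.ec50_ng_ml + plasma)
            emit("drug", dose, plasma, occ)

    return pd.DataFrame(rows, columns=[
        "animal_id", "treatment", "dose_mg_kg", "region",
        "signal_fmol_mg", "plasma_ng_ml"])


# -- PET study -----------------------------------------------------------------

@dataclass(frozen=True)
class PETStudyTruth:
    """Ground truth for a baseline / post-dose PET scan pair.

    The reference-region curve is a sum of exponentials (kBq/mL, time in
    minutes) that rises from zero and washes out; target regions follow the
    SRTM with the stated parameters, and the post-dose scan multiplies each
    BP_ND by (1 - occupancy).  Frame noise is Gaussian with SD proportional
    to 1/sqrt(frame duration), the usual count-statistics proxy.
    """

    schedule: FrameSchedule = field(default_factory=default_90min_schedule)
    ref_exponentials: tuple = ((30.0, 0.08), (-30.0, 1.2))  # (ampl, 1/min)
    regions: dict = field(default_factory=lambda: {
        "hippocampus": (1.05, 0.17, 2.0),     # (R1, k2, BP_ND)
        "frontal_cortex": (1.00, 0.16, 1.6),
    })
    occupancy: float = 0.0
    injected_mbq: float = 280.0
    body_weight_kg: float = 75.0
    reference_region: str = "cerebellum"
    noise_scale: float = 0.0  # fractional SD of the reference peak at 60 s
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be within [0, 1]")
        for name, (r1, k2, bp) in self.regions.items():
            if bp < 0:
                raise ValueError(f"BP_ND must be non-negative ({name})")
            if k2 <= 0:
                raise ValueError(f"k2 must be positive ({name})")


@dataclass
class PETStudy:
    scans: dict          # scan_id -> {region -> TimeActivityCurve}
    meta: ScanMeta
    truth: PETStudyTruth


def _reference_tac(truth: PETStudyTruth, scan_id) -> TimeActivityCurve:
    grid, slices = _fine_grid(truth.schedule)
    fine = np.zeros_like(grid)
    for amp, lam in truth.ref_exponentials:
        fine += amp * np.exp(-lam * grid)
    fine = np.clip(fine, 0.0, None)
    vals = _frame_average(fine, grid, slices, truth.schedule)
    return TimeActivityCurve(schedule=truth.schedule, activity_kbq_ml=vals,
                             region=truth.reference_region, scan_id=scan_id)


def gen_pet_study(truth: PETStudyTruth) -> PETStudy:
    """Baseline and post-dose scans for all regions plus the reference.

    The reference curve is shared within each scan; the baseline scan uses
    the nominal BP_ND of every region and the post-dose scan uses
    BP_ND * (1 - occupancy).
    """
    rng = np.random.default_rng(truth.seed)
    scans = {}
    for scan_id, occ in (("baseline", 0.0), ("postdose", truth.occupancy)):
        ref = _reference_tac(truth, scan_id)
        peak = float(ref.activity_kbq_ml.max())
        regions = {truth.reference_region: ref}
        for name, (r1, k2, bp) in truth.regions.items():
            params = SRTMParams(r1=r1, k2=k2, bp_nd=bp * (1.0 - occ))
            tac = srtm_forward(ref, params, region=name, scan_id=scan_id)
            if truth.noise_scale > 0:
                sd = truth.noise_scale * peak / np.sqrt(
                    truth.schedule.dur_s / 60.0)
                tac.activity_kbq_ml = tac.activity_kbq_ml + rng.normal(
                    0.0, sd, size=sd.size)
            regions[name] = tac
        scans[scan_id] = regions
    meta = ScanMeta(injected_mbq=truth.injected_mbq,
                    body_weight_kg=truth.body_weight_kg,
                    reference_region=truth.reference_region)
    return PETStudy(scans=scans, meta=meta, truth=truth)


# -- EEG study -----------------------------------------------------------------

#: anterior(-1) to posterior(+1) coordinate of the 10/20 channels
_AP_COORD = {
    "Fp1": -1.0, "Fp2": -1.0,
    "F7": -0.6, "F3": -0.6, "Fz": -0.6, "F4": -0.6, "F8": -0.6,
    "T7": 0.0, "C3": 0.0, "Cz": 0.0, "C4": 0.0, "T8": 0.0,
    "P7": 0.6, "P3": 0.6, "Pz": 0.6, "P4": 0.6, "P8": 0.6,
    "O1": 1.0, "O2": 1.0,
}


def channel_topography(name, channels=CHANNELS_10_20):
    """Named topography weight vectors over the montage.

    ``uniform`` is all ones, ``posterior`` ramps towards occipital sites,
    ``frontal`` towards frontopolar sites.
    """
    ap = np.array([_AP_COORD[c] for c in channels])
    if name == "uniform":
        return np.ones(len(channels))
    if name == "posterior":
        return 0.25 + 0.75 * (1.0 + ap) / 2.0
    if name == "frontal":
        return 0.25 + 0.75 * (1.0 - ap) / 2.0
    raise ValueError(f"unknown topography {name!r}")


@dataclass(frozen=True)
class EEGEffect:
    """Band-limited multiplicative power change.

    ``change`` is the fractional power change at the centre (e.g. +0.19);
    the profile is Gaussian in log2-frequency with SD ``width_octaves``;
    ``topography`` is a per-channel weight vector or a named pattern.
    """

    center_hz: float
    width_octaves: float = 0.5
    change: float = 0.0
    topography: object = "uniform"

    def weights(self, channels):
        if isinstance(self.topography, str):
            return channel_topography(self.topography, channels)
        w = np.asarray(self.topography, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("topography weights must be finite")
        return w

    def gain(self, freqs_hz):
        lf = np.log2(np.maximum(freqs_hz, 1e-12))
        return self.change * np.exp(
            -(lf - math.log2(self.center_hz)) ** 2
            / (2.0 * self.width_octaves ** 2))


@dataclass(frozen=True)
class EEGStudyTruth:
    """Study conditions for the synthetic resting EEG cohort.

    Defaults follow the clinical setting being emulated: 12 subjects,
    19-channel 10/20 montage at 256 Hz, ~220 s of usable data per
    condition, 1/f background, and subject alpha peaks drawn from
    N(9.3, 0.87^2) Hz.
    """

    n_subjects: int = 12
    channels: tuple = CHANNELS_10_20
    fs: float = 256.0
    duration_s: float = 220.0
    n_recordings: int = 1          # recordings per subject and condition
    gamma: float = 1.0
    background_v2_hz: float = 4e-11   # background PSD at 1 Hz (V^2/Hz)
    alpha_mean_hz: float = 9.3
    alpha_sd_hz: float = 0.87
    alpha_rel_height: float = 6.0  # alpha peak density / background at peak
    alpha_width_octaves: float = 0.20
    alpha_amp_cv: float = 0.4
    n_background_sources: int = 5
    effects: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 2 * 64.0:
            raise ValueError("sampling rate must exceed twice the 64 Hz "
                             "analysis ceiling")
        for eff in self.effects:
            if eff.center_hz * 2.0 ** eff.width_octaves >= self.fs / 2.0:
                raise ValueError("drug effect profile extends above Nyquist")


@dataclass
class EEGStudy:
    truth: EEGStudyTruth
    recordings: list      # of EEGRecording
    alpha_hz: dict        # subject id -> generating alpha peak (Hz)

    def get(self, subject, condition):
        return [r for r in self.recordings
                if r.subject == subject and r.condition == condition]

    @property
    def subjects(self):
        return sorted(self.alpha_hz)


def _shaped_noise(rng, psd_one_sided, mixing, n, fs):
    """Channels x samples noise whose per-channel one-sided PSD is given.

    ``psd_one_sided``: (n_sources, n_bins) target density per source;
    ``mixing``: (n_channels, n_sources) with unit-norm rows so the channel
    densities are convex mixtures of the source densities.
    """
    n_src, n_bins = psd_one_sided.shape
    z = (rng.standard_normal((n_src, n_bins), dtype=np.float32)
         + 1j * rng.standard_normal((n_src, n_bins), dtype=np.float32))
    z /= math.sqrt(2.0)
    amp = np.sqrt(psd_one_sided * fs * n / 2.0).astype(np.float32)
    spec = mixing.astype(np.float32) @ (z * amp)
    spec[:, 0] = 0.0
    if n % 2 == 0:
        spec[:, -1] = spec[:, -1].real
    return spec


def gen_eeg_study(truth: EEGStudyTruth) -> EEGStudy:
    """Baseline and drug recordings for every subject.

    The theoretical one-sided channel density is
    ``k / f^gamma + alpha bump`` (the bump is Gaussian in log2-frequency at
    the subject's alpha frequency with posterior topography), and under
    drug the whole density is multiplied per channel by
    ``1 + sum_j change_j * w_jc * G_j(f)``.  Background channels mix a
    small set of latent 1/f sources so cross-channel correlations are
    realistic.  Fixed seed implies bit-identical output.
    """
    if truth.duration_s < 60:
        raise ValueError("at least 60 s per condition is required for "
                         "stable spectral estimates")
    rng = np.random.default_rng(truth.seed)
    n = int(round(truth.duration_s * truth.fs))
    freqs = np.fft.rfftfreq(n, 1.0 / truth.fs)
    n_ch = len(truth.channels)

    bg = truth.background_v2_hz / np.maximum(freqs, 1.0) ** truth.gamma

    alpha_topo = channel_topography("posterior", truth.channels)
    lf = np.log2(np.maximum(freqs, 1e-12))

    recordings = []
    alpha_by_subject = {}
    for i in range(truth.n_subjects):
        sid = f"S{i + 1:02d}"
        f_alpha = float(rng.normal(truth.alpha_mean_hz, truth.alpha_sd_hz))
        f_alpha = float(np.clip(f_alpha, 7.5, 11.5))  # keep inside 7-12 search
        alpha_by_subject[sid] = f_alpha
        amp = (truth.alpha_rel_height * truth.background_v2_hz / f_alpha
               * math.exp(rng.normal(0.0, truth.alpha_amp_cv)))
        alpha_psd = amp * np.exp(
            -(lf - math.log2(f_alpha)) ** 2
            / (2.0 * truth.alpha_width_octaves ** 2))

        mixing = rng.standard_normal((n_ch, truth.n_background_sources))
        mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)

        for condition in ("baseline", "drug"):
            if condition == "drug" and truth.effects:
                gain = np.ones((n_ch, freqs.size))
                for eff in truth.effects:
                    gain += np.outer(eff.weights(truth.channels),
                                     eff.gain(freqs))
                sqrt_gain = np.sqrt(np.clip(gain, 0.05, None)).astype(np.float32)
            else:
                sqrt_gain = None
            for rec_idx in range(truth.n_recordings):
                spec = _shaped_noise(rng, np.tile(bg, (truth.n_background_sources, 1)),
                                     mixing, n, truth.fs)
                spec += _shaped_noise(rng, alpha_psd[None, :],
                                      alpha_topo[:, None], n, truth.fs)
                if sqrt_gain is not None:
                    spec = spec * sqrt_gain
                data = sfft.irfft(spec, n=n, axis=1)
                recordings.append(EEGRecording(
                    data=data, fs=truth.fs, channels=truth.channels,
                    subject=sid, condition=condition, rec_index=rec_idx))

    return EEGStudy(truth=truth, recordings=recordings,
                    alpha_hz=alpha_by_subject)
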