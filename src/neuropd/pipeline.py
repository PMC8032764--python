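"""End-to-end orchestration: synthesize, fit, report.

A run is described by a YAML/dict config (validated against a schema of
known keys), executes its stages in dependency order, derives a recorded
per-stage sub-seed from the global seed by hashing, and writes a manifest
of inputs, outputs (with checksums), seeds and versions.  Re-running a
stage from saved intermediates with the recorded sub-seed reproduces its
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .doseresponse import fit_hill
from .eeg_spectra import (align_to_mean_alpha, detect_alpha_peak,
                          log_frequency_grid, power_change, preprocess,
                          relative_power, wavelet_power)
from .eeg_stats import (attach_frequencies, cluster_randomization_test,
                        jackknife_peak)
from .occupancy import (PlasmaConversionSpec, fit_emax, occupancy_from_bp,
                        rat_occupancy_table, total_to_free_nM)
from .pet_kinetics import srtm_fit_basis
from .synth import (EEGEffect, EEGStudyTruth, HillTruth, OccupancyCohortTruth,
                    PETStudyTruth, gen_conc_response, gen_eeg_study,
                    gen_occupancy_cohort, gen_pet_study)

log = logging.getLogger("neuropd.pipeline")

STAGES = ("synth", "doseresponse", "occupancy", "pet", "eeg")

#: allowed config keys; nested dicts constrain nested sections
_SCHEMA = {
    "seed": None,
    "output_dir": None,
    "stages": None,
    "conversion": {"molecular_weight": None, "free_fraction_rat": None,
                   "free_fraction_human": None},
    "doseresponse": {"fix_a": None, "fix_b": None, "fix_d": None},
    "occupancy": {"region": None, "rescale_to_asymptote": None,
                  "emax_fixed": None},
    "pet": {"occupancy": None, "noise_scale": None},
    "eeg": {"n_subjects": None, "duration_s": None, "n_recordings": None,
            "n_perm": None, "cluster_alpha": None, "alignment_target_hz": None,
            "amplitude_reject_uv": None, "effects": None},
}

_DEFAULTS = {
    "seed": 0,
    "output_dir": "neuropd_run",
    "stages": list(STAGES),
    "conversion": {"molecular_weight": 445.469,
                   "free_fraction_rat": 0.14,
                   "free_fraction_human": 0.055},
    "doseresponse": {"fix_a": 0.0, "fix_b": None, "fix_d": None},
    "occupancy": {"region": "hippocampus", "rescale_to_asymptote": True,
                  "emax_fixed": None},
    "pet": {"occupancy": 0.94, "noise_scale": 0.0},
    "eeg": {"n_subjects": 12, "duration_s": 220.0, "n_recordings": 1,
            "n_perm": 1000, "cluster_alpha": 0.01,
            "alignment_target_hz": 9.3, "amplitude_reject_uv": 150.0,
            "effects": [
                {"center_hz": 7.3, "width_octaves": 0.5, "change": 0.19},
                {"center_hz": 34.9, "width_octaves": 0.5, "change": -0.19},
            ]},
}


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    def check(sub, schema, prefix):
        unknown = [f"{prefix}{k}" for k in sub if k not in schema]
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        for k, v in sub.items():
            if isinstance(schema[k], dict):
                if not isinstance(v, dict):
                    raise ConfigError(f"section {prefix}{k} must be a mapping")
                check(v, schema[k], f"{prefix}{k}.")

    cfg = cfg or {}
    check(cfg, _SCHEMA, "")
    merged = json.loads(json.dumps(_DEFAULTS))
    for k, v in cfg.items():
        if isinstance(v, dict):
            merged[k].update(v)
        else:
            merged[k] = v
    bad = [s for s in merged["stages"] if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    return merged


def load_config(path) -> dict:
    return validate_config(yaml.safe_load(Path(path).read_text()) or {})


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (independent of execution order)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the configured stages and return the manifest."""
    cfg = validate_config(config)
    out = Path(out_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": cfg["seed"], "config": cfg,
                "stages": {}, "timing": {}}

    runners = {"synth": _stage_synth, "doseresponse": _stage_doseresponse,
               "occupancy": _stage_occupancy, "pet": _stage_pet,
               "eeg": _stage_eeg}
    # dependency order is the canonical stage order
    for stage in [s for s in STAGES if s in cfg["stages"]]:
        sub_seed = stage_seed(cfg["seed"], stage)
        log.info("stage=%s status=start seed=%d", stage, sub_seed)
        t0 = time.time()
        try:
            outputs = runners[stage](cfg, out, sub_seed)
        except FileNotFoundError as exc:
            raise RuntimeError(
                f"stage {stage!r}: missing input {exc.filename!r}; run the "
                f"'synth' stage (or provide the file) first") from exc
        manifest["stages"][stage] = {
            "seed": sub_seed,
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }
        manifest["timing"][stage] = round(time.time() - t0, 3)
        log.info("stage=%s status=done elapsed=%.1fs", stage,
                 manifest["timing"][stage])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def analyze_eeg_study(study, n_perm=1000, cluster_alpha=0.01, seed=0,
                      target_hz=9.3, reject_uv=150.0):
    """Full spectral analysis of a (synthetic or loaded) EEG study.

    Preprocess every recording, estimate wavelet spectra, align each
    subject's spectra to the group alpha target, normalise to relative
    power, compute drug-versus-baseline percent change, and run the
    cluster randomization test on the channel-averaged relative spectra.
    Frequencies lost to alignment padding (NaN in any subject) are dropped
    from the test; they sit at the grid edges because alignment shifts are
    constant per subject.

    Returns a dict with the grid, subject ids, per-subject change spectra
    (channel-averaged and channel-resolved), the cluster result, and the
    tested frequencies.
    """
    grid = log_frequency_grid()
    specs = {"baseline": {}, "drug": {}}
    for rec in study.recordings:
        r = preprocess(rec, amplitude_reject_uv=reject_uv)
        specs[rec.condition].setdefault(rec.subject, []).append(
            wavelet_power(r, grid))
    aligned = {"baseline": {}, "drug": {}}
    for subject in sorted(specs["baseline"]):
        peak = detect_alpha_peak(specs["baseline"][subject][0])
        for cond in ("baseline", "drug"):
            aligned[cond][subject] = [
                relative_power(align_to_mean_alpha(sp, peak, target_hz))
                for sp in specs[cond][subject]]

    subjects, change_ch, change = power_change(aligned["drug"],
                                               aligned["baseline"])

    def condition_matrix(cond):
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            for subject in subjects:
                stack = np.stack([sp.power for sp in aligned[cond][subject]])
                rows.append(np.nanmean(stack, axis=(0, 1)))
        return np.stack(rows)

    a, b = condition_matrix("drug"), condition_matrix("baseline")
    valid = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
    result = cluster_randomization_test(a[:, valid], b[:, valid],
                                        n_perm=n_perm,
                                        cluster_alpha=cluster_alpha,
                                        seed=seed)
    attach_frequencies(result, grid.freqs_hz[valid])
    return {"grid": grid, "subjects": subjects, "change": change,
            "change_channel": change_ch, "clusters": result,
            "tested_freqs_hz": grid.freqs_hz[valid]}


# -- stages ---------------------------------------------------------------------

def _stage_synth(cfg, out, seed):
    rng = np.random.default_rng(seed)
    written = []

    truth = HillTruth(A=0.0, B=-42.0, C=8.0, D=0.9)
    concs = np.geomspace(1.0, 1000.0, 8)
    table = gen_conc_response(truth, concs, replicates=8,
                              noise_sd=0.02 * abs(truth.B - truth.A),
                              seed=int(rng.integers(2 ** 31)))
    p = out / "conc_response.csv"
    io.write_conc_response(table, p)
    io.write_truth_sidecar(truth, out / "conc_response.truth.json")
    written += [p, out / "conc_response.truth.json"]

    cohort_truth = OccupancyCohortTruth(seed=int(rng.integers(2 ** 31)))
    cohort = gen_occupancy_cohort(cohort_truth)
    p = out / "cohort.csv"
    io.write_cohort(cohort, p)
    io.write_truth_sidecar(cohort_truth, out / "cohort.truth.json")
    written += [p, out / "cohort.truth.json"]

    # human exposure-occupancy subjects (9, spanning the dose range)
    ec50, emax = 541.0, 1.0
    plasma = np.geomspace(60.0, 4000.0, 9)
    occ = emax * plasma / (ec50 + plasma) + rng.normal(0, 0.05, 9)
    np.savetxt(out / "human_occupancy.csv",
               np.column_stack([plasma, occ]), delimiter=",",
               header="plasma_ng_ml,occupancy", comments="")
    written.append(out / "human_occupancy.csv")

    pet_truth = PETStudyTruth(occupancy=float(cfg["pet"]["occupancy"]),
                              noise_scale=float(cfg["pet"]["noise_scale"]),
                              seed=int(rng.integers(2 ** 31)))
    study = gen_pet_study(pet_truth)
    tacs = [tac for scan in study.scans.values() for tac in scan.values()]
    p = out / "tacs.csv"
    io.write_tacs(tacs, p)
    io.write_scan_meta(study.meta, out / "scan_meta.json")
    written += [p, out / "scan_meta.json"]

    eeg_cfg = cfg["eeg"]
    effects = tuple(EEGEffect(**e) for e in eeg_cfg["effects"])
    eeg_truth = EEGStudyTruth(n_subjects=int(eeg_cfg["n_subjects"]),
                              duration_s=float(eeg_cfg["duration_s"]),
                              n_recordings=int(eeg_cfg["n_recordings"]),
                              effects=effects,
                              seed=int(rng.integers(2 ** 31)))
    study = gen_eeg_study(eeg_truth)
    eeg_dir = out / "eeg"
    eeg_dir.mkdir(exist_ok=True)
    for rec in study.recordings:
        p = eeg_dir / f"{rec.subject}_{rec.condition}_{rec.rec_index}.csv"
        io.write_eeg_csv(rec, p)
        written += [p, p.with_suffix(".json")]
    return written


def _stage_doseresponse(cfg, out, seed):
    table = io.read_conc_response(out / "conc_response.csv")
    fixed = {}
    for key, name in (("fix_a", "A"), ("fix_b", "B"), ("fix_d", "D")):
        if cfg["doseresponse"][key] is not None:
            fixed[name] = float(cfg["doseresponse"][key])
    fit = fit_hill(table["conc_nM"], table["response"], fixed=fixed)
    p = out / "doseresponse_fit.json"
    p.write_text(json.dumps(fit.to_dict(), indent=2))
    return [p]


def _stage_occupancy(cfg, out, seed):
    conv = cfg["conversion"]
    cohort = io.read_cohort(out / "cohort.csv")
    region = cfg["occupancy"]["region"]
    table, fit = rat_occupancy_table(
        cohort, region,
        rescale_to_asymptote=bool(cfg["occupancy"]["rescale_to_asymptote"]))
    spec = PlasmaConversionSpec(conv["molecular_weight"],
                                conv["free_fraction_rat"])
    report = {"region": region, "hill_fit": fit.to_dict(),
              "ec50_total_ng_ml": fit.C,
              "ec50_free_nM": total_to_free_nM(fit.C, spec)}
    p1 = out / "rat_occupancy.csv"
    table.to_csv(p1, index=False)

    human = np.loadtxt(out / "human_occupancy.csv", delimiter=",", skiprows=1)
    efit = fit_emax(human[:, 0], human[:, 1],
                    fix_emax=cfg["occupancy"]["emax_fixed"])
    hspec = PlasmaConversionSpec(conv["molecular_weight"],
                                 conv["free_fraction_human"])
    report["emax_fit"] = efit.to_dict()
    report["human_ec50_free_nM"] = total_to_free_nM(efit.ec50, hspec)
    p2 = out / "occupancy_report.json"
    p2.write_text(json.dumps(report, indent=2))
    return [p1, p2]


def _stage_pet(cfg, out, seed):
    scans = io.read_tacs(out / "tacs.csv")
    meta = io.read_scan_meta(out / "scan_meta.json")
    report = {"reference_region": meta.reference_region, "regions": {}}
    fits = {}
    for scan_id, regions in scans.items():
        ref = regions[meta.reference_region]
        for name, tac in regions.items():
            if name == meta.reference_region:
                continue
            fits[(scan_id, name)] = srtm_fit_basis(tac, ref)
    for (scan_id, name), f in fits.items():
        report["regions"].setdefault(name, {})[scan_id] = {
            "R1": f.r1, "k2_per_min": f.k2, "BP_ND": f.bp_nd, "rss": f.rss}
    for name, per_scan in report["regions"].items():
        if {"baseline", "postdose"} <= set(per_scan):
            per_scan["occupancy"] = occupancy_from_bp(
                per_scan["baseline"]["BP_ND"], per_scan["postdose"]["BP_ND"])
    p = out / "pet_report.json"
    p.write_text(json.dumps(report, indent=2))
    return [p]


class _LoadedStudy:
    def __init__(self, recordings):
        self.recordings = recordings


def _stage_eeg(cfg, out, seed):
    eeg_cfg = cfg["eeg"]
    eeg_dir = out / "eeg"
    if not eeg_dir.exists():
        raise RuntimeError("stage 'eeg': missing input directory 'eeg'; "
                           "run the 'synth' stage first")
    study = _LoadedStudy([io.read_eeg_csv(p)
                          for p in sorted(eeg_dir.glob("*.csv"))])
    res = analyze_eeg_study(study, n_perm=int(eeg_cfg["n_perm"]),
                            cluster_alpha=float(eeg_cfg["cluster_alpha"]),
                            seed=seed,
                            target_hz=float(eeg_cfg["alignment_target_hz"]),
                            reject_uv=float(eeg_cfg["amplitude_reject_uv"]))
    grid, subjects, change = res["grid"], res["subjects"], res["change"]
    result = res["clusters"]

    summary = {"subjects": subjects,
               "clusters": [{"start_hz": c.start_hz, "end_hz": c.end_hz,
                             "size": c.size, "sign": c.sign, "p": c.p_value}
                            for c in result.clusters]}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for c in result.significant():
            if c.size < 3:  # too narrow for a peak-frequency estimate
                continue
            est = jackknife_peak(change, grid.freqs_hz,
                                 band=(c.start_hz, c.end_hz),
                                 mode="max" if c.sign > 0 else "min")
            key = f"peak_{'pos' if c.sign > 0 else 'neg'}_hz"
            summary[key] = {"mean": est.mean_hz, "sem": est.sem_hz}
            sel = (grid.freqs_hz >= c.start_hz) & (grid.freqs_hz <= c.end_hz)
            summary[key]["mean_change_pct"] = float(np.nanmean(change[:, sel]))

    rows = []
    for s_idx, subject in enumerate(subjects):
        for f_idx, f_hz in enumerate(grid.freqs_hz):
            rows.append((subject, f_hz, change[s_idx, f_idx]))
    p1 = out / "eeg_change.csv"
    pd.DataFrame(rows, columns=["subject", "freq_hz", "change_pct"]).to_csv(
        p1, index=False)
    p2 = out / "eeg_summary.json"
    p2.write_text(json.dumps(summary, indent=2))
    return [p1, p2]
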