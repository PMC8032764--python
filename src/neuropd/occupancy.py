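"""Receptor-occupancy quantification from ex vivo autoradiography and PET.

Rat arm: radioligand signal under a saturating dose of a selective blocker
estimates the non-displaceable component (off-target subtypes plus classical
nonspecific binding); specific binding ``S`` is each animal's signal minus
the blocker-group mean, occupancy is the fractional reduction of ``S``
relative to the vehicle-group mean, and occupancy versus individual plasma
concentration is fitted with a Hill curve constrained to slope 1.

Human arm: occupancy is the fractional reduction of the SRTM binding
potential BP_ND between a baseline and a post-dose scan, and the
exposure-occupancy relation is fitted with an Emax model
``E = Emax * C / (EC50 + C)`` with profile-likelihood confidence intervals.

Plasma units: total ng/mL are converted to free nM with
``free_nM = conc * 1000 / MW * free_fraction``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .doseresponse import HillFit, fit_hill

__all__ = [
    "PlasmaConversionSpec",
    "SpecificBindingResult",
    "EmaxFit",
    "specific_binding",
    "percent_occupancy",
    "fit_occupancy_vs_plasma",
    "total_to_free_nM",
    "fit_emax",
    "occupancy_from_bp",
    "rat_occupancy_table",
]

VEHICLE = "vehicle"
BLOCKER = "blocker"
DRUG = "drug"


@dataclass(frozen=True)
class PlasmaConversionSpec:
    """Molecular weight (g/mol) and plasma free fraction (0-1]."""

    molecular_weight: float
    free_fraction: float

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if not 0 < self.free_fraction <= 1:
            raise ValueError("free fraction must be in (0, 1]")


@dataclass
class SpecificBindingResult:
    region: str
    nonspecific: float          # blocker-group mean signal (fmol/mg)
    vehicle_mean: float         # mean specific binding of vehicle animals
    table: pd.DataFrame         # per-animal rows with specific binding S
    negative_s_animals: list    # animal ids whose S < 0 (noise), flagged


def specific_binding(records: pd.DataFrame, region: str) -> SpecificBindingResult:
    """Per-animal specific binding in one region.

    ``records`` needs columns ``animal_id, treatment, region,
    signal_fmol_mg`` (``plasma_ng_ml`` is carried through when present).
    The blocker-group mean estimates the non-displaceable signal and is
    subtracted from every animal; negative values are permitted but
    flagged.
    """
    sub = records.loc[records["region"] == region].copy()
    blocker = sub.loc[sub["treatment"] == BLOCKER, "signal_fmol_mg"]
    vehicle = sub.loc[sub["treatment"] == VEHICLE, "signal_fmol_mg"]
    if blocker.empty:
        raise ValueError(f"no blocker (full-block) animals in region {region!r}")
    if vehicle.empty:
        raise ValueError(f"no vehicle animals in region {region!r}")

    nonspecific = float(blocker.mean())
    sub["specific_fmol_mg"] = sub["signal_fmol_mg"] - nonspecific
    vehicle_mean = float(
        sub.loc[sub["treatment"] == VEHICLE, "specific_fmol_mg"].mean()
    )
    neg = sub.loc[(sub["specific_fmol_mg"] < 0) & (sub["treatment"] != BLOCKER),
                  "animal_id"].tolist()
    return SpecificBindingResult(region=region, nonspecific=nonspecific,
                                 vehicle_mean=vehicle_mean, table=sub,
                                 negative_s_animals=neg)


def percent_occupancy(s_drug, s_vehicle_mean):
    """Occupancy y = 100 * (1 - S_drug / S_vehicle_mean), unclipped.

    Values outside [0, 100] can occur with noisy specific binding and are
    returned as-is.
    """
    if s_vehicle_mean <= 0:
        raise ValueError("vehicle-mean specific binding must be positive")
    return 100.0 * (1.0 - np.asarray(s_drug, dtype=float) / s_vehicle_mean)


def fit_occupancy_vs_plasma(plasma_ng_ml, occupancy_pct) -> HillFit:
    """Hill fit of percent occupancy versus plasma concentration, slope 1.

    The floor is fixed at 0; the asymptotic maximum B (which may fall
    short of 100% when the radioligand also labels off-target sites) and
    the half-maximal concentration C (EC50, ng/mL) are estimated.
    """
    occ = np.asarray(occupancy_pct, dtype=float)
    if np.all(np.abs(occ) < 1e-9):
        return HillFit(A=0.0, B=np.nan, C=np.nan, D=1.0, converged=False,
                       fixed=("A", "D"), n_obs=occ.size)
    return fit_hill(plasma_ng_ml, occ, fixed={"A": 0.0, "D": 1.0})


def total_to_free_nM(conc_ng_ml, spec: PlasmaConversionSpec):
    """Convert a total plasma concentration (ng/mL) to free nM."""
    conc = np.asarray(conc_ng_ml, dtype=float)
    if np.any(conc < 0):
        raise ValueError("plasma concentration must be non-negative")
    out = conc * 1000.0 / spec.molecular_weight * spec.free_fraction
    return float(out) if np.isscalar(conc_ng_ml) else out


@dataclass
class EmaxFit:
    emax: float                  # fraction (0, 1]
    ec50: float                  # same units as the input concentrations
    ci_emax: tuple               # 95% profile-likelihood interval
    ci_ec50: tuple
    rss: float
    n_obs: int
    converged: bool = True
    ci_unbounded: bool = False   # EC50 interval open-ended or > one decade wide

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.emax * conc / (self.ec50 + conc)

    def to_dict(self):
        return {"emax": self.emax, "ec50": self.ec50,
                "ci_emax": list(self.ci_emax), "ci_ec50": list(self.ci_ec50),
                "rss": self.rss, "n_obs": self.n_obs,
                "converged": self.converged, "ci_unbounded": self.ci_unbounded}


def _emax_rss(concs, occs, emax, ec50):
    r = occs - emax * concs / (ec50 + concs)
    return float(r @ r)


def fit_emax(concs, occupancies, fix_emax=None) -> EmaxFit:
    """Least-squares Emax fit of occupancy fractions versus concentration.

    ``fix_emax`` pins the plateau (e.g. 1.0 for full occupancy at
    saturation); otherwise Emax is estimated within (0, 1].  95% confidence
    intervals come from the profile-likelihood (F-test) criterion
    ``RSS(theta) <= RSS_min * (1 + F(1, n-p, 0.95)/(n-p))``.
    """
    x = np.asarray(concs, dtype=float).ravel()
    y = np.asarray(occupancies, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("concentration and occupancy lengths differ")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    pos = x[x > 0]
    if pos.size < 2:
        raise ValueError("need at least two positive concentrations")

    lo_c, hi_c = math.log10(pos.min() / 100.0), math.log10(pos.max() * 100.0)

    if fix_emax is not None:
        def resid(theta):
            return y - fix_emax * x / (10.0 ** theta[0] + x)
        sol = optimize.least_squares(resid, [np.median(np.log10(pos))],
                                     bounds=([lo_c], [hi_c]),
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14)
        emax, ec50 = float(fix_emax), 10.0 ** float(sol.x[0])
        n_free = 1
    else:
        def resid(theta):
            return y - theta[0] * x / (10.0 ** theta[1] + x)
        best = None
        for lc0 in np.quantile(np.log10(pos), [0.25, 0.5, 0.75]):
            sol = optimize.least_squares(
                resid, [min(max(y.max(), 0.1), 1.0), lc0],
                bounds=([1e-6, lo_c], [1.0, hi_c]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
        sol = best
        emax, ec50 = float(sol.x[0]), 10.0 ** float(sol.x[1])
        n_free = 2

    rss = float(2 * sol.cost)
    n, dof = x.size, x.size - n_free

    ci_emax = (emax, emax)
    ci_ec50 = (ec50, ec50)
    unbounded = False
    if dof > 0 and rss > 0:
        crit = rss * (1.0 + stats.f.ppf(0.95, 1, dof) / dof)

        def profile_rss_ec50(log_c):
            c = 10.0 ** log_c
            if fix_emax is not None:
                return _emax_rss(x, y, fix_emax, c)
            # Emax enters linearly given EC50: closed-form within (0, 1]
            g = x / (c + x)
            denom = g @ g
            e = float(np.clip((g @ y) / denom, 1e-6, 1.0)) if denom > 0 else 1.0
            return _emax_rss(x, y, e, c)

        ci_ec50, open_ended = _profile_interval(
            profile_rss_ec50, math.log10(ec50), crit, lo_c - 2, hi_c + 2,
            transform=lambda v: 10.0 ** v)
        # flag intervals open at either end or spanning over a decade:
        # the EC50 is then not usefully identified by the design
        unbounded = open_ended or (ci_ec50[0] > 0
                                   and ci_ec50[1] / ci_ec50[0] > 10.0)

        if fix_emax is None:
            def profile_rss_emax(e):
                r = optimize.minimize_scalar(
                    lambda lc: _emax_rss(x, y, e, 10.0 ** lc),
                    bounds=(lo_c - 2, hi_c + 2), method="bounded")
                return r.fun
            ci_emax, _ = _profile_interval(
                profile_rss_emax, emax, crit, 1e-6, 1.0)

    return EmaxFit(emax=emax, ec50=ec50, ci_emax=ci_emax, ci_ec50=ci_ec50,
                   rss=rss, n_obs=n, converged=bool(sol.success),
                   ci_unbounded=unbounded)


def _profile_interval(rss_of, center, crit, lo, hi, transform=None):
    """Bracket the two RSS(theta) = crit crossings around the optimum."""
    transform = transform or (lambda v: v)
    f = lambda v: rss_of(v) - crit
    if f(center) >= 0:
        # essentially perfect fit: the criterion is met only at the optimum
        return (transform(center), transform(center)), False

    def find(bound):
        if f(bound) < 0:  # criterion never exceeded inside the range
            return transform(bound), True
        grid = np.linspace(center, bound, 64)
        prev = grid[0]
        for g in grid[1:]:
            if f(g) > 0:
                return transform(optimize.brentq(f, prev, g)), False
            prev = g
        return transform(bound), True

    lo_v, lo_open = find(lo)
    hi_v, hi_open = find(hi)
    return (lo_v, hi_v), (lo_open or hi_open)


def occupancy_from_bp(bp_baseline, bp_drug):
    """Fractional reduction of BP_ND: (baseline - drug) / baseline."""
    if bp_baseline <= 0:
        raise ValueError("baseline BP_ND must be positive")
    return (bp_baseline - bp_drug) / bp_baseline


def rat_occupancy_table(records: pd.DataFrame, region: str,
                        rescale_to_asymptote: bool = True):
    """Full rat-arm quantification for one region.

    Computes per-animal specific binding, per treated animal occupancy
    versus its individual plasma level, and the slope-1 Hill fit of the
    exposure-occupancy relation.  With ``rescale_to_asymptote`` the
    occupancies are re-expressed relative to the fitted plateau B (the
    convention in which the curve's asymptote corresponds to 100%
    occupancy of the drug-accessible sites).

    Returns ``(table, fit)`` where ``table`` has one row per drug-treated
    animal.
    """
    sb = specific_binding(records, region)
    drug = sb.table.loc[sb.table["treatment"] == DRUG].copy()
    if drug.empty:
        raise ValueError(f"no drug-treated animals in region {region!r}")
    if drug["plasma_ng_ml"].isna().any():
        raise ValueError("drug-treated animals must have plasma concentrations")
    drug["occupancy_pct"] = percent_occupancy(
        drug["specific_fmol_mg"].to_numpy(), sb.vehicle_mean)
    fit = fit_occupancy_vs_plasma(drug["plasma_ng_ml"].to_numpy(),
                                  drug["occupancy_pct"].to_numpy())
    if rescale_to_asymptote and fit.converged and np.isfinite(fit.B) and fit.B > 0:
        drug["occupancy_rescaled_pct"] = drug["occupancy_pct"] * 100.0 / fit.B
    return drug, fit
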