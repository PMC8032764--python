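"""Concentration-response fitting and affinity/selectivity arithmetic.

The central model is the four-parameter logistic (Hill) curve

    y = A + (B - A) / (1 + (C / x)^D)

with floor ``A``, ceiling ``B``, midpoint ``C`` (an IC50 or EC50 in nM)
and Hill coefficient ``D``.  Binding IC50s are converted to equilibrium
inhibition constants with the Cheng-Prusoff correction
``Ki = IC50 / (1 + L/Kd)`` for radioligand concentration ``L`` and
radioligand affinity ``Kd``.  Subtype selectivity is summarised as fold
ratios of Ki values relative to a reference subtype, with support for
censored ("no binding above X") measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "HillFit",
    "CensoredKi",
    "FoldRatio",
    "SelectivityResult",
    "hill",
    "fit_hill",
    "cheng_prusoff",
    "modulation_percent",
    "fold_selectivity",
]

#: optimisation bounds for the Hill coefficient
_D_BOUNDS = (0.1, 10.0)


def hill(x, A, B, C, D):
    """Evaluate the four-parameter logistic at concentrations ``x`` (nM)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if C <= 0:
        raise ValueError("midpoint C must be positive")
    return A + (B - A) / (1.0 + (C / x) ** D)


@dataclass
class HillFit:
    """Result of a Hill-curve least-squares fit.

    ``se`` maps parameter names to standard errors; parameters that were
    held fixed do not appear in it.
    """

    A: float
    B: float
    C: float
    D: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    fixed: tuple = ()
    rss: float = float("nan")
    residual_sd: float = float("nan")
    n_obs: int = 0

    def predict(self, x):
        return hill(x, self.A, self.B, self.C, self.D)

    def to_dict(self):
        return {
            "A": self.A, "B": self.B, "C": self.C, "D": self.D,
            "se": dict(self.se), "converged": self.converged,
            "fixed": list(self.fixed), "rss": self.rss,
            "residual_sd": self.residual_sd, "n_obs": self.n_obs,
        }


_PNAMES = ("A", "B", "C", "D")


def fit_hill(concentrations, responses, fixed=None):
    """Fit the Hill equation by bounded least squares.

    Parameters
    ----------
    concentrations, responses : array-like
        Paired observations; replicates appear as repeated concentrations
        and all enter the loss individually.
    fixed : dict, optional
        Map of parameter name (``"A"``, ``"B"``, ``"D"``) to a constant,
        e.g. ``{"A": 0.0}`` for modulation curves or ``{"A": 0.0, "D": 1.0}``
        for exposure-occupancy curves.  ``C`` is always estimated.

    Notes
    -----
    The midpoint is optimised on a log10 scale with bounds tied to the
    observed concentration range (C in [min x / 100, max x * 100]) and the
    fit is restarted from three initial midpoints; the Hill model is badly
    conditioned on a linear concentration scale.
    """
    fixed = dict(fixed or {})
    if "C" in fixed:
        raise ValueError("the midpoint C cannot be fixed")
    unknown = set(fixed) - {"A", "B", "D"}
    if unknown:
        raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")

    x = np.asarray(concentrations, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")

    free = [p for p in _PNAMES if p not in fixed]
    n_distinct = np.unique(x).size
    if n_distinct < len(free):
        raise ValueError(
            f"need at least {len(free)} distinct concentrations, got {n_distinct}"
        )
    if np.ptp(y) == 0:  # degenerate: all responses equal
        return HillFit(A=np.nan, B=np.nan, C=np.nan, D=np.nan,
                       converged=False, fixed=tuple(fixed), n_obs=x.size)

    lo_c, hi_c = math.log10(x.min() / 100.0), math.log10(x.max() * 100.0)
    span = np.ptp(y)
    y_lo, y_hi = y.min() - 2 * span, y.max() + 2 * span

    # initial direction: does y increase with log x?
    lx = np.log(x)
    slope_sign = 1.0 if np.corrcoef(lx, y)[0, 1] >= 0 else -1.0

    # per-concentration means, for initialisation only
    ux = np.unique(x)
    my = np.array([y[x == v].mean() for v in ux])

    def init_AB():
        if slope_sign > 0:
            return my[0], my[-1]
        return my[-1], my[0]

    def pack(theta):
        vals = {}
        i = 0
        for p in _PNAMES:
            if p in fixed:
                vals[p] = float(fixed[p])
            elif p == "C":
                vals[p] = 10.0 ** theta[i]
                i += 1
            else:
                vals[p] = theta[i]
                i += 1
        return vals

    def resid(theta):
        v = pack(theta)
        return hill(x, v["A"], v["B"], v["C"], v["D"]) - y

    lo, hi, order = [], [], []
    for p in _PNAMES:
        if p in fixed:
            continue
        order.append(p)
        if p == "C":
            lo.append(lo_c); hi.append(hi_c)
        elif p == "D":
            lo.append(_D_BOUNDS[0]); hi.append(_D_BOUNDS[1])
        else:
            lo.append(y_lo); hi.append(y_hi)

    a0, b0 = init_AB()
    logc_inits = np.quantile(np.log10(ux), [0.25, 0.5, 0.75])
    best = None
    for lc0 in logc_inits:
        theta0 = []
        for p in order:
            if p == "A":
                theta0.append(np.clip(a0, y_lo, y_hi))
            elif p == "B":
                theta0.append(np.clip(b0, y_lo, y_hi))
            elif p == "C":
                theta0.append(np.clip(lc0, lo_c, hi_c))
            else:
                theta0.append(1.0)
        sol = optimize.least_squares(
            resid, theta0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    vals = pack(best.x)
    rss = float(2 * best.cost)
    dof = x.size - len(order)
    residual_sd = math.sqrt(rss / dof) if dof > 0 else float("nan")

    se = {}
    if dof > 0:
        J = best.jac
        try:
            cov = np.linalg.inv(J.T @ J) * rss / dof
            sd = np.sqrt(np.clip(np.diag(cov), 0, None))
            for p, s, t in zip(order, sd, best.x):
                # C was optimised as log10(C): delta-method back-transform
                se[p] = float(s * 10.0 ** t * math.log(10)) if p == "C" else float(s)
        except np.linalg.LinAlgError:
            pass

    return HillFit(A=vals["A"], B=vals["B"], C=vals["C"], D=vals["D"],
                   se=se, converged=best.success, fixed=tuple(fixed),
                   rss=rss, residual_sd=residual_sd, n_obs=x.size)


def cheng_prusoff(ic50, L, Kd):
    """Ki = IC50 / (1 + L/Kd) for radioligand concentration L and affinity Kd."""
    if Kd <= 0:
        raise ValueError("radioligand Kd must be positive")
    if L < 0:
        raise ValueError("radioligand concentration must be non-negative")
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    return ic50 / (1.0 + L / Kd)


def modulation_percent(control_current, test_current):
    """Percent change of a GABA-evoked current relative to control.

    Negative values indicate inhibition (negative allosteric modulation),
    positive values potentiation.
    """
    if control_current <= 0:
        raise ValueError("control current must be positive")
    return 100.0 * (test_current / control_current - 1.0)


@dataclass(frozen=True)
class CensoredKi:
    """Lower-bound affinity: no displacement observed up to ``bound`` nM."""

    bound: float

    def __post_init__(self):
        if self.bound <= 0:
            raise ValueError("censoring bound must be positive")


@dataclass(frozen=True)
class FoldRatio:
    value: float
    censored: bool = False


@dataclass
class SelectivityResult:
    reference: str
    ratios: dict
    min_ratio: float
    min_subtype: str
    min_censored: bool


def fold_selectivity(ki_by_subtype, reference):
    """Fold selectivity of each subtype's Ki over the reference subtype's.

    Censored entries (:class:`CensoredKi`) contribute lower-bound ratios
    flagged as censored.  Returns all ratios plus the minimum across
    subtypes (the headline selectivity figure).
    """
    if reference not in ki_by_subtype:
        raise ValueError(f"reference subtype {reference!r} missing")
    ref = ki_by_subtype[reference]
    if isinstance(ref, CensoredKi):
        raise ValueError("reference Ki may not be censored")
    if ref <= 0:
        raise ValueError("Ki values must be positive")

    ratios = {}
    for name, ki in ki_by_subtype.items():
        if name == reference:
            continue
        if isinstance(ki, CensoredKi):
            ratios[name] = FoldRatio(ki.bound / ref, censored=True)
        else:
            if ki <= 0:
                raise ValueError("Ki values must be positive")
            ratios[name] = FoldRatio(ki / ref, censored=False)

    if ratios:
        min_subtype = min(ratios, key=lambda n: ratios[n].value)
        min_ratio = ratios[min_subtype].value
        min_censored = ratios[min_subtype].censored
    else:
        min_subtype, min_ratio, min_censored = reference, 1.0, False
    return SelectivityResult(reference=reference, ratios=ratios,
                             min_ratio=min_ratio, min_subtype=min_subtype,
                             min_censored=min_censored)
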