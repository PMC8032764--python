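"""Randomization statistics for spectra: clusters, peak frequencies, topographies.

Three procedures, all seed-controlled:

* a cluster-based randomization test over the frequency axis for paired
  spectra (baseline versus drug): per-frequency paired t-tests are
  thresholded at a cluster-forming alpha, maximal contiguous same-sign runs
  form clusters, and observed cluster sizes are referred to the permutation
  distribution of the largest cluster size obtained by sign-flipping the
  within-subject differences (this controls the familywise error across
  frequencies for effects of either sign);
* jackknife pseudo-value estimation of the peak frequency of a group-level
  effect spectrum, providing a standard error for (and t-tests between)
  peak locations of non-linear group statistics;
* a topography-similarity randomization test comparing the average
  within-drug correlation of subjects' effect topographies against the
  between-drug correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats

__all__ = [
    "Cluster",
    "ClusterResult",
    "PeakEstimate",
    "TopographyTestResult",
    "cluster_randomization_test",
    "attach_frequencies",
    "jackknife_pseudo_values",
    "jackknife_peak",
    "compare_peaks",
    "topography_similarity_test",
]


@dataclass
class Cluster:
    start_hz: float
    end_hz: float
    size: int         # number of grid frequencies
    sign: int         # +1 increase, -1 decrease
    p_value: float
    mass: float       # summed t-values (optional statistic)


@dataclass
class ClusterResult:
    clusters: list
    t_values: np.ndarray
    p_values: np.ndarray
    n_perm: int
    cluster_alpha: float
    exhaustive: bool = False

    def significant(self, alpha=0.05):
        return [c for c in self.clusters if c.p_value < alpha]


def _paired_t(diffs):
    """Per-frequency paired t statistics for an (n_sub, n_freq) array."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def _find_clusters(above, sign, t):
    """Maximal contiguous supra-threshold runs of a common sign.

    Yields ``(first_index, last_index, sign, t_mass)`` tuples.
    """
    out = []
    i = 0
    nf = above.size
    while i < nf:
        if above[i]:
            j = i
            while j + 1 < nf and above[j + 1] and sign[j + 1] == sign[i]:
                j += 1
            out.append((i, j, int(sign[i]), float(np.sum(t[i:j + 1]))))
            i = j + 1
        else:
            i += 1
    return out


def _sign_matrix(n_sub, n_perm, rng):
    """Sign-flip assignments; exhaustive enumeration when feasible."""
    if 2 ** n_sub <= n_perm:
        signs = np.array(list(product((1.0, -1.0), repeat=n_sub)))
        return signs, True
    return rng.choice([1.0, -1.0], size=(n_perm, n_sub)), False


def cluster_randomization_test(spectra_a, spectra_b, n_perm=10000,
                               cluster_alpha=0.01, seed=0,
                               statistic="size") -> ClusterResult:
    """Paired cluster test of condition A versus condition B across frequency.

    ``spectra_a`` and ``spectra_b`` are (n_subjects, n_freq) arrays with
    matched subject rows; ``statistic`` selects the cluster summary referred
    to the null distribution (``"size"`` = number of grid frequencies, the
    default; ``"mass"`` = summed absolute t).  Cluster p-values are
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    a = np.asarray(spectra_a, dtype=float)
    b = np.asarray(spectra_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("conditions must be matched (n_subjects, n_freq) arrays")
    n_sub, n_freq = a.shape
    if n_sub < 5:
        raise ValueError("need at least 5 paired subjects")
    if statistic not in ("size", "mass"):
        raise ValueError("statistic must be 'size' or 'mass'")

    diffs = a - b
    t_obs = _paired_t(diffs)
    dof = n_sub - 1
    t_crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, dof)
    p_freq = 2.0 * stats.t.sf(np.abs(t_obs), dof)
    observed = _find_clusters(np.abs(t_obs) > t_crit, np.sign(t_obs), t_obs)

    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n_sub, n_perm, rng)
    n_eff = signs.shape[0]

    # sum of squares is sign-invariant: the permuted t only needs the mean
    ss = np.sum(diffs * diffs, axis=0)
    null_max = np.zeros(n_eff)
    means = (signs @ diffs) / n_sub
    var = (ss / n_sub - means ** 2) * (n_sub / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = means / np.sqrt(var / n_sub)
    t_null = np.nan_to_num(t_null)
    above = np.abs(t_null) > t_crit
    sgn = np.sign(t_null)
    for k in range(n_eff):
        best = 0.0
        for i0, i1, s, mass in _find_clusters(above[k], sgn[k], t_null[k]):
            val = (i1 - i0 + 1) if statistic == "size" else abs(mass)
            best = max(best, val)
        null_max[k] = best

    clusters = []
    for i0, i1, s, mass in observed:
        val = (i1 - i0 + 1) if statistic == "size" else abs(mass)
        p = (1.0 + np.sum(null_max >= val)) / (n_eff + 1.0)
        clusters.append(Cluster(start_hz=float(i0), end_hz=float(i1),
                                size=i1 - i0 + 1, sign=s, p_value=float(p),
                                mass=mass))
    return ClusterResult(clusters=clusters, t_values=t_obs, p_values=p_freq,
                         n_perm=n_eff, cluster_alpha=cluster_alpha,
                         exhaustive=exhaustive)


def attach_frequencies(result: ClusterResult, freqs_hz):
    """Replace grid-index cluster bounds with actual frequencies (Hz)."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    for c in result.clusters:
        c.start_hz = float(freqs_hz[int(c.start_hz)])
        c.end_hz = float(freqs_hz[int(c.end_hz)])
    return result


# -- jackknife pseudo-value peak estimation -------------------------------------

def jackknife_pseudo_values(samples, statistic):
    """Jackknife pseudo-values of a group statistic.

    ``samples`` is an (n, ...) array of per-subject data and ``statistic``
    maps such an array to a scalar.  Pseudo-values are
    ``p_i = n * theta_full - (n - 1) * theta_(-i)``; for a statistic linear
    in the subjects their mean equals the full-sample statistic exactly,
    and in general their mean and SD give a bias-corrected estimate and a
    standard error.
    """
    x = np.asarray(samples)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    theta_full = statistic(x)
    pseudo = np.empty(n)
    for i in range(n):
        pseudo[i] = n * theta_full - (n - 1) * statistic(np.delete(x, i, axis=0))
    return pseudo, theta_full


@dataclass
class PeakEstimate:
    mean_hz: float
    sem_hz: float
    pseudo_values_hz: np.ndarray
    band: tuple
    n_subjects: int
    flat: bool = False


def _interp_peak_log2(values, log2_freqs, mode):
    """Peak location in log2-frequency with parabolic refinement.

    ``mode``: 'max' for positive effects, 'min' for negative ones.
    Sub-grid resolution matters because effect peaks rarely sit exactly on
    the 1/8-octave grid.
    """
    v = values if mode == "max" else -values
    k = int(np.nanargmax(v))
    if 0 < k < v.size - 1 and np.all(np.isfinite(v[k - 1:k + 2])):
        y0, y1, y2 = v[k - 1], v[k], v[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # proper local maximum
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            step = log2_freqs[1] - log2_freqs[0]
            return log2_freqs[k] + delta * step
    return log2_freqs[k]


def jackknife_peak(effect_spectra, freqs_hz, band, mode="max") -> PeakEstimate:
    """Jackknife pseudo-value estimate of a group effect's peak frequency.

    The statistic is the peak (in log2-frequency, parabolically
    interpolated) of the subject-mean effect spectrum within ``band``.
    Pseudo-values ``p_i = n*theta_full - (n-1)*theta_(-i)`` yield a mean and
    SEM on the log2 scale, reported back in Hz.
    """
    x = np.asarray(effect_spectra, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need an (n_subjects >= 3, n_freq) effect array")
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    sel = (freqs_hz >= band[0]) & (freqs_hz <= band[1])
    if sel.sum() < 3:
        raise ValueError("band must contain at least 3 grid frequencies")
    lf = np.log2(freqs_hz[sel])
    xb = x[:, sel]
    n = x.shape[0]

    flat = bool(np.nanstd(xb.mean(axis=0)) == 0)
    pseudo, _ = jackknife_pseudo_values(
        xb, lambda s: _interp_peak_log2(s.mean(axis=0), lf, mode))
    mean_l2 = float(pseudo.mean())
    sem_l2 = float(pseudo.std(ddof=1) / math.sqrt(n))
    return PeakEstimate(mean_hz=2.0 ** mean_l2,
                        sem_hz=(2.0 ** mean_l2) * math.log(2.0) * sem_l2,
                        pseudo_values_hz=2.0 ** pseudo,
                        band=tuple(band), n_subjects=n, flat=flat)


def compare_peaks(est_a: PeakEstimate, est_b: PeakEstimate, paired=True):
    """Two-sample t-test on jackknife pseudo-values (log2 scale); returns p.

    ``paired`` assumes the same subjects in the same order underwent both
    drugs (the default for a crossover design); otherwise Welch's test.
    """
    a = np.log2(est_a.pseudo_values_hz)
    b = np.log2(est_b.pseudo_values_hz)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal subject counts")
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p)


# -- topography similarity -------------------------------------------------------

@dataclass
class TopographyTestResult:
    r_within: tuple      # per drug
    r_between: float
    statistic: float     # mean(r_within) - r_between
    p_value: float
    n_perm: int
    excluded_subjects: list = field(default_factory=list)


def _mean_pairwise(corr, idx_a, idx_b):
    if np.array_equal(idx_a, idx_b):
        iu = np.triu_indices(len(idx_a), k=1)
        return float(corr[np.ix_(idx_a, idx_a)][iu].mean())
    return float(corr[np.ix_(idx_a, idx_b)].mean())


def topography_similarity_test(topos_a, topos_b, n_perm=10000,
                               seed=0) -> TopographyTestResult:
    """Are two drugs' effect topographies more similar within than between?

    ``topos_a``/``topos_b`` are (n_subjects, n_channels) band-topography
    arrays for the two drugs on the same montage.  The statistic is the
    mean of the two within-drug average pairwise Pearson correlations minus
    the between-drug average correlation; its null distribution comes from
    permuting the drug labels of the stacked topographies (one-sided p).
    Zero-variance topographies are excluded with a warning entry.
    """
    a = np.asarray(topos_a, dtype=float)
    b = np.asarray(topos_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("topographies must be (n_subjects, n_channels) on "
                         "a shared montage")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 subjects per drug")

    stacked = np.vstack([a, b])
    sd = stacked.std(axis=1)
    excluded = list(np.nonzero(sd == 0)[0])
    keep = sd > 0
    stacked = stacked[keep]
    na = int(keep[:a.shape[0]].sum())
    nb = stacked.shape[0] - na
    if na < 2 or nb < 2:
        raise ValueError("too few subjects with non-degenerate topographies")

    corr = np.corrcoef(stacked)
    n_tot = stacked.shape[0]
    idx = np.arange(n_tot)

    def statistic(order):
        ia, ib = order[:na], order[na:]
        rw1 = _mean_pairwise(corr, ia, ia)
        rw2 = _mean_pairwise(corr, ib, ib)
        rb = _mean_pairwise(corr, ia, ib)
        return rw1, rw2, rb, 0.5 * (rw1 + rw2) - rb

    rw1, rw2, rb, obs = statistic(idx)

    # vectorised label permutations: with indicator z of drug-A membership,
    # the within/between correlation sums are quadratic forms in z
    rng = np.random.default_rng(seed)
    z = np.zeros((n_perm, n_tot))
    for k in range(n_perm):
        z[k, rng.permutation(n_tot)[:na]] = 1.0
    zc = z @ corr
    s_aa = np.einsum("ki,ki->k", zc, z) - na
    w = 1.0 - z
    s_bb = np.einsum("ki,ki->k", w @ corr, w) - nb
    s_ab = np.einsum("ki,ki->k", zc, w)
    null = 0.5 * (s_aa / (na * (na - 1)) + s_bb / (nb * (nb - 1))) \
        - s_ab / (na * nb)
    p = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    return TopographyTestResult(r_within=(rw1, rw2), r_between=rb,
                                statistic=obs, p_value=float(p), n_perm=n_perm,
                                excluded_subjects=excluded)
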