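"""Per-wavenumber group comparison of spectral fingerprints.

For two groups of preprocessed spectra this module computes, per retained
wavenumber: the differential fingerprint Delta = mean(cases) - mean(refs),
the reference-group SD, the two-tailed Student t p-value (pooled variance;
Welch optional), the Mann-Whitney AUC = U/(n1*n2) with ties counted one
half, and the standardized effect size Delta / SD_ref. The area under the
absolute differential fingerprint is integrated trapezoidally per
contiguous grid segment (never across the silent-region gap). A PCA site
check tests whether one diagnosis group clusters by clinical site in the
subspace carrying >= 95% of the variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectra import contiguous_segments

__all__ = [
    "WavenumberStats",
    "PcaSiteCheck",
    "differential_fingerprint",
    "pointwise_ttest",
    "pointwise_auc",
    "effect_size_curve",
    "area_abs_diff",
    "compare_groups",
    "pca_site_check",
]


@dataclass
class WavenumberStats:
    wavenumbers: np.ndarray
    delta: np.ndarray
    sd_ref: np.ndarray
    p_t: np.ndarray
    auc_w: np.ndarray
    effect: np.ndarray
    n1: int
    n2: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "wavenumber": self.wavenumbers, "delta": self.delta,
            "sd_ref": self.sd_ref, "p_t": self.p_t, "auc_w": self.auc_w,
            "effect": self.effect,
        })


def _as_matrices(cases, refs):
    A = np.atleast_2d(np.asarray(cases, dtype=float))
    B = np.atleast_2d(np.asarray(refs, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("case and reference matrices must share the grid")
    return A, B


def differential_fingerprint(cases, refs):
    """Elementwise mean difference and reference-group SD (ddof=1).

    Returns ``(delta, sd_ref)``.
    """
    A, B = _as_matrices(cases, refs)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both groups need at least 2 samples")
    return A.mean(axis=0) - B.mean(axis=0), B.std(axis=0, ddof=1)


def pointwise_ttest(cases, refs, welch: bool = False) -> np.ndarray:
    """Two-tailed two-sample t-test p-value per wavenumber.

    Student's pooled-variance test by default (``welch=True`` switches to
    unequal variances). Columns with zero pooled variance get p = 1 when the
    means agree and p = float tiny otherwise.
    """
    A, B = _as_matrices(cases, refs)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both groups need at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(A, B, axis=0, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    bad = ~np.isfinite(p) | zero_var
    if bad.any():
        same = np.abs(A.mean(axis=0) - B.mean(axis=0)) < 1e-12
        p[bad & same] = 1.0
        p[bad & ~same] = np.finfo(float).tiny
    return p


def pointwise_auc(cases, refs) -> np.ndarray:
    """Mann-Whitney AUC per wavenumber: U/(n1*n2), ties counted one half.

    Exact (rank-based), no normal approximation; oriented so that values
    above 0.5 mean cases tend to exceed references.
    """
    A, B = _as_matrices(cases, refs)
    n1, n2 = A.shape[0], B.shape[0]
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    joint = np.concatenate([A, B], axis=0)
    ranks = sps.rankdata(joint, axis=0)  # midranks handle ties
    r1 = ranks[:n1].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)


def effect_size_curve(delta, sd_ref) -> np.ndarray:
    """Standardized differential fingerprint Delta / SD_ref."""
    delta = np.asarray(delta, dtype=float)
    sd_ref = np.asarray(sd_ref, dtype=float)
    if np.any(sd_ref <= 0):
        raise ValueError("sd_ref must be positive everywhere")
    return delta / sd_ref


def area_abs_diff(delta, wavenumbers) -> float:
    """Trapezoidal integral of |Delta| (AU * cm^-1), summed over contiguous
    grid segments; the silent-region gap contributes nothing."""
    delta = np.asarray(delta, dtype=float)
    wn = np.asarray(wavenumbers, dtype=float)
    if delta.shape != wn.shape:
        raise ValueError("delta and wavenumbers must have equal length")
    return float(sum(np.trapezoid(np.abs(delta[seg]), wn[seg])
                     for seg in contiguous_segments(wn)))


def compare_groups(cases, refs, wavenumbers) -> WavenumberStats:
    """All per-wavenumber statistics in one pass."""
    A, B = _as_matrices(cases, refs)
    delta, sd_ref = differential_fingerprint(A, B)
    return WavenumberStats(
        wavenumbers=np.asarray(wavenumbers, dtype=float),
        delta=delta,
        sd_ref=sd_ref,
        p_t=pointwise_ttest(A, B),
        auc_w=pointwise_auc(A, B),
        effect=np.divide(delta, sd_ref, out=np.zeros_like(delta),
                         where=sd_ref > 0),
        n1=A.shape[0],
        n2=B.shape[0],
    )


# ------------------------------------------------------------------ PCA check
@dataclass
class PcaSiteCheck:
    explained_variance_ratio: np.ndarray
    n_components: int
    statistic: float                 # between-site centroid dispersion
    p_value: float
    site_sizes: pd.Series


def _between_site_dispersion(scores: np.ndarray, codes: np.ndarray,
                             n_sites: int) -> float:
    grand = scores.mean(axis=0)
    stat = 0.0
    for s in range(n_sites):
        sub = scores[codes == s]
        stat += sub.shape[0] * float(np.sum((sub.mean(axis=0) - grand) ** 2))
    return stat


def pca_site_check(X, sites, var_target: float = 0.95, n_perm: int = 999,
                   seed: int = 0) -> PcaSiteCheck:
    """Test for clinical-site clustering within one diagnosis group.

    PCA on centered spectra; the smallest number of leading components
    reaching ``var_target`` cumulative explained variance is retained; the
    weighted between-site centroid dispersion in that subspace is compared
    to its permutation distribution (site labels shuffled).
    """
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    sites = pd.Series(np.asarray(sites))
    counts = sites.value_counts()
    if len(counts) < 2:
        raise ValueError("at least two sites are required")
    if counts.min() < 3:
        raise ValueError("every site needs at least 3 samples")

    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]))
    scores_full = pca.fit_transform(X - X.mean(axis=0))
    evr = pca.explained_variance_ratio_
    m = int(np.searchsorted(np.cumsum(evr), var_target) + 1)
    m = min(m, scores_full.shape[1])
    scores = scores_full[:, :m]

    codes = pd.factorize(sites)[0]
    n_sites = codes.max() + 1
    obs = _between_site_dispersion(scores, codes, n_sites)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _between_site_dispersion(scores, perm, n_sites) >= obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PcaSiteCheck(explained_variance_ratio=evr, n_components=m,
                        statistic=obs, p_value=p, site_sizes=counts)
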