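"""Spectral quality control via a from-scratch Local Outlier Factor.

Classical LOF: for each point, the k-distance is the distance to its k-th
nearest neighbour (ties at the k-th distance enlarge the neighbourhood), the
reachability distance to a neighbour o is max(k-distance(o), d(p, o)), the
local reachability density (lrd) is the inverse mean reachability over the
neighbourhood, and the LOF score is the mean ratio of the neighbours' lrd to
the point's own lrd. Scores near 1 indicate inliers.

To keep scores finite on exactly duplicated points, lrd uses
``1 / (mean reachability + 1e-10)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = ["LofResult", "lof_scores", "flag_outliers", "qc_features"]

_LRD_EPS = 1e-10


@dataclass
class LofResult:
    scores: pd.Series           # LOF per sample, > 0
    k: int
    flagged: list = field(default_factory=list)
    threshold_rule: str = ""


def lof_scores(X, k: int = 20) -> LofResult:
    """LOF scores for a feature matrix (ndarray or DataFrame, rows=samples).

    Euclidean metric; requires n >= k + 1.
    """
    if isinstance(X, pd.DataFrame):
        ids = X.index
        A = X.to_numpy(dtype=float)
    else:
        A = np.asarray(X, dtype=float)
        ids = pd.RangeIndex(A.shape[0])
    n = A.shape[0]
    if n <= k:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")

    D = squareform(pdist(A, metric="euclidean"))
    np.fill_diagonal(D, np.inf)
    Dsort = np.sort(D, axis=1)
    kdist = Dsort[:, k - 1]

    # neighbourhoods include every point at distance <= k-distance (ties)
    neigh = [np.flatnonzero(D[i] <= kdist[i]) for i in range(n)]
    lrd = np.empty(n)
    for i in range(n):
        reach = np.maximum(kdist[neigh[i]], D[i, neigh[i]])
        lrd[i] = 1.0 / (reach.mean() + _LRD_EPS)
    scores = np.array([lrd[neigh[i]].mean() / lrd[i] for i in range(n)])
    return LofResult(pd.Series(scores, index=ids, name="lof"), k=k)


def flag_outliers(result: LofResult, cutoff: float | None = None,
                  top_fraction: float | None = None) -> list:
    """Flag samples by fixed score cutoff (default 1.5) *or* top fraction.

    Exactly one rule may be given; with neither, the 1.5 cutoff applies.
    Ties in the top-fraction rule are broken by sample id so the flagged
    count is exact.
    """
    if cutoff is not None and top_fraction is not None:
        raise ValueError("give either cutoff or top_fraction, not both")
    s = result.scores
    if top_fraction is not None:
        if not 0.0 <= top_fraction < 1.0:
            raise ValueError("top_fraction must be in [0, 1)")
        m = int(round(top_fraction * len(s)))
        order = s.sort_values(ascending=False, kind="mergesort")
        # stable sort on score; break remaining ties lexicographically by id
        order = order.iloc[np.lexsort((order.index.astype(str),
                                       -order.to_numpy()))]
        flagged = sorted(order.index[:m].tolist())
        rule = f"top_fraction={top_fraction}"
    else:
        cut = 1.5 if cutoff is None else cutoff
        flagged = sorted(s.index[s > cut].tolist())
        rule = f"cutoff={cut}"
    result.flagged = flagged
    result.threshold_rule = rule
    return flagged


def qc_features(cohort, cfg=None):
    """Default QC feature space: water-corrected and masked, *not* normalized.

    Keeping absolute absorbance makes globally attenuated spectra (e.g. from
    faulty measurements) stand out; L2 normalization would hide them.
    """
    from .preprocess import PreprocessConfig, apply_pipeline
    from dataclasses import replace
    base = cfg or PreprocessConfig()
    # QC space is fixed regardless of the downstream preprocessing variant,
    # so flagged samples do not depend on the classification configuration
    qc_cfg = replace(base, do_water_correction=True, do_normalize=False,
                     do_second_derivative=False)
    return apply_pipeline(cohort, qc_cfg).spectra
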