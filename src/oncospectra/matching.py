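"""Covariate-balanced cohort construction by optimal matching.

Cases are matched 1:1 (or 1:k) to references by minimizing the total
Mahalanobis distance over (age, sex, BMI) subject to a propensity-score
caliper: a pair is admissible only if the two logit propensities differ by
at most ``caliper_sd_mult`` standard deviations of the pooled logits. The
assignment is solved exactly (Jonker-Volgenant via scipy) with forbidden
pairs encoded as a penalty larger than any feasible total distance, so the
solution first maximizes the number of matched cases and then minimizes the
distance; cases with no admissible reference are reported unmatched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment

__all__ = [
    "COVARIATES",
    "MatchResult",
    "fit_propensity",
    "mahalanobis_matrix",
    "optimal_pair_match",
    "optimal_multi_ref_match",
    "balance_table",
    "match_cohort",
]

COVARIATES = ("age", "sex", "bmi")


@dataclass
class MatchResult:
    pairs: list                      # (case_id, tuple of ref_ids)
    total_distance: float
    caliper: float
    unmatched: list = field(default_factory=list)

    @property
    def case_ids(self) -> list:
        return [c for c, _ in self.pairs]

    @property
    def ref_ids(self) -> list:
        return [r for _, refs in self.pairs for r in refs]

    @property
    def matched_ids(self) -> list:
        return self.case_ids + self.ref_ids


def _split(meta: pd.DataFrame, case_label: str = "case"):
    is_case = meta["group"] == case_label
    if not is_case.any() or is_case.all():
        raise ValueError("both a case and a reference group are required")
    return meta.index[is_case], meta.index[~is_case]


def fit_propensity(meta: pd.DataFrame, case_label: str = "case",
                   covariates=COVARIATES):
    """Logistic regression of group membership on the matching covariates.

    Returns ``(propensity, logit)`` as Series aligned to ``meta``; fitted by
    maximum likelihood (Newton). Perfect separation raises with a hint to
    match without calipers.
    """
    X = meta.loc[:, list(covariates)].astype(float)
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("covariates must be finite with no missing values")
    y = (meta["group"] == case_label).astype(float)
    if y.min() == y.max():
        raise ValueError("both groups must be present")
    try:
        fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        p = fit.predict(sm.add_constant(X))
    except Exception as exc:  # statsmodels PerfectSeparation / singular
        raise ValueError(
            "propensity model could not be fitted (perfect separation?); "
            "consider caliper-free matching") from exc
    p = np.clip(p, 1e-12, 1 - 1e-12)
    logit = np.log(p / (1 - p))
    return pd.Series(p, index=meta.index, name="propensity"), \
        pd.Series(logit, index=meta.index, name="logit")


def mahalanobis_matrix(meta: pd.DataFrame, case_label: str = "case",
                       covariates=COVARIATES) -> pd.DataFrame:
    """Case x reference Mahalanobis distances with the pooled within-group
    covariance of the matching covariates."""
    cases, refs = _split(meta, case_label)
    Xc = meta.loc[cases, list(covariates)].astype(float).to_numpy()
    Xr = meta.loc[refs, list(covariates)].astype(float).to_numpy()
    n1, n2 = len(cases), len(refs)
    S1 = np.cov(Xc, rowvar=False, ddof=1) if n1 > 1 else np.zeros((Xc.shape[1],) * 2)
    S2 = np.cov(Xr, rowvar=False, ddof=1) if n2 > 1 else np.zeros((Xr.shape[1],) * 2)
    S = ((max(n1 - 1, 0)) * S1 + (max(n2 - 1, 0)) * S2) / max(n1 + n2 - 2, 1)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; drop a constant covariate") from exc
    diff = Xc[:, None, :] - Xr[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diff, Sinv, diff)
    D = np.sqrt(np.maximum(d2, 0.0))
    return pd.DataFrame(D, index=cases, columns=refs)


def _caliper_width(logits: pd.Series, caliper_sd_mult: float) -> float:
    return caliper_sd_mult * float(logits.std(ddof=1))


def _solve(D: pd.DataFrame, admissible: np.ndarray):
    """Penalty-encoded rectangular assignment; returns list of (i, j)."""
    C = D.to_numpy().copy()
    big = float(C[admissible].sum()) + float(C.max(initial=0.0)) + 1.0
    C[~admissible] = big
    rows, cols = linear_sum_assignment(C)
    keep = admissible[rows, cols]
    return list(zip(rows[keep], cols[keep]))


def optimal_pair_match(D: pd.DataFrame, logits: pd.Series,
                       caliper_sd_mult: float = 0.2) -> MatchResult:
    """Optimal 1:1 matching under the caliper, minimizing total distance.

    ``D`` is the case x reference distance matrix; ``logits`` holds the
    logit propensities of *all* samples (cases and references). Ties are
    broken deterministically by lexicographic sample id.
    """
    return optimal_multi_ref_match(D, logits, caliper_sd_mult, k=1)


def optimal_multi_ref_match(D: pd.DataFrame, logits: pd.Series,
                            caliper_sd_mult: float = 0.2,
                            k: int = 1) -> MatchResult:
    """Optimal 1:k matching (each matched case gets exactly k distinct
    references) via case replication in the assignment problem."""
    if k < 1:
        raise ValueError("k must be >= 1")
    D = D.sort_index(axis=0).sort_index(axis=1)  # deterministic tie-break
    if not np.all(np.isfinite(D.to_numpy())):
        raise ValueError("distance matrix must be finite")
    cases, refs = list(D.index), list(D.columns)
    if k > len(refs):
        raise ValueError(f"1:{k} matching needs at least {k} references")
    caliper = _caliper_width(logits, caliper_sd_mult)
    lc = logits.loc[cases].to_numpy()
    lr = logits.loc[refs].to_numpy()
    admissible = np.abs(lc[:, None] - lr[None, :]) <= caliper + 1e-12
    if not admissible.any():
        raise ValueError("no admissible case-reference pair under the caliper")

    Drep = pd.DataFrame(np.repeat(D.to_numpy(), k, axis=0))
    arep = np.repeat(admissible, k, axis=0)
    assign = _solve(Drep, arep)

    got: dict = {c: [] for c in cases}
    for i, j in assign:
        got[cases[i // k]].append(refs[j])
    pairs, unmatched, total = [], [], 0.0
    for c in cases:
        if len(got[c]) == k:
            refs_c = tuple(sorted(got[c]))
            pairs.append((c, refs_c))
            total += float(D.loc[c, list(refs_c)].sum())
        else:
            unmatched.append(c)
    if not pairs:
        raise ValueError("no case could be matched under the caliper")
    return MatchResult(pairs=pairs, total_distance=total, caliper=caliper,
                       unmatched=unmatched)


def balance_table(meta: pd.DataFrame, match: MatchResult,
                  case_label: str = "case",
                  covariates=COVARIATES) -> pd.DataFrame:
    """Standardized mean differences before and after matching.

    SMD = (mean_case - mean_ref) / pooled SD, the pooled SD being
    sqrt((s_case^2 + s_ref^2)/2) of the sample set on which the SMD is
    computed. Zero pooled SD with equal means yields SMD 0.
    """
    if not match.pairs:
        raise ValueError("empty match result")

    def smd(sub: pd.DataFrame) -> pd.Series:
        g = sub["group"] == case_label
        out = {}
        for c in covariates:
            x1 = sub.loc[g, c].astype(float)
            x0 = sub.loc[~g, c].astype(float)
            s = np.sqrt((x1.var(ddof=1) + x0.var(ddof=1)) / 2.0)
            num = x1.mean() - x0.mean()
            if s == 0 or not np.isfinite(s):
                if abs(num) < 1e-12:
                    out[c] = 0.0
                else:
                    raise ValueError(f"zero pooled SD for covariate {c!r} "
                                     "with unequal means")
            else:
                out[c] = num / s
        return pd.Series(out)

    before = smd(meta)
    after = smd(meta.loc[match.matched_ids])
    return pd.DataFrame({"smd_before": before, "smd_after": after})


def match_cohort(meta: pd.DataFrame, case_label: str = "case",
                 caliper_sd_mult: float = 0.2, k: int = 1,
                 covariates=COVARIATES):
    """Convenience wrapper: propensity fit, distances, optimal match,
    balance. Returns ``(MatchResult, balance DataFrame)``."""
    _, logits = fit_propensity(meta, case_label, covariates)
    D = mahalanobis_matrix(meta, case_label, covariates)
    match = optimal_multi_ref_match(D, logits, caliper_sd_mult, k=k)
    return match, balance_table(meta, match, case_label, covariates)
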