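"""Matching: propensity model, Mahalanobis distances, optimal assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oncospectra import (SimConfig, balance_table, fit_propensity,
                         generate_cohort, mahalanobis_matrix, match_cohort,
                         optimal_multi_ref_match, optimal_pair_match)


def _meta(age, sex, bmi, group, ids=None):
    ids = ids or [f"S{i:03d}" for i in range(len(age))]
    return pd.DataFrame({"age": age, "sex": sex, "bmi": bmi, "group": group},
                        index=pd.Index(ids, name="sample_id"))


def _newton_logistic(X, y, iters=200):
    """Independently coded Newton-Raphson logistic MLE (oracle)."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X1.shape[1])
    for _ in range(iters):
        p = 1 / (1 + np.exp(-X1 @ beta))
        W = p * (1 - p)
        H = X1.T @ (W[:, None] * X1)
        step = np.linalg.solve(H, X1.T @ (y - p))
        beta += step
        if np.abs(step).max() < 1e-12:
            break
    return 1 / (1 + np.exp(-X1 @ beta))


class TestPropensity:
    def test_identical_distributions_give_case_fraction(self, rng):
        n = 60
        age = np.tile(rng.normal(55, 5, n // 2), 2)
        sex = np.tile(rng.integers(0, 2, n // 2), 2)
        bmi = np.tile(rng.normal(25, 2, n // 2), 2)
        meta = _meta(age, sex, bmi, ["case"] * (n // 2) + ["reference"] * (n // 2))
        p, _ = fit_propensity(meta)
        np.testing.assert_allclose(p.to_numpy(), 0.5, atol=1e-6)

    def test_matches_newton_oracle_and_is_monotone_in_age(self):
        # age-shifted but overlapping groups; sex/bmi form balanced cells
        meta = _meta(age=[68, 62, 56, 50, 64, 58, 52, 46],
                     sex=[1, 0, 1, 0] * 2,
                     bmi=[25, 27, 26, 24, 26, 25, 24, 27],
                     group=["case"] * 4 + ["reference"] * 4)
        p, logit = fit_propensity(meta)
        X = meta[["age", "sex", "bmi"]].to_numpy(float)
        y = (meta["group"] == "case").to_numpy(float)
        oracle = _newton_logistic(X, y)
        np.testing.assert_allclose(p.to_numpy(), oracle, atol=1e-6)
        # within each (sex, bmi) cell the propensity rises with age
        for _, cell in meta.assign(p=p).groupby(["sex", "bmi"]):
            cell = cell.sort_values("age")
            assert (np.diff(cell["p"].to_numpy()) > -1e-9).all()

    def test_refit_is_deterministic(self, rng):
        cfg = SimConfig(n_cases=40, n_refs=40, seed=10)
        cohort, _ = generate_cohort(cfg)
        p1, _ = fit_propensity(cohort.meta)
        p2, _ = fit_propensity(cohort.meta)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-8)


class TestMahalanobis:
    def test_identical_covariates_give_zero_distance(self):
        meta = _meta(age=[50, 62, 50, 60, 40, 55, 70],
                     sex=[1, 0, 1, 0, 1, 1, 0],
                     bmi=[25, 27, 25, 28, 22, 30, 26],
                     group=["case"] * 2 + ["reference"] * 5)
        D = mahalanobis_matrix(meta)
        assert D.loc["S000", "S002"] == pytest.approx(0.0, abs=1e-9)
        assert (D.to_numpy() >= 0).all()

    def test_matches_solve_based_oracle(self, rng):
        age = rng.normal(55, 8, 10)
        sex = rng.integers(0, 2, 10)
        bmi = rng.normal(25, 3, 10)
        meta = _meta(age, sex, bmi, ["case"] * 4 + ["reference"] * 6)
        D = mahalanobis_matrix(meta)
        X = meta[["age", "sex", "bmi"]].to_numpy(float)
        S = (3 * np.cov(X[:4], rowvar=False) + 5 * np.cov(X[4:], rowvar=False)) / 8
        for i in range(4):
            for j in range(6):
                diff = X[i] - X[4 + j]
                exp = np.sqrt(diff @ np.linalg.solve(S, diff))
                assert D.iloc[i, j] == pytest.approx(exp, abs=1e-10)

    def test_singular_covariance_guides_user(self):
        meta = _meta(age=[50, 52, 54, 56], sex=[1, 1, 1, 1],
                     bmi=[25, 26, 24, 27], group=["case"] * 2 + ["reference"] * 2)
        with pytest.raises(ValueError, match="constant covariate"):
            mahalanobis_matrix(meta)


def _exhaustive_best(D: pd.DataFrame, logits: pd.Series, caliper: float):
    """Best total distance over all full injections of cases into references
    using only admissible pairs (oracle for instances where all cases can be
    matched)."""
    cases, refs = list(D.index), list(D.columns)
    best = np.inf
    for combo in itertools.permutations(refs, len(cases)):
        ok = all(abs(logits[c] - logits[r]) <= caliper + 1e-12
                 for c, r in zip(cases, combo))
        if ok:
            best = min(best, sum(D.loc[c, r] for c, r in zip(cases, combo)))
    return best


class TestOptimalMatch:
    def test_exact_twins_give_zero_distance(self):
        meta = _meta(age=[50, 60, 70, 50, 60, 70, 45, 80],
                     sex=[1, 0, 1, 1, 0, 1, 0, 1],
                     bmi=[22, 25, 28, 22, 25, 28, 30, 20],
                     group=["case"] * 3 + ["reference"] * 5)
        match, _ = match_cohort(meta, caliper_sd_mult=10.0)
        assert match.total_distance == pytest.approx(0.0, abs=1e-9)
        assert len(match.pairs) == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n_case, n_ref = rng.integers(3, 6), rng.integers(5, 8)
        D = pd.DataFrame(rng.uniform(0, 10, size=(n_case, n_ref)),
                         index=[f"C{i}" for i in range(n_case)],
                         columns=[f"R{j}" for j in range(n_ref)])
        logits = pd.Series(rng.normal(0, 1, n_case + n_ref),
                           index=list(D.index) + list(D.columns))
        caliper_mult = 2.0  # generous so full matchings exist
        caliper = caliper_mult * logits.std(ddof=1)
        oracle = _exhaustive_best(D, logits, caliper)
        if not np.isfinite(oracle):
            pytest.skip("instance admits no full matching")
        match = optimal_pair_match(D, logits, caliper_mult)
        assert match.unmatched == []
        assert match.total_distance == pytest.approx(oracle, abs=1e-9)

    def test_beats_or_ties_greedy_nearest_neighbor(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            D = pd.DataFrame(rng.uniform(0, 5, size=(5, 7)),
                             index=[f"C{i}" for i in range(5)],
                             columns=[f"R{j}" for j in range(7)])
            logits = pd.Series(0.0, index=list(D.index) + list(D.columns))
            match = optimal_pair_match(D, logits, 1.0)
            # greedy: cases in order take their nearest unused reference
            used, greedy_total = set(), 0.0
            for c in D.index:
                choices = D.loc[c].drop(list(used))
                used.add(choices.idxmin())
                greedy_total += choices.min()
            assert match.total_distance <= greedy_total + 1e-9

    def test_caliper_feasibility_and_reference_uniqueness(self, rng):
        cfg = SimConfig(n_cases=30, n_refs=60, seed=12)
        cohort, _ = generate_cohort(cfg)
        _, logits = fit_propensity(cohort.meta)
        D = mahalanobis_matrix(cohort.meta)
        match = optimal_pair_match(D, logits, 0.2)
        refs = match.ref_ids
        assert len(refs) == len(set(refs))
        for c, (r,) in match.pairs:
            assert abs(logits[c] - logits[r]) <= match.caliper + 1e-9

    def test_unmatchable_case_is_reported(self):
        D = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]],
                         index=["C0", "C1"], columns=["R0", "R1"])
        logits = pd.Series({"C0": 0.0, "C1": 50.0, "R0": 0.1, "R1": -0.1})
        match = optimal_pair_match(D, logits, 0.02)
        assert match.unmatched == ["C1"]
        assert [c for c, _ in match.pairs] == ["C0"]


class TestMultiRefMatch:
    def test_k1_reduces_to_pair_matching(self, rng):
        D = pd.DataFrame(rng.uniform(0, 10, size=(4, 7)),
                         index=[f"C{i}" for i in range(4)],
                         columns=[f"R{j}" for j in range(7)])
        logits = pd.Series(rng.normal(size=11),
                           index=list(D.index) + list(D.columns))
        a = optimal_pair_match(D, logits, 2.0)
        b = optimal_multi_ref_match(D, logits, 2.0, k=1)
        assert a.pairs == b.pairs
        assert a.total_distance == pytest.approx(b.total_distance)

    def test_two_cases_five_refs_k2_matches_enumeration(self, rng):
        D = pd.DataFrame(rng.uniform(0, 10, size=(2, 5)),
                         index=["C0", "C1"], columns=[f"R{j}" for j in range(5)])
        logits = pd.Series(0.0, index=list(D.index) + list(D.columns))
        match = optimal_multi_ref_match(D, logits, 1.0, k=2)
        best = np.inf
        refs = list(D.columns)
        for quad in itertools.permutations(refs, 4):
            total = (D.loc["C0", quad[0]] + D.loc["C0", quad[1]]
                     + D.loc["C1", quad[2]] + D.loc["C1", quad[3]])
            best = min(best, total)
        assert match.total_distance == pytest.approx(best, abs=1e-9)

    def test_degenerate_equal_distances(self):
        D = pd.DataFrame(np.full((2, 6), 3.0), index=["C0", "C1"],
                         columns=[f"R{j}" for j in range(6)])
        logits = pd.Series(0.0, index=list(D.index) + list(D.columns))
        match = optimal_multi_ref_match(D, logits, 1.0, k=2)
        assert match.total_distance == pytest.approx(2 * 2 * 3.0)


class TestBalance:
    def test_twinned_match_zeroes_smd(self):
        meta = _meta(age=[50, 60, 50, 60, 80, 90],
                     sex=[1, 0, 1, 0, 1, 1],
                     bmi=[22, 25, 22, 25, 30, 31],
                     group=["case"] * 2 + ["reference"] * 4)
        match, balance = match_cohort(meta, caliper_sd_mult=10.0)
        np.testing.assert_allclose(balance["smd_after"].to_numpy(), 0.0,
                                   atol=1e-9)

    def test_group_swap_flips_smd_sign(self):
        meta = _meta(age=[60, 62, 50, 52], sex=[1, 0, 0, 1],
                     bmi=[27, 28, 24, 23],
                     group=["case"] * 2 + ["reference"] * 2)
        swapped = meta.copy()
        swapped["group"] = np.where(meta["group"] == "case",
                                    "reference", "case")
        from oncospectra.matching import balance_table, MatchResult
        m = MatchResult(pairs=[("S000", ("S002",)), ("S001", ("S003",))],
                        total_distance=0.0, caliper=1.0)
        m2 = MatchResult(pairs=[("S002", ("S000",)), ("S003", ("S001",))],
                         total_distance=0.0, caliper=1.0)
        b1 = balance_table(meta, m)
        b2 = balance_table(swapped, m2)
        np.testing.assert_allclose(b1["smd_before"].to_numpy(),
                                   -b2["smd_before"].to_numpy(), atol=1e-12)

    def test_matching_reduces_age_imbalance_on_confounded_cohort(self):
        cfg = SimConfig(n_cases=80, n_refs=160, seed=23, age_shift=5.0)
        cohort, _ = generate_cohort(cfg)
        _, balance = match_cohort(cohort.meta.assign(
            group=np.where(cohort.meta["group"] == "case", "case", "reference")))
        assert abs(balance.loc["age", "smd_after"]) < \
            abs(balance.loc["age", "smd_before"])
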