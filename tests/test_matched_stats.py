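"""Matched-pair inference: conditional logistic likelihood, AUC, Holm,
selection, optimism bootstrap and the nonparametric small-sample tests,
each checked against an independent brute-force oracle where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from immunomethyl import matched_stats as ms


# ---------------------------------------------------------------- oracles


def grid_clogit_1d(d, lo=-10, hi=10, step=1e-4):
    """Brute-force maximiser of sum log sigma(d_i * b) on a fine grid."""
    grid = np.arange(lo, hi + step / 2, step)
    ll = np.log(expit(np.outer(grid, d))).sum(axis=1)
    return grid[np.argmax(ll)], ll.max()


def holm_bruteforce(p):
    """Literal step-down formula: sort, cumulative max of (m-j+1)*p_(j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(np.ones(m))  # placeholder
    vals = [(m - j) * p[order[j]] for j in range(m)]
    running, out_sorted = 0.0, []
    for v in vals:
        running = max(running, v)
        out_sorted.append(min(1.0, running))
    out = np.empty(m)
    out[order] = out_sorted
    return out


def auc_pair_counting(cases, controls):
    conc = ties = 0
    for x in cases:
        for y in controls:
            conc += x > y
            ties += x == y
    return (conc + 0.5 * ties) / (len(cases) * len(controls))


def _cohort_from_exposure(x_case, x_control):
    """Minimal matched cohort with one exposure column."""
    n = len(x_case)
    rows, scores = [], {}
    for i in range(n):
        rows.append({"sample_id": f"p{i}c", "pair_id": f"p{i}", "is_case": True})
        rows.append({"sample_id": f"p{i}k", "pair_id": f"p{i}", "is_case": False})
        scores[f"p{i}c"] = x_case[i]
        scores[f"p{i}k"] = x_control[i]
    sheet = pd.DataFrame(rows).set_index("sample_id")
    cohort = ms.MatchedCohort(sheet, validate=False)
    sc = pd.DataFrame({"x": pd.Series(scores)})
    return cohort, sc


def simulate_matched(n_pairs, log_or, rng, n_exposures=1):
    """Pairs with conditional case assignment: P(case=subj1) = sigma(b'(x1-x2))."""
    x1 = rng.normal(size=(n_pairs, n_exposures))
    x2 = rng.normal(size=(n_pairs, n_exposures))
    beta = np.full(n_exposures, log_or)
    p_first = expit((x1 - x2) @ beta)
    first_is_case = rng.random(n_pairs) < p_first
    xc = np.where(first_is_case[:, None], x1, x2)
    xk = np.where(first_is_case[:, None], x2, x1)
    rows, data = [], {}
    for i in range(n_pairs):
        rows.append({"sample_id": f"p{i}c", "pair_id": f"p{i}", "is_case": True})
        rows.append({"sample_id": f"p{i}k", "pair_id": f"p{i}", "is_case": False})
        data[f"p{i}c"] = xc[i]
        data[f"p{i}k"] = xk[i]
    sheet = pd.DataFrame(rows).set_index("sample_id")
    cohort = ms.MatchedCohort(sheet, validate=False)
    scores = pd.DataFrame.from_dict(
        data, orient="index", columns=[f"x{j}" for j in range(n_exposures)]
    )
    return cohort, scores


# ---------------------------------------------------------------- clogit


class TestFitClogit:
    def test_symmetric_differences_give_zero(self):
        d = pd.DataFrame({"x": [+1.0, -1.0]})
        fit = ms.fit_clogit(d)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.or_table(0.1)["OR"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_oracle_on_three_pairs(self):
        d = np.array([+1.0, +1.0, -1.0])
        fit = ms.fit_clogit(pd.DataFrame({"x": d}))
        b_grid, ll_grid = grid_clogit_1d(d)
        assert fit.beta[0] == pytest.approx(np.log(2), abs=1e-6)
        assert fit.beta[0] == pytest.approx(b_grid, abs=1e-3)
        assert fit.loglik >= ll_grid - 1e-9

    def test_separation_flagged(self):
        d = pd.DataFrame({"x": [+1.0, +1.0, +1.0]})
        fit = ms.fit_clogit(d)
        assert fit.separation and not fit.converged

    def test_no_within_pair_variation_rejected(self):
        with pytest.raises(ValueError, match="variation"):
            ms.fit_clogit(pd.DataFrame({"x": [0.0, 0.0, 0.0]}))

    @pytest.mark.parametrize("seed", range(4))
    def test_random_small_instances_match_grid(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            d = rng.choice([-2, -1, 1, 2], size=5).astype(float)
            if len(set(np.sign(d))) > 1:  # avoid separation
                break
        fit = ms.fit_clogit(pd.DataFrame({"x": d}))
        b_grid, ll_grid = grid_clogit_1d(d)
        assert abs(fit.beta[0] - b_grid) < 1e-3
        assert fit.loglik >= ll_grid - 1e-9

    def test_multivariable_gradient_zero_at_optimum(self, rng):
        d = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        fit = ms.fit_clogit(d)
        mu = expit(d.to_numpy() @ fit.beta)
        grad = d.to_numpy().T @ (1 - mu)
        assert np.max(np.abs(grad)) < 1e-6


# ---------------------------------------------------------------- AUC


class TestAuc:
    def test_perfect_separation(self):
        a, _ = ms.auc([0.9, 0.8], [0.1, 0.2])
        assert a == 1.0

    def test_all_ties(self):
        a, (lo, hi) = ms.auc([0.5, 0.5], [0.5, 0.5])
        assert a == 0.5 and lo == pytest.approx(a) and hi == pytest.approx(a)

    def test_pair_counting_example(self):
        # concordant pairs: (0.7,0.5), (0.7,0.2), (0.4,0.2); discordant: (0.4,0.5)
        a, _ = ms.auc([0.7, 0.4], [0.5, 0.2])
        assert a == pytest.approx(3 / 4)
        a_ties, _ = ms.auc([0.7, 0.4], [0.4, 0.2])  # one tie counts one half
        assert a_ties == pytest.approx(3.5 / 4)

    @given(
        cases=st.lists(st.integers(0, 5), min_size=1, max_size=8),
        controls=st.lists(st.integers(0, 5), min_size=1, max_size=8),
    )
    def test_matches_exhaustive_counting_and_mann_whitney(self, cases, controls):
        a, _ = ms.auc(cases, controls)
        assert a == pytest.approx(auc_pair_counting(cases, controls))
        u, _ = ms.mann_whitney(cases, controls)
        assert a == pytest.approx(u / (len(cases) * len(controls)))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ms.auc([], [0.1])

    def test_delong_ci_covers_large_sample(self, rng):
        cases = rng.normal(1.0, 1, 400)
        controls = rng.normal(0.0, 1, 400)
        a, (lo, hi) = ms.auc(cases, controls)
        # true AUC for N(1,1) vs N(0,1) is Phi(1/sqrt(2)) ~= 0.7602
        assert lo < 0.7602 < hi


# ---------------------------------------------------------------- Holm


class TestHolm:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.04, 0.03], [0.03, 0.06, 0.06]),
            ([0.02, 0.02, 0.02, 0.02], [0.08, 0.08, 0.08, 0.08]),
        ],
    )
    def test_hand_worked_examples(self, p, expected):
        assert np.allclose(ms.holm_adjust(p), expected)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_bruteforce_and_dominates_raw(self, p):
        adj = ms.holm_adjust(p)
        assert np.allclose(adj, holm_bruteforce(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ms.holm_adjust([0.5, 1.5])


# ---------------------------------------------------------------- selection & bootstrap


class TestBackwardSelect:
    def test_single_strong_exposure_retained(self, rng):
        cohort, scores = simulate_matched(80, log_or=1.5, rng=rng)
        mf = ms.backward_select(cohort, scores)
        assert mf.selected == ["x0"]

    def test_strong_exposure_survives_noise_companion(self):
        keep = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            cohort, scores = simulate_matched(60, log_or=1.5, rng=rng)
            scores["noise"] = rng.normal(size=len(scores))
            mf = ms.backward_select(cohort, scores)
            keep += "x0" in mf.selected
        assert keep >= 28

    def test_null_exposures_usually_dropped(self):
        empty = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            cohort, scores = simulate_matched(20, log_or=0.0, rng=rng, n_exposures=2)
            mf = ms.backward_select(cohort, scores)
            empty += len(mf.selected) == 0
        # each null exposure stays with prob ~alpha_stay=0.2
        assert empty / 40 > 0.5

    def test_deterministic_given_data(self, rng):
        cohort, scores = simulate_matched(50, log_or=0.5, rng=rng, n_exposures=3)
        a = ms.backward_select(cohort, scores)
        b = ms.backward_select(cohort, scores)
        assert a.selected == b.selected and a.trace == b.trace


class TestBootstrapAuc:
    def test_identity_replicate_has_zero_optimism(self, rng):
        cohort, scores = simulate_matched(40, log_or=1.0, rng=rng)
        mf = ms.bootstrap_adjusted_auc(
            cohort, scores, B=1, seed=0,
            resampler=lambda _rng, ids: np.asarray(ids),
        )
        assert mf.optimism == pytest.approx(0.0, abs=1e-12)
        assert mf.adjusted_auc == pytest.approx(mf.apparent_auc)

    def test_planted_effect_adjusted_auc_in_range(self):
        # exposure built to give AUC ~ 0.75
        rng = np.random.default_rng(5)
        cohort, scores = simulate_matched(100, log_or=1.35, rng=rng)
        mf = ms.bootstrap_adjusted_auc(cohort, scores, B=50, seed=1)
        assert 0.6 < mf.adjusted_auc < 0.8

    def test_requires_positive_B(self, rng):
        cohort, scores = simulate_matched(10, log_or=0.0, rng=rng)
        with pytest.raises(ValueError):
            ms.bootstrap_adjusted_auc(cohort, scores, B=0)


# ---------------------------------------------------------------- nonparametrics


class TestWilcoxon:
    def test_all_positive_three_diffs_exact(self):
        _, p = ms.wilcoxon_signed_rank([1.0, 2.0, 3.0], alternative="greater")
        assert p == pytest.approx(1 / 8)

    def test_antisymmetric_two_sided(self):
        _, p = ms.wilcoxon_signed_rank([+1.0, -1.0])
        assert p == pytest.approx(1.0)

    def test_degenerate_all_zero(self):
        with pytest.raises(ValueError, match="degenerate"):
            ms.wilcoxon_signed_rank([0.0, 0.0])

    def test_large_n_close_to_monte_carlo(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.3, 1.0, size=30)
        d = np.round(d, 3)
        _, p = ms.wilcoxon_signed_rank(d)
        # Monte-Carlo null: random sign flips of |d|
        absd = np.abs(d[d != 0])
        ranks = pd.Series(absd).rank().to_numpy()
        obs = ranks[np.sign(d[d != 0]) > 0].sum()
        n_mc = 100_000
        signs = rng.random((n_mc, len(ranks))) < 0.5
        w_null = (signs * ranks).sum(axis=1)
        mean_w = ranks.sum() / 2
        p_mc = np.mean(np.abs(w_null - mean_w) >= abs(obs - mean_w) - 1e-9)
        assert abs(p - p_mc) < 0.01


class TestMannWhitney:
    def test_identical_groups(self):
        _, p = ms.mann_whitney([1.0, 2.0], [1.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_disjoint_supports_exact(self):
        _, p = ms.mann_whitney([3.0, 4.0], [1.0, 2.0])
        assert p == pytest.approx(2 / 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ms.mann_whitney([], [1.0])


class TestJonckheereTerpstra:
    def test_maximal_trend_exact(self):
        jt, p, method = ms.jonckheere_terpstra(
            [[1, 2], [3, 4]], alternative="increasing"
        )
        assert jt == 4.0 and method == "exact"
        assert p == pytest.approx(1 / 6)

    def test_exact_matches_full_enumeration(self):
        """Exact p equals a literal enumeration over value partitions."""
        groups = [[1.0, 5.0], [2.0, 4.0], [3.0, 6.0]]
        jt, p, _ = ms.jonckheere_terpstra(groups, alternative="increasing")
        pooled = [x for g in groups for x in g]
        count = total = 0
        for perm in itertools.permutations(pooled):
            g = [np.array(perm[:2]), np.array(perm[2:4]), np.array(perm[4:])]
            stat = sum(
                np.sum(h[None, :] > lo[:, None]) + 0.5 * np.sum(h[None, :] == lo[:, None])
                for lo, h in itertools.combinations(g, 2)
            )
            total += 1
            count += stat >= jt - 1e-12
        assert p == pytest.approx(count / total)

    def test_null_expectation(self, rng):
        groups = [rng.normal(size=12), rng.normal(size=12), rng.normal(size=12)]
        jt, _, _ = ms.jonckheere_terpstra(groups, method="normal")
        expect = (12 * 12 * 3) / 2  # sum over the three ordered group pairs
        assert abs(jt - expect) < 120

    def test_normal_close_to_permutation(self, rng):
        groups = [rng.normal(0, 1, 15), rng.normal(0.3, 1, 15), rng.normal(0.6, 1, 15)]
        _, p_perm, _ = ms.jonckheere_terpstra(groups, n_perm=20_000, seed=3)
        _, p_norm, _ = ms.jonckheere_terpstra(groups, method="normal")
        assert abs(p_perm - p_norm) < 0.02

    def test_power_with_planted_trend(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            groups = [
                rng.normal(0.0, 1, 15), rng.normal(0.7, 1, 15), rng.normal(1.4, 1, 15)
            ]
            _, p, _ = ms.jonckheere_terpstra(groups, method="normal")
            hits += p < 0.05
        assert hits >= 36

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ms.jonckheere_terpstra([[1, 2, 3]])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert ms.spearman_rho(x, x)[0] == pytest.approx(1.0)
        assert ms.spearman_rho(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_rank_formula(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        expected = np.corrcoef(rx, ry)[0, 1]
        assert ms.spearman_rho(x, y)[0] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- cohort container


class TestMatchedCohort:
    def test_pair_validation(self):
        sheet = pd.DataFrame(
            {
                "pair_id": ["p0", "p0"],
                "is_case": [True, True],
                "age": [50.0, 50.0],
            },
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="p0"):
            ms.MatchedCohort(sheet)

    def test_age_gap_enforced(self):
        sheet = pd.DataFrame(
            {
                "pair_id": ["p0", "p0"],
                "is_case": [True, False],
                "age": [50.0, 53.0],
            },
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="age gap"):
            ms.MatchedCohort(sheet, age_tolerance=1.0)
        ms.MatchedCohort(sheet, age_tolerance=5.0)  # fine at +/-5y

    def test_differences_complete_pairs_only(self):
        cohort, scores = _cohort_from_exposure([1.0, 2.0], [0.5, np.nan])
        d = cohort.differences(scores)
        assert list(d.index) == ["p0"] and d.iloc[0, 0] == pytest.approx(0.5)


def test_univariable_association_table(small_cohort, rich_reference, rich_panel):
    """End-to-end table: OR/CI/p/p_adj/AUC invariants on a real score block."""
    from immunomethyl import proxy_scores as ps

    betas, sheet, _ = small_cohort
    cohort = ms.MatchedCohort(sheet, age_tolerance=1.0)
    scores = ps.compute_mdnlr(
        betas, rich_panel.neu_probes[:3], rich_panel.panlym_probes[:3]
    ).reindex(sheet.index)
    out = ms.univariable_associations(cohort, scores)
    assert out.shape[0] == 9
    assert ((out["CI_low"] <= out["OR"]) & (out["OR"] <= out["CI_high"])).all()
    assert (out["p_adj"] >= out["p"] - 1e-12).all()
    assert out["AUC"].between(0, 1).all()
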