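"""Statistical tests checked against hand enumeration oracles.

The oracles below enumerate null distributions directly (sign patterns,
group-label assignments, hypergeometric tables with exact integer
arithmetic) and share no code with the implementation path.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from flydyad import (
    ResponderRules,
    StatResult,
    WindowSummary,
    bonferroni,
    classify_responders,
    fisher_exact,
    kruskal_wallis,
    mann_whitney_u,
    wilcoxon_signed_rank,
    window_comparison_suite,
)


# ---------------------------------------------------------------------------
# oracles

def signed_rank_p_enumeration(a, b):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, keep in zip(ranks, signs) if keep)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs)
    hi = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(lo, hi))


def mann_whitney_p_permutation(a, b):
    """Two-sided exact p over all C(n1+n2, n1) group assignments."""
    a, b = list(a), list(b)
    pooled = np.array(a + b, float)
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum()
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


def fisher_p_hypergeometric(a, b, c, d):
    """Two-sided exact p by integer hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def count(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x)

    obs = count(a)
    total = math.comb(n, c1)
    acc = sum(
        count(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if count(x) <= obs
    )
    return float(Fraction(acc, total))


# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_hand_computed_h_statistic(self):
        r = kruskal_wallis([1, 2], [3, 4], [5, 6])
        assert r.statistic == pytest.approx(4.571428571, abs=1e-6)

    def test_identical_groups_give_unit_p(self):
        r = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(0.0, abs=1e-12) and r.p_raw == pytest.approx(1.0)

    def test_all_values_identical_is_degenerate(self):
        r = kruskal_wallis([2, 2], [2, 2, 2])
        assert r.degenerate and r.p_raw == 1.0

    def test_needs_two_groups_with_values(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3])
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2], [])


class TestWilcoxonSignedRank:
    def test_all_positive_n6_exact(self):
        r = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 0])
        assert r.p_raw == pytest.approx(2 / 64)

    def test_identical_pairs_degenerate(self):
        r = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert r.p_raw == 1.0 and r.degenerate

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_exact_path_matches_sign_enumeration(self, n, rng):
        for _ in range(5):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            got = wilcoxon_signed_rank(a, b).p_raw
            assert got == pytest.approx(signed_rank_p_enumeration(a, b), abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(0.5, 1.0, size=40)
        r = wilcoxon_signed_rank(a, b)
        assert 0 <= r.p_raw <= 1


class TestMannWhitney:
    def test_complete_separation_n3(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_raw == pytest.approx(0.1)

    def test_identical_multisets_unit_p_on_approximation_path(self):
        r = mann_whitney_u([1, 2, 3], [1, 2, 3])  # ties force the approx path
        assert r.p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5), (8, 6)])
    def test_exact_path_matches_permutation_oracle(self, n1, n2, rng):
        for _ in range(5):
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            got = mann_whitney_u(a, b).p_raw
            assert got == pytest.approx(mann_whitney_p_permutation(a, b), abs=1e-12)


class TestFisherExact:
    def test_perfect_association(self):
        r = fisher_exact([[10, 0], [0, 10]])
        assert r.p_raw == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_no_association(self):
        assert fisher_exact([[1, 1], [1, 1]]).p_raw == 1.0

    def test_zero_margin_is_degenerate(self):
        r = fisher_exact([[0, 0], [3, 5]])
        assert r.degenerate and r.p_raw == 1.0

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(0, 10, size=(2, 2))
            assert fisher_exact(t).p_raw == pytest.approx(fisher_exact(t.T).p_raw, rel=1e-9)

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            got = fisher_exact([[a, b], [c, d]]).p_raw
            assert got == pytest.approx(fisher_p_hypergeometric(a, b, c, d), rel=1e-9)


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.5, 3) == 1.0
        assert bonferroni(0.2, 1) == 0.2

    def test_marginal_flag_follows_parenthesis_rule(self):
        r = StatResult("t", 0.0, 0.03, m=3)
        assert r.p_corrected == pytest.approx(0.09)
        assert r.marginal and not r.significant
        r2 = StatResult("t", 0.0, 0.01, m=3)
        assert r2.significant and not r2.marginal


# ---------------------------------------------------------------------------
# suite and responders

def make_summary(pair_id, genotype, behavior, w_rates):
    rows = [
        (pair_id, genotype, "tester", behavior, w, r) for w, r in w_rates.items()
    ]
    return WindowSummary(
        rates=pd.DataFrame(
            rows, columns=["pair_id", "genotype", "fly", "behavior", "window", "rate"]
        ),
        window_mode="isi_split",
        pair_id=pair_id,
        genotype=genotype,
    )


class TestComparisonSuite:
    def _cohort(self, rng, effect=1.0, n=12, genotype="exp"):
        out = []
        for i in range(n):
            base = rng.gamma(4.0, 1.0)
            out.append(
                make_summary(
                    f"{genotype}{i}",
                    genotype,
                    "wing_extension",
                    {1: base, 2: base * effect + rng.normal(0, 0.1), 3: base + rng.normal(0, 0.1)},
                )
            )
        return out

    def test_nonsignificant_omnibus_gates_posthoc(self, rng):
        report = window_comparison_suite(self._cohort(rng, effect=1.0), "wing_extension")
        if report.omnibus.p_raw >= 0.05:
            assert report.posthoc == []

    def test_strong_effect_yields_gated_posthoc_with_family_size(self, rng):
        report = window_comparison_suite(self._cohort(rng, effect=6.0), "wing_extension")
        assert report.omnibus.p_raw < 0.05
        assert len(report.posthoc) == 3  # all window pairs among (1,2,3)
        assert all(r.m == 3 for r in report.posthoc)
        w2v1 = [r for r in report.posthoc if r.groups == "window 2 vs window 1"]
        assert w2v1 and w2v1[0].significant

    def test_three_genotypes_give_two_posthoc_comparisons(self, rng):
        cohort = (
            self._cohort(rng, effect=6.0, genotype="exp")
            + self._cohort(rng, effect=1.0, genotype="ctrl_gal4")
            + self._cohort(rng, effect=1.0, genotype="ctrl_uas")
        )
        report = window_comparison_suite(
            cohort, "wing_extension", design="between_genotypes",
            test_genotype="exp", window=2,
        )
        if report.omnibus.p_raw < 0.05:
            assert len(report.posthoc) == 2 and all(r.m == 2 for r in report.posthoc)

    def test_single_genotype_cannot_request_genotype_comparison(self, rng):
        with pytest.raises(ValueError, match="genotype"):
            window_comparison_suite(
                self._cohort(rng), "wing_extension", design="between_genotypes"
            )

    def test_report_frame_has_audit_columns(self, rng):
        df = window_comparison_suite(self._cohort(rng, effect=6.0), "wing_extension").to_frame()
        assert {"test", "p_raw", "m", "p_corrected", "significant", "marginal"} <= set(df.columns)


RESPONDER_CASES = [
    # behavior, w1, w2, w3, expected
    ("lunge", 0.0, 1.5, 0.0, True),    # floor: >1 lunge/min, no reference lunges
    ("lunge", 0.0, 1.0, 0.0, False),   # exactly 1/min is not "more than one"
    ("lunge", 0.0, 0.8, 0.0, False),   # below the floor
    ("lunge", 2.0, 2.9, 2.0, False),   # 45% < 50% against both references
    ("lunge", 2.0, 3.1, 2.0, True),    # 55% increase
    ("lunge", 2.0, 3.1, 0.5, True),    # >50% against window 3 alone suffices
    ("lunge", 0.0, 0.5, 2.0, False),   # nonzero w3 blocks the floor branch
    ("lunge", 4.0, 0.0, 4.0, False),   # decrease
    ("wing_extension", 0.0, 0.4, 0.0, False),  # below 500 ms/min floor
    ("wing_extension", 0.0, 0.6, 0.0, True),   # above the floor
    ("wing_extension", 1.0, 1.6, 1.8, True),   # >50% vs window 1
    ("wing_extension", 1.0, 1.4, 1.5, False),  # <50% vs both
]


class TestResponders:
    def test_twelve_case_truth_table(self):
        for beh in ("lunge", "wing_extension"):
            cases = [c for c in RESPONDER_CASES if c[0] == beh]
            summaries = [
                make_summary(f"p{i}", "exp", beh, {1: w1, 2: w2, 3: w3})
                for i, (_, w1, w2, w3, _) in enumerate(cases)
            ]
            got = classify_responders(summaries, beh)
            expected = [e for (_, _, _, _, e) in cases]
            assert got.responder.tolist() == expected

    def test_monotone_in_window2_rate(self):
        for w1, w3 in [(0.0, 0.0), (1.0, 2.0), (0.0, 1.0)]:
            prev = None
            for w2 in np.linspace(0, 10, 41):
                s = make_summary("p", "g", "lunge", {1: w1, 2: float(w2), 3: w3})
                now = classify_responders([s], "lunge").responder.iloc[0]
                if prev is not None:
                    assert not (prev and not now)  # responder never flips back off
                prev = now

    def test_missing_window_is_error(self):
        s = make_summary("p", "g", "lunge", {1: 0.0, 2: 1.0})
        with pytest.raises(KeyError):
            classify_responders([s], "lunge")

    def test_floor_rule_for_unknown_behavior_is_error(self):
        with pytest.raises(ValueError):
            ResponderRules().floor("headbutt")
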