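"""Statistical scheme for window- and genotype-wise behavior comparisons.

The behavioral rates are zero-inflated and non-normal, so the scheme is
nonparametric throughout: a Kruskal-Wallis omnibus gate across illumination
windows (or genotypes), followed — only when the omnibus p < 0.05 — by
post-hoc tests: the Wilcoxon signed-rank test for paired within-fly window
comparisons and the Mann-Whitney U-test for genotype comparisons, with
Bonferroni correction over the post-hoc family actually performed.  A raw
p < 0.05 that loses significance after correction is flagged ``marginal``
(shown in parentheses on figure panels by convention).

Responder classification marks flies whose window-2 behavior rose relative
to the flanking reference windows 1/3 — by more than 50% against a nonzero
reference, or above an absolute floor (1 lunge/min; 500 ms/min of wing
extension) when no behavior occurred in either reference window.  Fisher's
exact test compares responder frequencies against anatomical frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stim_schedule import WindowSummary

__all__ = [
    "StatResult",
    "StatReport",
    "ResponderRules",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "bonferroni",
    "fisher_exact",
    "window_comparison_suite",
    "classify_responders",
    "t_test_counts",
]

ALPHA = 0.05


@dataclass
class StatResult:
    """One test outcome with raw and Bonferroni-corrected p-values.

    ``m`` is the number of comparisons in the correction family (recorded in
    every result for auditability); ``marginal`` marks raw-significant
    results that did not survive correction; ``degenerate`` marks inputs on
    which the statistic is undefined (e.g. all values identical), reported
    as p = 1 rather than an error.
    """

    test: str
    statistic: float
    p_raw: float
    m: int = 1
    groups: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 or math.isnan(self.p_raw)):
            raise ValueError(f"p_raw out of [0,1]: {self.p_raw}")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def p_corrected(self) -> float:
        return bonferroni(self.p_raw, self.m)

    @property
    def significant(self) -> bool:
        return self.p_corrected < ALPHA

    @property
    def marginal(self) -> bool:
        return self.p_raw < ALPHA and not self.significant

    def with_m(self, m: int) -> "StatResult":
        return StatResult(self.test, self.statistic, self.p_raw, m, self.groups, self.degenerate)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "groups": self.groups,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "m": self.m,
            "p_corrected": self.p_corrected,
            "significant": self.significant,
            "marginal": self.marginal,
            "degenerate": self.degenerate,
        }


@dataclass
class StatReport:
    """Omnibus result plus the gated post-hoc family."""

    omnibus: StatResult
    posthoc: list[StatResult] = field(default_factory=list)
    design: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [self.omnibus.to_dict()] + [r.to_dict() for r in self.posthoc]
        df = pd.DataFrame(rows)
        df.insert(0, "design", self.design)
        return df


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-corrected p-value, capped at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def _as_arrays(*groups) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float) for g in groups]


def kruskal_wallis(*groups) -> StatResult:
    """Kruskal-Wallis H-test (tie-corrected) across >= 2 groups.

    When every value in every group is identical the tie correction leaves
    the statistic undefined; the result is p = 1 with the degenerate flag.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = _as_arrays(*groups)
    if any(a.size == 0 for a in arrs):
        raise ValueError("each group needs at least 1 value")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return StatResult("kruskal_wallis", float("nan"), 1.0, degenerate=True)
    h, p = stats.kruskal(*arrs)
    return StatResult("kruskal_wallis", float(h), float(p))


def wilcoxon_signed_rank(a, b, exact_below_n: int = 26) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  The exact null
    distribution over sign assignments is used when the effective n is below
    ``exact_below_n`` and the absolute differences are tie-free; otherwise a
    tie-corrected normal approximation (no continuity correction).  All
    differences zero yields p = 1 with the degenerate flag.
    """
    a, b = _as_arrays(a, b)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, degenerate=True)
    untied = np.unique(np.abs(d)).size == n
    if n < exact_below_n and untied:
        stat, p = stats.wilcoxon(d, method="exact", alternative="two-sided")
    else:
        stat, p = stats.wilcoxon(
            d, method="approx", alternative="two-sided", correction=False
        )
    return StatResult("wilcoxon_signed_rank", float(stat), float(min(p, 1.0)))


def mann_whitney_u(a, b, exact_below_n: int = 20) -> StatResult:
    """Two-sided Mann-Whitney U-test on independent samples.

    Exact for small untied samples (both below ``exact_below_n``),
    tie-corrected normal approximation (no continuity correction) otherwise.
    """
    a, b = _as_arrays(a, b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    untied = np.unique(pooled).size == pooled.size
    if untied and a.size < exact_below_n and b.size < exact_below_n:
        u, p = stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")
    else:
        u, p = stats.mannwhitneyu(
            a, b, method="asymptotic", alternative="two-sided", use_continuity=False
        )
    return StatResult("mann_whitney_u", float(u), float(min(p, 1.0)))


def fisher_exact(table) -> StatResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of all tables (at
    fixed margins) no more probable than the observed one.  A zero margin
    carries no information: p = 1 with the degenerate flag.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        odds = float("nan")
        return StatResult("fisher_exact", odds, 1.0, degenerate=True)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return StatResult("fisher_exact", float(odds), float(min(p, 1.0)))


def t_test_counts(a, b) -> StatResult:
    """Plain two-sample t-test for cell-count comparisons (parametric path)."""
    a, b = _as_arrays(a, b)
    stat, p = stats.ttest_ind(a, b)
    return StatResult("t_test", float(stat), float(p))


# ---------------------------------------------------------------------------
# comparison suites over WindowSummary collections

def _rates_matrix(
    summaries: list[WindowSummary], behavior: str, fly: str, windows: tuple[int, ...]
) -> np.ndarray:
    """pairs × windows rate matrix (paired rows, one per fly/pair)."""
    mat = np.array(
        [[s.rate(fly, behavior, w) for w in windows] for s in summaries], dtype=float
    )
    return mat


def window_comparison_suite(
    summaries: list[WindowSummary],
    behavior: str,
    design: str = "within_windows",
    fly: str = "tester",
    windows: tuple[int, ...] = (1, 2, 3),
    test_genotype: str | None = None,
    window: int = 2,
) -> StatReport:
    """The full omnibus-gated, Bonferroni-corrected comparison scheme.

    ``within_windows``: Kruskal-Wallis across the given windows' rates; if
    p < 0.05, paired signed-rank tests between all window pairs (paired per
    fly), Bonferroni m = number of post-hoc tests performed.

    ``between_genotypes``: Kruskal-Wallis across genotypes on the rate in
    one ``window``; if p < 0.05, Mann-Whitney tests of the testing genotype
    against each control, m = number of controls.  Each post-hoc result
    carries the family size m; marginal flags follow the parenthesis rule.
    """
    if design == "within_windows":
        mat = _rates_matrix(summaries, behavior, fly, windows)
        if mat.shape[0] < 2:
            raise ValueError("need >= 2 pairs for a within-window comparison")
        omnibus = kruskal_wallis(*[mat[:, j] for j in range(mat.shape[1])])
        omnibus.groups = "windows " + ",".join(map(str, windows))
        posthoc: list[StatResult] = []
        if omnibus.p_raw < ALPHA:
            pairs = [
                (i, j) for i in range(len(windows)) for j in range(i + 1, len(windows))
            ]
            m = len(pairs)
            for i, j in pairs:
                r = wilcoxon_signed_rank(mat[:, j], mat[:, i]).with_m(m)
                r.groups = f"window {windows[j]} vs window {windows[i]}"
                posthoc.append(r)
        return StatReport(omnibus=omnibus, posthoc=posthoc, design=design)

    if design == "between_genotypes":
        by_geno: dict[str, list[float]] = {}
        for s in summaries:
            by_geno.setdefault(s.genotype, []).append(s.rate(fly, behavior, window))
        genotypes = list(by_geno)
        if len(genotypes) < 2:
            raise ValueError("need >= 2 genotypes for a genotype comparison")
        if test_genotype is None:
            test_genotype = genotypes[0]
        if test_genotype not in by_geno:
            raise ValueError(f"unknown test genotype {test_genotype!r}")
        omnibus = kruskal_wallis(*[by_geno[g] for g in genotypes])
        omnibus.groups = "genotypes " + ",".join(genotypes)
        posthoc = []
        if omnibus.p_raw < ALPHA:
            controls = [g for g in genotypes if g != test_genotype]
            m = len(controls)
            for g in controls:
                r = mann_whitney_u(by_geno[test_genotype], by_geno[g]).with_m(m)
                r.groups = f"{test_genotype} vs {g}"
                posthoc.append(r)
        return StatReport(omnibus=omnibus, posthoc=posthoc, design=design)

    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# responder classification

@dataclass(frozen=True)
class ResponderRules:
    """Thresholds of the window-2 'behavior increased' classification."""

    relative_increase: float = 0.5
    lunge_floor: float = 1.0  # bouts/min
    wing_floor: float = 0.5  # s/min (500 ms/min)
    reference_windows: tuple[int, ...] = (1, 3)

    def floor(self, behavior: str) -> float:
        if behavior == "lunge":
            return self.lunge_floor
        if behavior == "wing_extension":
            return self.wing_floor
        raise ValueError(f"no responder floor defined for behavior {behavior!r}")


def classify_responders(
    summaries: list[WindowSummary],
    behavior: str,
    rules: ResponderRules = ResponderRules(),
    fly: str = "tester",
) -> pd.DataFrame:
    """Per-fly window-2 responder classification.

    A fly responds if window 2 exceeds a *nonzero* reference window (1 or 3
    — either suffices) by more than ``relative_increase``, or — when no
    behavior was seen in either reference window — if window 2 exceeds the
    behavior's absolute floor.  Returns a tidy frame with columns
    ``pair_id, genotype, behavior, responder``.
    """
    rows = []
    for s in summaries:
        w2 = s.rate(fly, behavior, 2)
        refs = [s.rate(fly, behavior, w) for w in rules.reference_windows]
        relative = any(r > 0 and w2 > (1 + rules.relative_increase) * r for r in refs)
        floor = all(r == 0 for r in refs) and w2 > rules.floor(behavior)
        rows.append((s.pair_id, s.genotype, behavior, bool(relative or floor)))
    return pd.DataFrame(rows, columns=["pair_id", "genotype", "behavior", "responder"])
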