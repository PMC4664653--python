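"""Normality-gated group comparisons between brain regions.

Each group (the per-animal mean ratios of one region) is first tested
against a Gaussian; if every group passes at alpha = 0.05 the parametric
path is taken (unpaired two-sided t-test, or one-way ANOVA with Tukey's
HSD), otherwise the rank-based path (Mann-Whitney U, or Kruskal-Wallis with
Dunn's pairwise test under Holm adjustment). All tests are two-sided and
significance is declared at p < 0.05.

The default normality test is D'Agostino-Pearson; Shapiro-Wilk is
selectable (and is used automatically for 3 <= n < 8, where the
D'Agostino-Pearson statistic is undefined).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "normality_gate",
    "compare_two",
    "compare_many",
    "mann_whitney",
    "tukey_pairwise",
    "results_to_frame",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    test_name: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    alpha: float = ALPHA
    pairwise: dict[tuple[str, str], float] | None = None
    normality: dict[str, bool] = field(default_factory=dict)
    normality_test: str = "dagostino"

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _gate_one(x: np.ndarray, alpha: float, method: str) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        warnings.warn(
            f"normality gate: n = {x.size} < 3, failing closed (nonparametric path)",
            stacklevel=3,
        )
        return False
    if np.ptp(x) == 0:
        warnings.warn(
            "normality gate: constant sample, failing closed (nonparametric path)",
            stacklevel=3,
        )
        return False
    if method == "dagostino":
        if x.size < 8:
            warnings.warn(
                "normality gate: n < 8 is too small for D'Agostino-Pearson; "
                "using Shapiro-Wilk",
                stacklevel=3,
            )
            p = sps.shapiro(x).pvalue
        else:
            p = sps.normaltest(x).pvalue
    elif method == "shapiro":
        p = sps.shapiro(x).pvalue
    else:
        raise ValueError(f"unknown normality test {method!r}")
    return bool(p >= alpha)


def normality_gate(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
    method: str = "dagostino",
) -> dict[str, bool]:
    """Per-group Gaussian-fit gate. True = consistent with a Gaussian."""
    return {name: _gate_one(np.asarray(x), alpha, method) for name, x in groups.items()}


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for pooled n <= 20 (the exact null
    distribution does not correct for ties, which is conservative), normal
    approximation with tie correction otherwise."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    exact = pooled.size <= 20
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def compare_two(
    a: Sequence[float],
    b: Sequence[float],
    names: tuple[str, str] = ("A", "B"),
    alpha: float = ALPHA,
    normality_test: str = "dagostino",
    force: str | None = None,
) -> StatResult:
    """Two-region comparison: t-test if both groups pass the normality gate,
    Mann-Whitney otherwise. ``force`` ("parametric"/"nonparametric") skips
    the gate — e.g. to reproduce a reported Mann-Whitney p directly."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    gate = normality_gate({names[0]: a, names[1]: b}, alpha, normality_test)
    if force == "parametric" or (force is None and all(gate.values())):
        res = sps.ttest_ind(a, b)
        return StatResult("t-test", names, float(res.statistic), float(res.pvalue),
                          alpha, None, gate, normality_test)
    stat, p = mann_whitney(a, b)
    return StatResult("Mann-Whitney", names, stat, p, alpha, None, gate, normality_test)


def tukey_pairwise(groups: Mapping[str, np.ndarray]) -> dict[tuple[str, str], float]:
    names = list(groups)
    res = sps.tukey_hsd(*(np.asarray(groups[n], dtype=float) for n in names))
    out = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        out[(names[i], names[j])] = float(res.pvalue[i, j])
    return out


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def dunn_pairwise(groups: Mapping[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's rank-based pairwise test after Kruskal-Wallis, with tie
    correction, Holm-adjusted."""
    names = list(groups)
    sizes = np.array([len(groups[n]) for n in names])
    pooled = np.concatenate([np.asarray(groups[n], dtype=float) for n in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(names)), 2))
    raw = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw[k] = 2.0 * sps.norm.sf(abs(z))
    adj = _holm(raw)
    return {(names[i], names[j]): float(adj[k]) for k, (i, j) in enumerate(pairs)}


def compare_many(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
    normality_test: str = "dagostino",
    force: str | None = None,
) -> StatResult:
    """Three-or-more-region comparison: one-way ANOVA + Tukey HSD if all
    groups pass the gate, Kruskal-Wallis + Dunn (Holm) otherwise."""
    if len(groups) < 3:
        raise ValueError("compare_many requires >= 3 groups; use compare_two")
    arrays = {n: np.asarray(x, dtype=float) for n, x in groups.items()}
    if any(x.size < 2 for x in arrays.values()):
        raise ValueError("every group needs n >= 2")
    names = tuple(arrays)
    gate = normality_gate(arrays, alpha, normality_test)
    if force == "parametric" or (force is None and all(gate.values())):
        res = sps.f_oneway(*arrays.values())
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # degenerate zero between-group variance
            stat, p = max(stat, 0.0), 1.0
        return StatResult(
            "one-way ANOVA + Tukey", names, stat, p,
            alpha, tukey_pairwise(arrays), gate, normality_test,
        )
    res = sps.kruskal(*arrays.values())
    return StatResult(
        "Kruskal-Wallis + Dunn (Holm)", names, float(res.statistic), float(res.pvalue),
        alpha, dunn_pairwise(arrays), gate, normality_test,
    )


def results_to_frame(results: Sequence[StatResult]):
    """Flat comparisons table: one row per omnibus test and per post-hoc pair."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {"comparison": " vs ".join(r.groups), "test": r.test_name,
             "statistic": r.statistic, "p_value": r.p_value, "adjusted_p": np.nan,
             "significant": r.significant,
             "normality_gate": all(r.normality.values()) if r.normality else np.nan}
        )
        for (a, b), p in (r.pairwise or {}).items():
            rows.append(
                {"comparison": f"{a} vs {b}", "test": r.test_name + " (pairwise)",
                 "statistic": np.nan, "p_value": np.nan, "adjusted_p": p,
                 "significant": p < r.alpha, "normality_gate": np.nan}
            )
    return pd.DataFrame(
        rows,
        columns=["comparison", "test", "statistic", "p_value", "adjusted_p",
                 "significant", "normality_gate"],
    )
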