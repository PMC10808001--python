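"""Localization-stratified nonparametric statistics over element properties.

The omnibus test across localization groups is the Kruskal–Wallis rank sum
test (midrank tie correction, chi-square reference distribution, exact
permutation enumeration for tiny samples). Pairwise contrasts are Wilcoxon
rank-sum tests reported with the common-language effect size

    CLES(A, B) = [#(a > b) + 0.5 · #(a = b)] / (n_A · n_B)

and the plain difference of group medians; Holm adjustment is applied
across the whole pairwise family. A summary-statistic unpaired t test
(pooled or Welch) covers the small parametric comparisons used for
replicate instrument measurements.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .properties import basic_fraction  # noqa: F401  (re-exported convenience)


@dataclass
class TestResult:
    __test__ = False  # dataclass, not a pytest case

    statistic: float
    p_value: float
    method: str
    effect_size: Optional[float] = None   # CLES, pairwise only
    median_diff: Optional[float] = None   # pairwise only
    adjusted_p: Optional[float] = None    # Holm, filled by the caller
    groups: tuple = ()
    extra: dict = field(default_factory=dict)


def _check_groups(groups: Mapping[str, Sequence[float]], min_groups: int = 2) -> None:
    if len(groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups, got {len(groups)}")
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"group {name!r} contains non-finite values")


def _kw_statistic(values: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Kruskal–Wallis H with midrank tie correction (labels are 0..k-1)."""
    n = len(values)
    ranks = sps.rankdata(values)
    h = 0.0
    for g in range(k):
        r = ranks[labels == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n) if n > 1 else 1.0
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]],
    n_exact: int = 10,
    n_perm: int = 0,
    seed: int | None = None,
) -> TestResult:
    """Kruskal–Wallis rank sum test across ≥ 2 groups.

    The p-value comes from the chi-square distribution with k−1 degrees of
    freedom; when the total sample size is ≤ ``n_exact`` the exact
    permutation p over all label assignments is computed instead, and
    ``n_perm > 0`` requests a Monte Carlo permutation p for larger samples.
    All-identical data yield H = 0, p = 1 by convention.
    """
    _check_groups(groups)
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    labels = np.concatenate(
        [np.full(len(groups[g]), i) for i, g in enumerate(names)]
    )
    k, n = len(names), len(values)
    if n < 3:
        raise ValueError("need a total of at least 3 observations")
    if np.all(values == values[0]):
        return TestResult(0.0, 1.0, "kruskal-wallis", groups=tuple(names))
    h_obs = _kw_statistic(values, labels, k)
    extra: dict = {}
    if n <= n_exact:
        p = _kw_exact_p(values, labels, k, h_obs)
        method = "kruskal-wallis/exact"
    elif n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        lab = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(lab)
            if _kw_statistic(values, lab, k) >= h_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        method = "kruskal-wallis/permutation"
        extra["n_perm"] = n_perm
    else:
        p = float(sps.chi2.sf(h_obs, k - 1))
        method = "kruskal-wallis/chi2"
    return TestResult(float(h_obs), float(p), method, groups=tuple(names), extra=extra)


def _kw_exact_p(values: np.ndarray, labels: np.ndarray, k: int, h_obs: float) -> float:
    """Exact permutation p by enumerating all distinct label assignments."""
    n = len(values)
    sizes = [int((labels == g).sum()) for g in range(k)]
    count = total = 0
    positions = list(range(n))

    def assign(remaining: list[int], g: int, lab: np.ndarray):
        nonlocal count, total
        if g == k - 1:
            lab2 = lab.copy()
            lab2[remaining] = g
            total += 1
            if _kw_statistic(values, lab2, k) >= h_obs - 1e-12:
                count += 1
            return
        for combo in itertools.combinations(remaining, sizes[g]):
            lab2 = lab.copy()
            lab2[list(combo)] = g
            rest = [p for p in remaining if p not in combo]
            assign(rest, g + 1, lab2)

    assign(positions, 0, np.full(n, -1))
    return count / total


def cles(a: Sequence[float], b: Sequence[float]) -> float:
    """Common-language effect size: P(a > b) + 0.5·P(a = b)."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float(((a > b).sum() + 0.5 * (a == b).sum()) / (a.shape[0] * b.shape[1]))


def rank_sum_pair(
    a: Sequence[float], b: Sequence[float], exact_max: int = 10
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (U statistic, p, method).

    Exact null distribution when both samples are ≤ ``exact_max`` (scipy's
    exact method requires no ties and falls back to the tie-corrected
    normal approximation otherwise).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) <= exact_max and len(b) <= exact_max and len(np.unique(np.r_[a, b])) == len(a) + len(b):
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "asymptotic"


def pairwise_rank_sum(
    groups: Mapping[str, Sequence[float]], holm: bool = True
) -> list[TestResult]:
    """All unordered pairwise Wilcoxon rank-sum tests with CLES and the
    difference of medians; Holm adjustment across the family."""
    _check_groups(groups)
    names = list(groups)
    results = []
    for g1, g2 in itertools.combinations(names, 2):
        a, b = np.asarray(groups[g1], float), np.asarray(groups[g2], float)
        u, p, method = rank_sum_pair(a, b)
        results.append(
            TestResult(
                u, p, f"rank-sum/{method}",
                effect_size=cles(a, b),
                median_diff=float(np.median(a) - np.median(b)),
                groups=(g1, g2),
            )
        )
    if holm and results:
        holm_adjust(results)
    return results


def holm_adjust(results: Sequence[TestResult]) -> None:
    """Fill ``adjusted_p`` with Holm step-down values across one family."""
    adj = multipletests([r.p_value for r in results], method="holm")[1]
    for r, p in zip(results, adj):
        r.adjusted_p = float(p)


def unpaired_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> TestResult:
    """Two-tailed unpaired t test from summary statistics.

    ``welch=False`` pools the variances (classic two-sample t); ``welch=True``
    uses the Welch–Satterthwaite degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == sd2 == 0:
        if mean1 == mean2:
            return TestResult(0.0, 1.0, "t/degenerate")
        raise ValueError("zero variance with unequal means: t undefined")
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return TestResult(float(t), float(p), "t/welch" if welch else "t/pooled",
                      extra={"df": float(df)})


def unpaired_t_raw(x: Sequence[float], y: Sequence[float], welch: bool = False) -> TestResult:
    """Two-tailed unpaired t test from raw vectors."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return unpaired_t(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), welch=welch
    )


DEFAULT_PROPERTIES = ("basic_fraction", "H", "muH")


def element_property_frame(records, elements_by_id, labels, tables) -> pd.DataFrame:
    """One row per element with its localization label and the properties
    compared across groups (basic K/R fraction, H, µH)."""
    from .properties import hydrophobic_moment, mean_hydrophobicity

    rows = []
    by_id = {r.id: r for r in records}
    for sid, elements in elements_by_id.items():
        rec = by_id[sid]
        label = labels.get(sid, rec.label)
        for el in elements:
            res = rec.subsequence(el.start, el.end)
            rows.append({
                "sequence_id": sid, "label": label,
                "start": el.start, "end": el.end,
                "basic_fraction": basic_fraction(res),
                "H": mean_hydrophobicity(res, tables),
                "muH": hydrophobic_moment(res, tables),
            })
    return pd.DataFrame(rows)


def compare_by_localization(
    frame: pd.DataFrame,
    properties: Sequence[str] = DEFAULT_PROPERTIES,
) -> dict:
    """Per-property omnibus + pairwise comparison across localization groups.

    ``frame`` has one row per element with a ``label`` column and one column
    per property. Holm adjustment spans all pairs × properties as one
    family. Returns a JSON-serialisable report with group medians and IQRs.
    """
    labels = [l for l in frame["label"].dropna().unique()]
    if len(labels) < 2:
        raise ValueError("need at least 2 localization groups")
    report: dict = {"groups": {}, "properties": {}}
    for g in labels:
        report["groups"][g] = int((frame["label"] == g).sum())
    all_pairwise: list[TestResult] = []
    for prop in properties:
        groups = {
            g: frame.loc[frame["label"] == g, prop].to_numpy() for g in labels
        }
        omnibus = kruskal_wallis(groups)
        pairwise = pairwise_rank_sum(groups, holm=False)
        all_pairwise.extend(pairwise)
        summary = {
            g: {
                "median": float(np.median(v)),
                "iqr": [float(np.percentile(v, 25)), float(np.percentile(v, 75))],
                "n": int(len(v)),
            }
            for g, v in groups.items()
        }
        report["properties"][prop] = {
            "omnibus": {
                "statistic": omnibus.statistic, "p_value": omnibus.p_value,
                "method": omnibus.method,
            },
            "pairwise": pairwise,
            "summary": summary,
        }
    holm_adjust(all_pairwise)
    for prop in properties:
        report["properties"][prop]["pairwise"] = [
            {
                "groups": list(r.groups), "statistic": r.statistic,
                "p_value": r.p_value, "adjusted_p": r.adjusted_p,
                "cles": r.effect_size, "median_diff": r.median_diff,
                "method": r.method,
            }
            for r in report["properties"][prop]["pairwise"]
        ]
    return report
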