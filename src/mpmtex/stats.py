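"""Group comparisons with normality-gated tests, BH adjustment and tiers.

Each feature (or normalized channel brightness) is compared between two
groups with Welch's t-test when both groups pass a Shapiro-Wilk normality
check, and a two-sided Mann-Whitney U test otherwise. Feature p-values are
Benjamini-Hochberg adjusted jointly across the tested features; brightness
comparisons are reported per channel without adjustment. Significance is
flagged in tiers: the number of configured thresholds the (adjusted)
p-value falls below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "normality_test",
    "two_group_pvalue",
    "bh_adjust",
    "feature_significance",
    "brightness_comparison",
    "results_to_frame",
]

FEATURE_TIERS = (0.1, 0.05, 0.02)
BRIGHTNESS_TIERS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class StatResult:
    """Outcome of one two-group comparison."""

    name: str
    test: str               # "welch_t" | "mann_whitney_u" | "none"
    p_raw: float
    p_adj: float
    tier: int
    comparable: bool = True


def _tier(p: float, thresholds: tuple[float, ...]) -> int:
    if not np.isfinite(p):
        return 0
    return int(sum(p < t for t in thresholds))


def normality_test(values) -> float:
    """Shapiro-Wilk p-value; errors on n < 3 or constant input."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant values")
    return float(sps.shapiro(arr).pvalue)


def two_group_pvalue(a, b, alpha_norm: float = 0.05) -> tuple[str, float]:
    """Two-sided p-value with the normality gate.

    Welch's t-test is used iff BOTH groups pass Shapiro-Wilk at
    ``alpha_norm`` (p > alpha); otherwise a two-sided Mann-Whitney U test.
    A constant group counts as non-normal; if all values in both groups are
    identical the comparison is vacuous and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(np.concatenate([a, b])) == 0:
        return "welch_t", 1.0

    def _passes(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False
        return normality_test(x) > alpha_norm

    if _passes(a) and _passes(b):
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        return "welch_t", p
    p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
    return "mann_whitney_u", p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.asarray(sps.false_discovery_control(p, method="bh"))


def feature_significance(
    table,
    thresholds: tuple[float, ...] = FEATURE_TIERS,
    alpha_norm: float = 0.05,
) -> list[StatResult]:
    """Tumor-vs-normal comparison of every feature, BH-adjusted jointly.

    ``table`` is a texture.FeatureTable. Tier = number of thresholds the
    adjusted p-value falls below.
    """
    labels = np.asarray(table.labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("feature table must contain exactly two classes")
    mask = labels == classes[0]
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("each class needs at least 3 samples")

    names, tests, praw = [], [], []
    X = table.features.to_numpy(dtype=float)
    for j, name in enumerate(table.feature_names):
        test, p = two_group_pvalue(X[mask, j], X[~mask, j], alpha_norm=alpha_norm)
        names.append(name)
        tests.append(test)
        praw.append(p)
    padj = bh_adjust(praw)
    return [
        StatResult(name=n, test=t, p_raw=p, p_adj=float(q),
                   tier=_tier(float(q), thresholds))
        for n, t, p, q in zip(names, tests, praw, padj)
    ]


def brightness_comparison(
    records: list,
    grouping: str = "class",
    thresholds: tuple[float, ...] = BRIGHTNESS_TIERS,
    alpha_norm: float = 0.05,
) -> list[StatResult]:
    """Per-channel comparison of FAD-normalized brightness, no adjustment.

    ``grouping`` is "class" (tumor vs normal over all records) or
    "preparation:tumor" / "preparation:normal" (FFPE vs fixed-frozen within
    one class). A channel present in only one group is an error; a channel
    constant across both groups (FAD, which is 1 by construction) is
    reported as not comparable rather than tested.
    """
    if grouping == "class":
        g1 = [r for r in records if r.label == "tumor"]
        g2 = [r for r in records if r.label == "normal"]
    elif grouping.startswith("preparation:"):
        cls = grouping.split(":", 1)[1]
        pool = [r for r in records if r.label == cls]
        g1 = [r for r in pool if r.preparation == "FFPE"]
        g2 = [r for r in pool if r.preparation == "frozen"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("each group needs at least 3 samples")

    chans1 = {ch for r in g1 for ch in r.normalized}
    chans2 = {ch for r in g2 for ch in r.normalized}
    only = chans1 ^ chans2
    if only:
        raise ValueError(f"channel(s) {sorted(only)} absent from one group")

    results = []
    for ch in sorted(chans1):
        # A channel may be carried by only a subset of a mixed-preparation
        # group (NADH exists for FFPE members only); compare over carriers.
        a = np.array([r.normalized[ch] for r in g1 if ch in r.normalized])
        b = np.array([r.normalized[ch] for r in g2 if ch in r.normalized])
        if a.size < 3 or b.size < 3:
            raise ValueError(f"channel {ch!r} has fewer than 3 values in a group")
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise ValueError(f"channel {ch!r} has undefined brightness values")
        if np.ptp(np.concatenate([a, b])) == 0:
            results.append(StatResult(name=ch, test="none", p_raw=float("nan"),
                                      p_adj=float("nan"), tier=0, comparable=False))
            continue
        test, p = two_group_pvalue(a, b, alpha_norm=alpha_norm)
        results.append(StatResult(name=ch, test=test, p_raw=p, p_adj=p,
                                  tier=_tier(p, thresholds)))
    return results


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"name": r.name, "test": r.test, "p_raw": r.p_raw,
         "p_adj": r.p_adj, "tier": r.tier}
        for r in results
    ])
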