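"""Replicate-level viability statistics.

Viability (fraction of seeded embryos reaching the pupal stage) is compared
across sucrose concentrations with a one-way ANOVA plus eta-squared effect
size, Tukey HSD pairwise tests summarized as a compact letter display,
Levene's mean-centered test for variance homogeneity, and residual moment
diagnostics (adjusted Fisher–Pearson skewness and excess kurtosis, the
convention used by common spreadsheet software).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "one_way_anova_eta2",
    "tukey_hsd",
    "levene_mean_centered",
    "residual_moments",
    "ViabilityStatsResult",
    "viability_stats",
]


def _check_groups(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    return groups


def one_way_anova_eta2(groups):
    """Classical one-way ANOVA with eta-squared effect size.

    Returns ``(F, p, eta2)`` where ``eta2 = SS_between / SS_total``.
    """
    groups = _check_groups(groups)
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    dfb = len(groups) - 1
    dfw = allv.size - len(groups)
    sst = ssb + ssw
    eta2 = ssb / sst if sst > 0 else 0.0
    if ssw == 0:
        # identical within-group values: F is 0 when means agree, inf otherwise
        F = 0.0 if ssb == 0 else float("inf")
        p = 1.0 if ssb == 0 else 0.0
        return F, p, float(eta2)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return float(F), p, float(eta2)


def _compact_letters(labels, sig):
    """Greedy insert-and-absorb compact letter display.

    ``sig[(i, j)]`` is True when groups i and j differ significantly.
    Groups sharing any letter are not significantly different. Presentation
    aid only; the pairwise p-values carry the inference.
    """
    letter_sets: list[set] = []
    for i in range(len(labels)):
        placed = False
        for s in letter_sets:
            if all(not sig[tuple(sorted((i, j)))] for j in s):
                s.add(i)
                placed = True
        if not placed:
            letter_sets.append({i})
    # absorb letter sets contained in another
    keep = []
    for s in letter_sets:
        if not any(s < t for t in letter_sets if t is not s):
            keep.append(s)
    # verify every non-significant pair shares a letter; add pair sets if not
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if not sig[(i, j)] and not any(i in s and j in s for s in keep):
                keep.append({i, j})
    keep.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for idx, s in enumerate(keep):
        for i in sorted(s):
            letters[labels[i]] += alphabet[idx % len(alphabet)]
    return letters


def tukey_hsd(groups, alpha=0.05, labels=None):
    """Tukey honestly-significant-difference pairwise comparisons.

    Returns a DataFrame (group_1, group_2, mean_diff, p_adj, significant)
    and a dict mapping group label -> compact-letter string; groups that
    share a letter are not significantly different at ``alpha``.
    """
    groups = _check_groups(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    res = stats.tukey_hsd(*groups)
    rows = []
    sig = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group_1": labels[i],
                    "group_2": labels[j],
                    "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                    "p_adj": p,
                    "significant": p < alpha,
                }
            )
            sig[(i, j)] = p < alpha
    letters = _compact_letters(list(labels), sig)
    return pd.DataFrame(rows), letters


def levene_mean_centered(groups):
    """Levene's homoscedasticity test on absolute deviations from group means.

    Equivalent to a one-way ANOVA applied to ``|value - group mean|``.
    Returns ``(W, p)``.
    """
    groups = _check_groups(groups)
    W, p = stats.levene(*groups, center="mean")
    return float(W), float(p)


def residual_moments(residuals):
    """Adjusted Fisher–Pearson skewness and excess kurtosis of residuals.

    Sample-size-corrected (bias=False) versions, matching spreadsheet
    SKEW/KURT conventions; kurtosis is reported as excess (normal = 0).
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 4:
        raise ValueError("need at least 4 residuals for moment diagnostics")
    if np.ptp(r) == 0:
        raise ValueError("residuals have zero variance")
    return (
        float(stats.skew(r, bias=False)),
        float(stats.kurtosis(r, bias=False, fisher=True)),
    )


@dataclass
class ViabilityStatsResult:
    F: float
    p: float
    eta2: float
    tukey: pd.DataFrame
    letters: dict
    levene_W: float
    levene_p: float
    skewness: float
    excess_kurtosis: float
    alpha: float = 0.05

    def to_dict(self):
        return {
            "anova": {"F": self.F, "p": self.p, "eta2": self.eta2},
            "tukey": self.tukey.to_dict(orient="records"),
            "letters": self.letters,
            "levene": {"W": self.levene_W, "p": self.levene_p},
            "residual_moments": {
                "skewness": self.skewness,
                "excess_kurtosis": self.excess_kurtosis,
            },
            "alpha": self.alpha,
        }


def viability_stats(groups, labels=None, alpha=0.05) -> ViabilityStatsResult:
    """Full viability analysis for per-vial viabilities grouped by concentration."""
    groups = _check_groups(groups)
    F, p, eta2 = one_way_anova_eta2(groups)
    tukey, letters = tukey_hsd(groups, alpha=alpha, labels=labels)
    W, lp = levene_mean_centered(groups)
    resid = np.concatenate([g - g.mean() for g in groups])
    skw, kur = residual_moments(resid)
    return ViabilityStatsResult(F, p, eta2, tukey, letters, W, lp, skw, kur, alpha)
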