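"""Assumption checks, one-way ANOVA and Tukey HSD letter grouping.

Designed for small balanced designs such as triplicate 440/510 nm band ratios
across copigment:pigment molar ratios: Levene's test (centre = mean) for
homogeneity of variance, Shapiro-Wilk on pooled residuals for normality,
classic one-way ANOVA, and Tukey(-Kramer) pairwise comparisons with p-values
from the studentized range distribution, summarised as a compact letter
display (groups sharing a letter are not significantly different).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatioSample",
    "AssumptionResult",
    "TukeyComparison",
    "GroupStatsResult",
    "check_assumptions",
    "one_way_anova",
    "anova_tukey",
    "compact_letter_display",
    "load_reference_ratios",
    "load_q_critical_table",
]


@dataclass(frozen=True)
class RatioSample:
    """Replicate measurements of one group (e.g. one molar ratio at one pH)."""

    label: str
    values: tuple[float, ...]
    pH: float | None = None

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError(
                f"group {self.label!r}: need >= 2 replicates, got {len(vals)}"
            )

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class AssumptionResult:
    levene_stat: float
    levene_p: float
    shapiro_stat: float
    shapiro_p: float
    degenerate: bool = False  # zero variance everywhere


@dataclass(frozen=True)
class TukeyComparison:
    group_a: str
    group_b: str
    difference: float  # mean_a - mean_b
    q: float
    p_adj: float


@dataclass(frozen=True)
class GroupStatsResult:
    anova_F: float
    anova_p: float
    df_between: int
    df_within: int
    ms_within: float
    comparisons: tuple[TukeyComparison, ...]
    letters: dict[str, str]
    assumptions: AssumptionResult | None = None
    degenerate: bool = False  # exact separation: zero within-group variance


def _validate(samples: Sequence[RatioSample]) -> None:
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")


def check_assumptions(
    samples: Sequence[RatioSample], alpha: float = 0.05
) -> AssumptionResult:
    """Levene (centre = mean) on the groups; Shapiro-Wilk on pooled residuals.

    With zero variance in every group both tests are undefined; the result is
    flagged degenerate with statistic 0 / p 1.
    """
    _validate(samples)
    groups = [np.asarray(s.values) for s in samples]
    if all(np.ptp(g) == 0 for g in groups):
        return AssumptionResult(0.0, 1.0, 0.0, 1.0, degenerate=True)
    lev_stat, lev_p = stats.levene(*groups, center="mean")
    residuals = np.concatenate([g - g.mean() for g in groups])
    if residuals.size < 3:
        raise ValueError("Shapiro-Wilk needs total n >= 3")
    sh_stat, sh_p = stats.shapiro(residuals)
    return AssumptionResult(
        float(lev_stat), float(lev_p), float(sh_stat), float(sh_p)
    )


def one_way_anova(
    samples: Sequence[RatioSample],
) -> tuple[float, float, int, int, float, bool]:
    """Classic one-way decomposition: returns (F, p, df_between, df_within,
    ms_within, degenerate).  Zero within-group variance everywhere is the
    exact-separation degenerate case (F infinite when the means differ)."""
    _validate(samples)
    groups = [np.asarray(s.values) for s in samples]
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    N = int(ns.sum())
    grand = float(np.concatenate(groups).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df_b, df_w = k - 1, N - k
    ms_within = ss_within / df_w
    degenerate = ss_within == 0.0
    if degenerate:
        F = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = (ss_between / df_b) / ms_within
        p = float(stats.f.sf(F, df_b, df_w))
    return float(F), float(p), df_b, df_w, ms_within, degenerate


def anova_tukey(
    samples: Sequence[RatioSample],
    alpha: float = 0.05,
    assumptions: AssumptionResult | None = None,
) -> GroupStatsResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letter display.

    Unbalanced designs use the Tukey-Kramer standard error.  Adjusted p-values
    come from the studentized range distribution evaluated numerically.  The
    assumptions result is carried along advisorily, never blocking.
    """
    F, p, df_b, df_w, ms_within, degenerate = one_way_anova(samples)
    groups = [np.asarray(s.values) for s in samples]
    labels = [s.label for s in samples]
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    if degenerate:
        warnings.warn(
            "zero within-group variance everywhere: exact separation; "
            "F and p are degenerate",
            stacklevel=2,
        )

    comparisons = []
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            if degenerate:
                distinct = diff != 0.0
                q = np.inf if distinct else 0.0
                p_adj = 0.0 if distinct else 1.0
            else:
                se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_w))
            comparisons.append(
                TukeyComparison(labels[i], labels[j], diff, float(q), p_adj)
            )
            sig[i, j] = sig[j, i] = p_adj < alpha
    letters = compact_letter_display(labels, means, sig)
    return GroupStatsResult(
        anova_F=float(F),
        anova_p=float(p),
        df_between=df_b,
        df_within=df_w,
        ms_within=ms_within,
        comparisons=tuple(comparisons),
        letters=letters,
        assumptions=assumptions,
        degenerate=degenerate,
    )


def compact_letter_display(
    labels: Sequence[str],
    means: Sequence[float],
    significant: np.ndarray,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` is True when groups i and j differ.  Letters are
    assigned in order of ascending group mean ('a' to the lowest, the usual
    convention in food-chemistry tables); ties in mean break by label order.
    Groups share a letter iff no pair inside that letter's set is
    significantly different, and the letter sets regenerate exactly the given
    significance partition.
    """
    k = len(labels)
    # insert step: split every set containing a significant pair
    sets: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for s in [s for s in sets if i in s and j in s]:
                sets.remove(s)
                sets.extend([s - {i}, s - {j}])
            # absorb: drop empty sets, duplicates and sets contained in another
            kept: list[set[int]] = []
            for idx, s in enumerate(sets):
                redundant = any(
                    (s < t) or (s == t and idx > jdx)
                    for jdx, t in enumerate(sets)
                    if jdx != idx
                )
                if not redundant and s:
                    kept.append(s)
            sets = kept
    # letter order: ascending by the smallest group mean in each set
    mean_rank = sorted(range(k), key=lambda i: (means[i], labels[i]))
    pos = {g: r for r, g in enumerate(mean_rank)}
    sets.sort(key=lambda s: min(pos[i] for i in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, sets):
        for i in sorted(s):
            out[labels[i]] += letter
    for lab in out:
        out[lab] = "".join(sorted(out[lab]))
    return out


def letters_partition(
    letters: dict[str, str]
) -> dict[tuple[str, str], bool]:
    """Significance partition implied by a letter display (True = differ)."""
    labs = sorted(letters)
    return {
        (a, b): not (set(letters[a]) & set(letters[b]))
        for i, a in enumerate(labs)
        for b in labs[i + 1 :]
    }


def build_ratio_table(
    results: dict[float, tuple[Sequence[RatioSample], GroupStatsResult]]
) -> pd.DataFrame:
    """Mean +- SD with letters, one row per pH, one column block per group."""
    rows = []
    for ph, (samples, res) in results.items():
        row: dict[str, object] = {"pH": ph, "anova_F": res.anova_F, "anova_p": res.anova_p}
        for s in samples:
            row[f"mean_{s.label}"] = s.mean
            row[f"sd_{s.label}"] = s.sd
            row[f"letter_{s.label}"] = res.letters[s.label]
        rows.append(row)
    return pd.DataFrame(rows)


def load_reference_ratios() -> pd.DataFrame:
    """Published 440/510 nm ratio summary (mean, SD, letters) per pH and ratio."""
    with resources.files("copigmentation.data").joinpath(
        "table3_band_ratios.csv"
    ).open() as f:
        return pd.read_csv(f, comment="#")


def load_q_critical_table() -> pd.DataFrame:
    """Printed 5% studentized-range critical values (cross-check fixture)."""
    with resources.files("copigmentation.data").joinpath(
        "tukey_q_critical.csv"
    ).open() as f:
        return pd.read_csv(f, comment="#")
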