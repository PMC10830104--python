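"""Category-level comparison of normalized uptake rates.

Salts are grouped by the biological relevance of their ions — cations into
macronutrients (K+, NH4+), secondary nutrients (Ca2+, Mg2+), sodium, and
heavy metals (Ag+, Ba2+, Cd2+, Cu2+, Gd3+, La3+, Ni2+); anions into
macronutrients (NO3-, phosphates), secondary nutrients (SO4 2-),
micronutrients (Cl-) and neutral anions (CO3 2-, OH-).  Group means are
compared by one-way ANOVA followed by a Tukey-Kramer post hoc test (the
Kramer correction handles the uneven group sizes), summarized as a compact
letter display: groups sharing a letter are not significantly different.

Studentized-range quantiles come from scipy's numerical distribution, not
from printed tables, so any number of groups works.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import ions

__all__ = [
    "CategoryAssignment",
    "AnovaResult",
    "TukeyResult",
    "StatsError",
    "assign_categories",
    "one_way_anova",
    "tukey_kramer",
    "compact_letters",
    "category_summary",
]


class StatsError(ValueError):
    pass


CATION_CATEGORIES = ("macronutrient", "secondary_nutrient", "sodium", "heavy_metal")
ANION_CATEGORIES = ("macronutrient", "secondary_nutrient", "micronutrient", "neutral")


@dataclass(frozen=True)
class CategoryAssignment:
    salt_name: str
    cation_category: str
    anion_category: str

    def __post_init__(self):
        if self.cation_category not in CATION_CATEGORIES:
            raise StatsError(f"bad cation category {self.cation_category!r}")
        if self.anion_category not in ANION_CATEGORIES:
            raise StatsError(f"bad anion category {self.anion_category!r}")


def assign_categories(salt_name: str) -> CategoryAssignment:
    """Look a salt up in the bundled ion table and map each ion to its category."""
    cation, anion, _, _ = ions.parse_salt(salt_name)
    return CategoryAssignment(
        salt_name=salt_name,
        cation_category=ions.CATIONS[cation].nutrient_class,
        anion_category=ions.ANIONS[anion].nutrient_class,
    )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    undefined: bool = False


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F is the between-group mean square over the within-group mean square with
    (g-1, n-g) degrees of freedom.  When both between- and within-group
    variances vanish (all observations identical) F is undefined and flagged.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise StatsError("need >= 2 groups")
    if any(len(g) == 0 for g in gs):
        raise StatsError("every group needs >= 1 value")
    n = sum(len(g) for g in gs)
    k = len(gs)
    if n <= k:
        raise StatsError("total n must exceed the number of groups")
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0:
        if ms_between == 0:
            return AnovaResult(float("nan"), df_b, df_w, float("nan"), undefined=True)
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = ms_between / ms_within
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p)


@dataclass(frozen=True)
class TukeyResult:
    group_names: Tuple[str, ...]
    pairwise: pd.DataFrame  # columns: group_1, group_2, mean_diff, se, q, p, significant
    letters: Dict[str, str]
    ms_within: float
    df_within: int
    alpha: float


def tukey_kramer(
    groups: Sequence[Sequence[float]],
    names: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey-Kramer all-pairs comparison with unequal group sizes.

    For groups i, j the statistic is
    q_ij = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)),
    referred to the studentized range distribution with k groups and n - k
    degrees of freedom; with equal n the Kramer standard error reduces to the
    classical Tukey one.  Letters come from :func:`compact_letters`.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise StatsError("need >= 2 groups")
    if any(len(g) < 2 for g in gs):
        raise StatsError("every group needs >= 2 values for the pooled variance")
    names = list(names) if names is not None else [f"g{i}" for i in range(len(gs))]
    if len(names) != len(gs):
        raise StatsError("names must match groups")
    k = len(gs)
    n = sum(len(g) for g in gs)
    df_w = n - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    if msw == 0:
        raise StatsError("zero within-group variance: q undefined")
    means = [g.mean() for g in gs]
    rows = []
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(msw / 2.0 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
            significant = p < alpha
            sig[i, j] = sig[j, i] = significant
            rows.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "mean_diff": diff,
                    "se": se,
                    "q": q,
                    "p": p,
                    "significant": significant,
                }
            )
    letters = compact_letters(names, means, sig)
    return TukeyResult(
        group_names=tuple(names),
        pairwise=pd.DataFrame(rows),
        letters=letters,
        ms_within=float(msw),
        df_within=df_w,
        alpha=alpha,
    )


def compact_letters(
    names: Sequence[str], means: Sequence[float], significant: np.ndarray
) -> Dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` marks pairs whose means differ significantly.
    Groups sharing a letter are not significantly different; the letter sets
    form a clique cover of the non-significance graph.  Groups are processed
    in order of descending mean so 'a' tags the largest means.
    """
    k = len(names)
    order = sorted(range(k), key=lambda i: -means[i])
    # letter classes as lists of member indices
    classes: List[set] = [set(order)]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for cls in list(classes):
                if i in cls and j in cls:
                    # split the violated class
                    a, b = cls - {j}, cls - {i}
                    classes.remove(cls)
                    for new in (a, b):
                        if not any(new <= other for other in classes):
                            classes.append(new)
    # absorb: drop classes contained in others (already handled on insert)
    classes = [c for c in classes if not any(c < other for other in classes)]
    # order classes by the best (largest) mean they contain
    classes.sort(key=lambda c: -max(means[i] for i in c))
    letters: Dict[str, List[str]] = {nm: [] for nm in names}
    for li, cls in enumerate(classes):
        ch = chr(ord("a") + li)
        for i in cls:
            letters[names[i]].append(ch)
    return {nm: "".join(sorted(ls)) for nm, ls in letters.items()}


def category_summary(
    results: pd.DataFrame,
    by: str = "cation",
    alpha: float = 0.05,
    value_col: str = "ratio",
) -> Tuple[pd.DataFrame, AnovaResult, Optional[TukeyResult]]:
    """Per-category mean, 95 % CI, n and compact letter for a results table.

    ``results`` needs ``salt_name`` and ``value_col`` (normalized uptake) for
    plant runs.  Categories come from the bundled ion table.  Returns the
    summary table plus the ANOVA and (when every category has >= 2 values)
    Tukey-Kramer results.
    """
    if by not in ("cation", "anion"):
        raise StatsError("by must be 'cation' or 'anion'")
    df = results.copy()
    if "role" in df.columns:
        df = df[df["role"] == "plant"]
    df = df.dropna(subset=[value_col])
    if df.empty:
        raise StatsError("no usable rows in results table")
    cat_col = f"{by}_category"
    df[cat_col] = [
        getattr(assign_categories(s), cat_col) for s in df["salt_name"]
    ]
    grouped = {cat: g[value_col].to_numpy() for cat, g in df.groupby(cat_col)}
    names = list(grouped)
    values = [grouped[nm] for nm in names]
    anova = one_way_anova(values)
    tukey = None
    letters = {nm: "" for nm in names}
    if all(len(v) >= 2 for v in values):
        tukey = tukey_kramer(values, names=names, alpha=alpha)
        letters = tukey.letters
    rows = []
    for nm, v in zip(names, values):
        mean = float(np.mean(v))
        if len(v) >= 2:
            sem = stats.sem(v)
            half = sem * stats.t.ppf(1 - alpha / 2, len(v) - 1)
        else:
            half = float("nan")
        rows.append(
            {
                "category": nm,
                "n": len(v),
                "mean": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "letter": letters[nm],
            }
        )
    summary = pd.DataFrame(rows).sort_values("mean", ascending=False).reset_index(drop=True)
    return summary, anova, tukey
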