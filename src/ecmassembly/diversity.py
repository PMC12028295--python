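"""Alpha diversity indices and the ANOVA / Kruskal-Wallis decision rule.

Indices follow the vegan conventions: Shannon in nats, Simpson as the
Gini-Simpson probability 1 - sum(p^2), Pielou's evenness as Shannon / ln(S),
and Sobs as observed richness.  Group comparisons pick one-way ANOVA when
per-group normality (Shapiro-Wilk) and variance homogeneity (Levene and
Bartlett) all hold at alpha = 0.05, and Kruskal-Wallis otherwise; the full
assumption record is returned so the choice can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity.alpha import pielou_e, shannon, simpson, sobs

from .io import AsvTable

__all__ = [
    "alpha_diversity",
    "GroupTestResult",
    "compare_groups",
    "summarize_by_group",
]


def alpha_diversity(table: AsvTable) -> pd.DataFrame:
    """Per-sample Shannon (nats), Gini-Simpson, Pielou's evenness, Sobs.

    Pielou's evenness is undefined for single-ASV samples and reported as
    missing there.
    """
    totals = table.sample_sums()
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        s = int(sobs(col))
        rows.append(
            {
                "sample_id": sid,
                "shannon": float(shannon(col, base=np.e)),
                "simpson": float(simpson(col)),
                "pielou": float(pielou_e(col)) if s > 1 else np.nan,
                "sobs": s,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


@dataclass
class GroupTestResult:
    """Outcome of the test-selection procedure for one comparison."""

    comparison: str
    test_used: str  # "anova" or "kruskal"
    statistic: float
    p_value: float
    assumption_record: dict

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "assumption_record": self.assumption_record,
        }


def compare_groups(
    values, groups, *, comparison: str = "", alpha: float = 0.05
) -> GroupTestResult:
    """Compare a per-sample metric across factor levels.

    Runs Shapiro-Wilk per group plus Levene and Bartlett across groups; uses
    one-way ANOVA when every assumption p-value exceeds ``alpha``, otherwise
    Kruskal-Wallis.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [values[groups == g] for g in levels]
    if any(len(a) < 3 for a in arrays):
        raise ValueError("each group needs >= 3 samples")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("constant values in all groups")

    shapiro_p = {}
    normal = True
    for g, a in zip(levels, arrays):
        if np.ptp(a) == 0:  # constant group: not testable, treat as non-normal
            shapiro_p[str(g)] = 0.0
            normal = False
            continue
        p = float(stats.shapiro(a).pvalue)
        shapiro_p[str(g)] = p
        normal &= p > alpha
    levene_p = float(stats.levene(*arrays).pvalue)
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            bartlett_p = float(stats.bartlett(*arrays).pvalue)
        if np.isnan(bartlett_p):  # zero-variance group
            bartlett_p = 0.0
    except ValueError:
        bartlett_p = 0.0
    homoscedastic = levene_p > alpha and bartlett_p > alpha

    record = {
        "shapiro_p": shapiro_p,
        "levene_p": levene_p,
        "bartlett_p": bartlett_p,
        "alpha": alpha,
        "normal": bool(normal),
        "homoscedastic": bool(homoscedastic),
    }
    if normal and homoscedastic:
        stat, p = stats.f_oneway(*arrays)
        test = "anova"
    else:
        try:
            stat, p = stats.kruskal(*arrays)
        except ValueError:  # all values identical across groups
            stat, p = 0.0, 1.0
        test = "kruskal"
    return GroupTestResult(
        comparison=comparison,
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        assumption_record=record,
    )


def summarize_by_group(
    results: pd.DataFrame,
    metadata: pd.DataFrame,
    grouping=("host_type", "stage"),
) -> pd.DataFrame:
    """Mean +/- standard error of each index per group.

    Returns a tidy frame with one row per group and ``<index>_mean`` /
    ``<index>_se`` / ``n`` columns.  SE uses the sample standard deviation
    (ddof=1) over the non-missing values.
    """
    grouping = list(grouping)
    metrics = [c for c in results.columns if c != "sample_id"]
    joined = results.join(metadata[grouping], how="inner")
    rows = []
    for levels, sub in joined.groupby(grouping, sort=True):
        if not isinstance(levels, tuple):
            levels = (levels,)
        row = dict(zip(grouping, levels))
        row["n"] = len(sub)
        for mcol in metrics:
            vals = sub[mcol].dropna().to_numpy(float)
            row[f"{mcol}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{mcol}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
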