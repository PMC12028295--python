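"""Indicator-taxon detection: random forest ranking + lnRR effect sizes.

A random-forest classifier (1000 trees) trained on per-sample relative
abundances ranks ASVs by their association with a binary host contrast
(juvenile vs adult, conifer vs broadleaf).  Short-listed ASVs get a log
response ratio lnRR = ln(mean_A / mean_B) with a nonparametric bootstrap 95%
CI and a univariate ANOVA / Kruskal-Wallis test per ASV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from statsmodels.stats.multitest import multipletests

from .diversity import compare_groups
from .io import AsvTable, relative_abundance

logger = logging.getLogger(__name__)

__all__ = [
    "RFResult",
    "rf_classify",
    "lnrr_effects",
    "per_asv_tests",
    "indicator_analysis",
]


@dataclass
class RFResult:
    """Random-forest importance ranking for one contrast."""

    importances: pd.DataFrame  # per ASV: impurity (and optional permutation)
    oob_accuracy: float
    n_trees: int
    seed: int
    ranking_metric: str = "impurity_importance"

    def top(self, n: int, by: str | None = None) -> list[str]:
        by = by or self.ranking_metric
        return list(self.importances.sort_values(by, ascending=False).index[:n])


def rf_classify(
    table: AsvTable,
    labels,
    n_trees: int = 1000,
    seed: int = 0,
    *,
    n_permutation_repeats: int = 0,
) -> RFResult:
    """Train a random forest on relative abundances to predict a binary label.

    Returns per-ASV mean-decrease-in-impurity importances plus out-of-bag
    accuracy; set ``n_permutation_repeats > 0`` to additionally compute
    permutation importance (much slower for large forests) and rank by it.
    Fixed seed gives a reproducible ranking.
    """
    labels = np.asarray(labels)
    if len(pd.unique(labels)) < 2:
        raise ValueError("labels must have at least 2 classes")
    counts = np.bincount(pd.factorize(labels)[0])
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    X = relative_abundance(table).T  # samples x ASVs
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    rf.fit(X, labels)
    imp = pd.DataFrame(
        {"impurity_importance": rf.feature_importances_}, index=table.asv_ids
    )
    ranking = "impurity_importance"
    if n_permutation_repeats > 0:
        perm = permutation_importance(
            rf, X, labels, n_repeats=n_permutation_repeats, random_state=seed,
            n_jobs=1,
        )
        imp["permutation_importance"] = perm.importances_mean
        imp["permutation_importance_std"] = perm.importances_std
        ranking = "permutation_importance"
    return RFResult(
        importances=imp,
        oob_accuracy=float(rf.oob_score_),
        n_trees=n_trees,
        seed=seed,
        ranking_metric=ranking,
    )


def lnrr_effects(
    table: AsvTable,
    labels,
    top_asvs,
    n_boot: int = 1000,
    seed: int = 0,
    *,
    group_a=None,
    group_b=None,
) -> pd.DataFrame:
    """Log response ratios ln(mean_A / mean_B) with bootstrap 95% CIs.

    Group A/B default to the first/second label level in sorted order.  ASVs
    where one group mean is zero get a one-sided +/-inf sentinel lnRR with the
    CI endpoint from the nonzero side; ASVs with both means zero are skipped.
    Group means and SEs are reported in percent.
    """
    top_asvs = list(top_asvs)
    if not top_asvs:
        raise ValueError("top_asvs must be nonempty")
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels))
    a = group_a if group_a is not None else levels[0]
    b = group_b if group_b is not None else levels[1]
    rel = relative_abundance(table)
    idx = {asv: i for i, asv in enumerate(table.asv_ids)}
    ia = np.flatnonzero(labels == a)
    ib = np.flatnonzero(labels == b)
    rng = np.random.default_rng(seed)
    rows = []
    for asv in top_asvs:
        if asv not in idx:
            raise KeyError(f"unknown ASV {asv!r}")
        xa, xb = rel[idx[asv], ia], rel[idx[asv], ib]
        ma, mb = xa.mean(), xb.mean()
        if ma == 0 and mb == 0:
            logger.warning("lnrr_effects: ASV %s zero in both groups, skipped", asv)
            continue
        boot = np.empty(n_boot)
        for t in range(n_boot):
            ra = xa[rng.integers(0, len(xa), len(xa))].mean()
            rb = xb[rng.integers(0, len(xb), len(xb))].mean()
            if ra > 0 and rb > 0:
                boot[t] = np.log(ra / rb)
            elif ra == 0 and rb == 0:
                boot[t] = np.nan
            else:
                boot[t] = np.inf if ra > 0 else -np.inf
        finite = boot[np.isfinite(boot)]
        if ma > 0 and mb > 0:
            lnrr = float(np.log(ma / mb))
            lo, hi = (
                np.percentile(finite, [2.5, 97.5]) if len(finite) else (np.nan, np.nan)
            )
            one_sided = False
        else:
            lnrr = np.inf if ma > 0 else -np.inf
            lo = hi = np.nan
            one_sided = True
        rows.append(
            {
                "asv_id": asv,
                "lnrr": lnrr,
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "one_sided": one_sided,
                "mean_a_pct": 100 * ma,
                "se_a_pct": 100 * xa.std(ddof=1) / np.sqrt(len(xa)),
                "mean_b_pct": 100 * mb,
                "se_b_pct": 100 * xb.std(ddof=1) / np.sqrt(len(xb)),
                "group_a": str(a),
                "group_b": str(b),
            }
        )
    return pd.DataFrame(rows).set_index("asv_id", drop=False)


def per_asv_tests(table: AsvTable, labels, asvs=None) -> pd.DataFrame:
    """Univariate ANOVA / Kruskal-Wallis per ASV on relative abundances.

    Reports both the raw p-value and the Benjamini-Hochberg adjusted one.
    All-zero or constant ASVs are skipped.
    """
    labels = np.asarray(labels)
    rel = relative_abundance(table)
    asvs = list(asvs) if asvs is not None else list(table.asv_ids)
    idx = {asv: i for i, asv in enumerate(table.asv_ids)}
    rows = []
    for asv in asvs:
        vals = rel[idx[asv]]
        if np.ptp(vals) == 0:
            continue
        try:
            res = compare_groups(vals, labels, comparison=asv)
        except ValueError:
            continue
        rows.append(
            {
                "asv_id": asv,
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.set_index("asv_id", drop=False)
    return df


def indicator_analysis(
    table: AsvTable,
    metadata: pd.DataFrame,
    contrast: str = "stage",
    *,
    taxonomy: pd.DataFrame | None = None,
    top_n: int = 30,
    n_trees: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, RFResult]:
    """Full indicator workflow for one binary contrast column of metadata.

    Short-lists the ``top_n`` ASVs by RF importance, then attaches
    lnRR effect sizes, group means +/- SE (%), and per-ASV tests.  The lnRR
    orientation is juvenile/adult for ``stage`` and conifer/broadleaf for
    ``host_type`` (recorded in the ``group_a``/``group_b`` columns).
    """
    labels = metadata.loc[list(table.sample_ids), contrast].to_numpy()
    orientation = {
        "stage": ("juvenile", "adult"),
        "host_type": ("conifer", "broadleaf"),
    }.get(contrast)
    ga, gb = orientation if orientation else (None, None)
    rf = rf_classify(table, labels, n_trees=n_trees, seed=seed)
    short_list = rf.top(top_n)
    eff = lnrr_effects(
        table, labels, short_list, n_boot=n_boot, seed=seed, group_a=ga, group_b=gb
    )
    tests = per_asv_tests(table, labels, asvs=short_list)
    out = eff.join(rf.importances.loc[eff.index], how="left")
    out = out.join(
        tests[["test_used", "statistic", "p_value", "p_adjusted"]], how="left"
    )
    if taxonomy is not None:
        cols = [c for c in ("genus", "lineage") if c in taxonomy.columns]
        out = out.join(taxonomy.loc[taxonomy.index.intersection(out.index), cols])
    return out.sort_values(rf.ranking_metric, ascending=False), rf
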