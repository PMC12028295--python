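"""Beta diversity: Bray-Curtis distances, NMDS ordination, PERMANOVA, ANOSIM.

Distances are computed on Hellinger-transformed relative abundances.
PERMANOVA uses Anderson's distance-based sum-of-squares partition, reporting
both the pseudo-F and R^2 = SS_between / SS_total; ANOSIM uses the rank-based
R statistic.  Both use the permutation p-value estimator
``(1 + #{perm stat >= observed}) / (1 + n_permutations)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, rankdata
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "bray_curtis",
    "OrdinationResult",
    "nmds",
    "group_ellipses",
    "MultivarTestResult",
    "permanova",
    "anosim",
]


def bray_curtis(matrix: np.ndarray, sample_ids) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    ``matrix`` is features x samples (e.g. Hellinger-transformed relative
    abundances).  d(x, y) = sum|x - y| / sum(x + y).
    """
    X = np.asarray(matrix, float).T  # samples x features
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = X.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(sample_ids, zero) if z]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in sample_ids])


@dataclass
class OrdinationResult:
    """NMDS embedding with Kruskal stress-1 and per-group 95% ellipses."""

    coordinates: pd.DataFrame  # samples x (NMDS1, NMDS2)
    stress: float
    ellipses: dict  # group -> {center, cov, radius2}

    def summary(self) -> str:
        lines = [
            f"NMDS ordination: {len(self.coordinates)} samples, "
            f"stress-1 = {self.stress:.3f}",
        ]
        for g, e in self.ellipses.items():
            c = e["center"]
            lines.append(f"  {g}: center = ({c[0]:.3f}, {c[1]:.3f})")
        return "\n".join(lines)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_starts: int = 20,
    groups=None,
    max_iter: int = 300,
    eps: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS of a distance matrix, best of ``n_starts`` restarts.

    Minimizes Kruskal stress-1 (monotone regression of embedded distances on
    observed dissimilarities).  Coordinates are centered.  If ``groups`` maps
    sample ids to labels, a normal-theory 95% ellipse is attached per group.
    """
    from sklearn.manifold import MDS

    if len(d.ids) < 4:
        raise ValueError("NMDS needs at least 4 samples")
    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    coords = mds.fit_transform(np.asarray(d.data))
    coords = coords - coords.mean(axis=0)
    cdf = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"NMDS{i+1}" for i in range(k)]
    )
    ellipses = {}
    if groups is not None:
        labels = pd.Series({s: groups[s] for s in d.ids})
        ellipses = group_ellipses(cdf, labels)
    return OrdinationResult(coordinates=cdf, stress=float(mds.stress_), ellipses=ellipses)


def group_ellipses(coordinates: pd.DataFrame, labels: pd.Series) -> dict:
    """Normal-theory 95% confidence ellipse per group.

    Returns ``{group: {"center": mean, "cov": covariance,
    "radius2": chi2.ppf(0.95, df=2)}}`` — the ellipse is the set
    ``(x - center)' cov^-1 (x - center) = radius2``.
    """
    out = {}
    for g in pd.unique(labels):
        pts = coordinates.loc[labels[labels == g].index].to_numpy(float)
        if len(pts) < 3:
            continue
        out[str(g)] = {
            "center": pts.mean(axis=0),
            "cov": np.cov(pts, rowvar=False),
            "radius2": float(chi2.ppf(0.95, df=coordinates.shape[1])),
        }
    return out


@dataclass
class MultivarTestResult:
    """PERMANOVA / ANOSIM outcome for one factor."""

    factor: str
    method: str
    statistic: float  # R^2 (PERMANOVA) or R (ANOSIM)
    f_statistic: float | None
    p_value: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "method": self.method,
            "statistic": self.statistic,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _factor_array(d: DistanceMatrix, factor) -> np.ndarray:
    if isinstance(factor, (pd.Series, dict)):
        factor = pd.Series(factor)
        return factor.loc[list(d.ids)].to_numpy()
    factor = np.asarray(factor)
    if len(factor) != len(d.ids):
        raise ValueError("factor must cover all samples")
    return factor


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Total and within-group SS from squared distances (Anderson)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 1:
            continue
        block = d2[np.ix_(idx, idx)]
        ss_within += block[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix, factor, n_permutations: int = 999, seed: int = 0, *,
    factor_name: str = "factor",
) -> MultivarTestResult:
    """One-factor PERMANOVA on a distance matrix.

    Reports R^2 = SS_between / SS_total and the pseudo-F, with the label
    permutation p-value.
    """
    labels = _factor_array(d, factor)
    codes, levels = pd.factorize(labels)
    a = len(levels)
    if a < 2:
        raise ValueError("factor needs at least 2 levels")
    n = len(d.ids)
    d2 = np.asarray(d.data) ** 2

    def f_and_r2(c):
        ss_total, ss_within = _permanova_ss(d2, c, a)
        ss_between = ss_total - ss_within
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
        return f, ss_between / ss_total

    f_obs, r2 = f_and_r2(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        f_perm, _ = f_and_r2(rng.permutation(codes))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return MultivarTestResult(
        factor=factor_name,
        method="PERMANOVA",
        statistic=float(r2),
        f_statistic=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def anosim(
    d: DistanceMatrix, factor, n_permutations: int = 999, seed: int = 0, *,
    factor_name: str = "factor",
) -> MultivarTestResult:
    """Analysis of similarities (Clarke's R) with permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (N(N-1)/4),
    ranks taken over all off-diagonal distance pairs.
    """
    labels = _factor_array(d, factor)
    codes, levels = pd.factorize(labels)
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    n = len(d.ids)
    iu = np.triu_indices(n, 1)
    ranks = rankdata(np.asarray(d.data)[iu])
    denom = n * (n - 1) / 4.0

    def r_stat(c):
        within = c[iu[0]] == c[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(codes)) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return MultivarTestResult(
        factor=factor_name,
        method="ANOSIM",
        statistic=float(r_obs),
        f_statistic=None,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
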