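"""GAM-based abundance-occupancy neutral-assembly fit.

The neutral expectation for a dispersal-assembled community is a tight,
monotone relationship between a taxon's mean relative abundance and its
occurrence frequency (the fraction of samples in which it is detected).  The
model here regresses per-ASV occupancy — successes out of the group's sample
count — on log10 mean relative abundance with a penalized binomial
(logit-link) spline smoother.  Two statistics summarize the fit:

* ``pseudo_r2 = 1 - residual deviance / null deviance`` — how much of the
  occupancy deviance the abundance-occupancy curve explains; high values
  indicate a neutral-like community.
* the migration statistic ``m = sum(f_obs*(1-f_obs)) / sum(f_pred*(1-f_pred))``
  — the ratio of observed to fitted occupancy binomial-variance terms.
  Note the statistic equals 1 when observed and fitted frequencies coincide;
  its ecological reading (dispersal vs mismatch) is left to the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.gam.api import BSplines, GLMGam

from .io import AsvTable, relative_abundance

__all__ = [
    "GroupProfile",
    "NeutralFitResult",
    "NeutralOccupancyGAM",
    "occurrence_frequency",
    "migration_rate",
    "fit_all_groups",
]

DEFAULT_ALPHA_GRID = tuple(10.0 ** np.arange(-3, 5))


@dataclass
class GroupProfile:
    """Per-ASV occupancy and abundance within one host group.

    ``f_obs`` is the fraction of the group's samples where the ASV is
    detected; ``mean_log_abund`` is log10 of its mean relative abundance over
    the group's samples.  ASVs absent from the whole group are excluded so
    the log is defined.
    """

    asv_ids: list[str]
    f_obs: np.ndarray
    mean_log_abund: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.f_obs = np.asarray(self.f_obs, float)
        self.mean_log_abund = np.asarray(self.mean_log_abund, float)
        if not (len(self.asv_ids) == len(self.f_obs) == len(self.mean_log_abund)):
            raise ValueError("profile fields must have equal length")
        if self.f_obs.size and (self.f_obs.min() < 0 or self.f_obs.max() > 1):
            raise ValueError("f_obs must lie in [0, 1]")

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "asv_id": self.asv_ids,
                "mean_log_abund": self.mean_log_abund,
                "f_obs": self.f_obs,
            }
        )


def occurrence_frequency(table: AsvTable, group_samples) -> GroupProfile:
    """Build the abundance-occupancy profile of one sample group."""
    group_samples = list(group_samples)
    if not group_samples:
        raise ValueError("empty sample group")
    sub = table.select_samples(group_samples)
    rel = relative_abundance(sub)
    n = sub.n_samples
    f_obs = (sub.counts > 0).sum(axis=1) / n
    mean_rel = rel.mean(axis=1)
    keep = mean_rel > 0
    return GroupProfile(
        asv_ids=[a for a, k in zip(sub.asv_ids, keep) if k],
        f_obs=f_obs[keep],
        mean_log_abund=np.log10(mean_rel[keep]),
        n_samples=n,
    )


def migration_rate(f_obs, f_pred) -> float:
    """Ratio of observed to predicted occupancy variance terms.

    m = sum_i f_obs_i (1 - f_obs_i) / sum_i f_pred_i (1 - f_pred_i)
    """
    f_obs = np.asarray(f_obs, float)
    f_pred = np.asarray(f_pred, float)
    if f_obs.shape != f_pred.shape:
        raise ValueError("f_obs and f_pred must have the same length")
    for name, v in (("f_obs", f_obs), ("f_pred", f_pred)):
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError(f"{name} entries must lie in [0, 1]")
    denom = float(np.sum(f_pred * (1.0 - f_pred)))
    if denom == 0.0:
        raise ZeroDivisionError(
            "degenerate predicted occupancies: all f_pred in {0, 1}"
        )
    return float(np.sum(f_obs * (1.0 - f_obs))) / denom


@dataclass
class NeutralFitResult:
    """Fitted abundance-occupancy curve for one group.

    Carries the fitted occurrence frequencies, the deviance-based pseudo-R²,
    the migration statistic m, and a pointwise 95% confidence band over an
    abundance grid (computed on the logit scale and back-transformed).
    """

    profile: GroupProfile
    f_pred: np.ndarray
    pseudo_r2: float
    m: float
    band_grid: np.ndarray
    band_fit: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    smoother_spec: dict
    deviance: float
    null_deviance: float
    edf: float
    converged: bool = True

    @property
    def n_asvs(self) -> int:
        return self.profile.n_asvs

    def to_dataframe(self) -> pd.DataFrame:
        """Per-ASV export (abundance, observed and fitted occupancy)."""
        df = self.profile.to_dataframe()
        df["f_pred"] = self.f_pred
        return df

    def band_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_log_abund": self.band_grid,
                "f_fit": self.band_fit,
                "band_lower": self.band_lower,
                "band_upper": self.band_upper,
            }
        )

    def summary(self) -> str:
        spec = self.smoother_spec
        lines = [
            "Neutral abundance-occupancy fit (binomial GAM, logit link)",
            "=" * 58,
            f"ASVs:                 {self.n_asvs}",
            f"samples in group:     {self.profile.n_samples}",
            f"basis dim (k):        {spec['k']}",
            f"penalty alpha (GCV):  {spec['alpha']:.4g}",
            f"effective df:         {self.edf:.2f}",
            f"null deviance:        {self.null_deviance:.2f}",
            f"residual deviance:    {self.deviance:.2f}",
            f"pseudo R2:            {self.pseudo_r2:.4f}",
            f"migration rate m:     {self.m:.4f}",
        ]
        return "\n".join(lines)


class NeutralOccupancyGAM:
    """Penalized binomial spline regression of occupancy on log abundance.

    Parameters
    ----------
    profile : GroupProfile
        Per-ASV occupancy (out of ``n_samples``) and log10 mean relative
        abundance for one host group.
    k : int
        Spline basis dimension (cubic B-splines).  Reduced with a warning if
        the group has fewer unique abundance values than basis functions.
    alpha : float, optional
        Smoothing penalty.  If None (default) it is selected by generalized
        cross-validation over ``alpha_grid``.
    """

    def __init__(
        self,
        profile: GroupProfile,
        *,
        k: int = 10,
        alpha: float | None = None,
        alpha_grid=DEFAULT_ALPHA_GRID,
        band_points: int = 100,
    ) -> None:
        if profile.n_asvs < 10:
            raise ValueError(
                f"insufficient data: {profile.n_asvs} ASVs (< 10) in group"
            )
        self.profile = profile
        n_unique = len(np.unique(profile.mean_log_abund))
        k_eff = min(k, max(4, n_unique - 1))
        if k_eff < k:
            warnings.warn(
                f"reducing spline basis from {k} to {k_eff}: "
                f"only {n_unique} unique abundance values",
                stacklevel=2,
            )
        self.k = k_eff
        self.alpha = alpha
        self.alpha_grid = tuple(alpha_grid)
        self.band_points = band_points

    @classmethod
    def from_table(
        cls, table: AsvTable, group_samples, **kwargs
    ) -> "NeutralOccupancyGAM":
        return cls(occurrence_frequency(table, group_samples), **kwargs)

    # ------------------------------------------------------------------
    @staticmethod
    def _edf(gam, res, alpha: float) -> float:
        """Effective df: trace[(X'WX + penalty)^-1 X'WX] at the fitted mu.

        Computed directly — the results object's hat-matrix trace mishandles
        binomial (successes, failures) endog.
        """
        X = gam.exog
        mu = np.asarray(res.fittedvalues, float)
        w = gam.n_trials * mu * (1.0 - mu)
        xtwx = X.T @ (w[:, None] * X)
        pen = gam.penal.penalty_matrix(alpha=[alpha])
        return float(np.trace(np.linalg.solve(xtwx + pen, xtwx)))

    def _gam(self, alpha: float):
        prof = self.profile
        successes = np.rint(prof.f_obs * prof.n_samples).astype(int)
        endog = np.column_stack([successes, prof.n_samples - successes])
        x = prof.mean_log_abund[:, None]
        bs = BSplines(x, df=[self.k], degree=[3], include_intercept=True)
        gam = GLMGam(
            endog, smoother=bs, family=sm.families.Binomial(), alpha=[alpha]
        )
        return gam, bs

    def fit(self) -> NeutralFitResult:
        prof = self.profile
        successes = np.rint(prof.f_obs * prof.n_samples).astype(int)
        if np.ptp(successes) == 0:
            # constant occupancy: the smoother cannot beat the intercept
            return self._fit_intercept_only(successes)
        if self.alpha is None:
            alpha = self._select_alpha_gcv()
        else:
            alpha = float(self.alpha)
        gam, bs = self._gam(alpha)
        res = gam.fit()
        if not res.converged:
            raise RuntimeError(
                "occupancy GAM did not converge "
                f"(alpha={alpha}, k={self.k}, n={prof.n_asvs})"
            )
        f_pred = np.clip(np.asarray(res.fittedvalues, float), 0.0, 1.0)
        pseudo_r2 = 1.0 - res.deviance / res.null_deviance
        m = migration_rate(prof.f_obs, f_pred)

        grid = np.linspace(
            prof.mean_log_abund.min(), prof.mean_log_abund.max(), self.band_points
        )
        X = bs.transform(grid[:, None])
        lin = X @ res.params
        cov = res.cov_params()
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
        band_fit = expit(lin)
        band_lower = expit(lin - 1.96 * se)
        band_upper = expit(lin + 1.96 * se)

        return NeutralFitResult(
            profile=prof,
            f_pred=f_pred,
            pseudo_r2=float(pseudo_r2),
            m=float(m),
            band_grid=grid,
            band_fit=band_fit,
            band_lower=band_lower,
            band_upper=band_upper,
            smoother_spec={
                "basis": "cubic B-spline",
                "k": self.k,
                "alpha": float(alpha),
                "alpha_selection": "gcv_grid" if self.alpha is None else "fixed",
                "link": "logit",
                "family": "binomial",
            },
            deviance=float(res.deviance),
            null_deviance=float(res.null_deviance),
            edf=self._edf(gam, res, alpha),
            converged=bool(res.converged),
        )

    def _fit_intercept_only(self, successes: np.ndarray) -> NeutralFitResult:
        prof = self.profile
        endog = np.column_stack([successes, prof.n_samples - successes])
        glm = sm.GLM(endog, np.ones((prof.n_asvs, 1)), family=sm.families.Binomial())
        res = glm.fit()
        f_hat = float(expit(res.params[0]))
        se = float(np.sqrt(res.cov_params()[0, 0]))
        grid = np.linspace(
            prof.mean_log_abund.min(), prof.mean_log_abund.max(), self.band_points
        )
        f_pred = np.full(prof.n_asvs, f_hat)
        return NeutralFitResult(
            profile=prof,
            f_pred=f_pred,
            pseudo_r2=0.0,
            m=migration_rate(prof.f_obs, f_pred),
            band_grid=grid,
            band_fit=np.full_like(grid, f_hat),
            band_lower=np.full_like(grid, float(expit(res.params[0] - 1.96 * se))),
            band_upper=np.full_like(grid, float(expit(res.params[0] + 1.96 * se))),
            smoother_spec={
                "basis": "intercept-only (constant occupancy)",
                "k": 1,
                "alpha": 0.0,
                "alpha_selection": "degenerate",
                "link": "logit",
                "family": "binomial",
            },
            deviance=float(res.deviance),
            null_deviance=float(res.null_deviance),
            edf=1.0,
            converged=True,
        )

    def _select_alpha_gcv(self) -> float:
        """GCV over the alpha grid: n * deviance / (n - edf)^2."""
        n = self.profile.n_asvs
        best_alpha, best_gcv = None, np.inf
        for alpha in self.alpha_grid:
            gam, _ = self._gam(alpha)
            try:
                res = gam.fit()
            except Exception:  # singular/no-convergence at extreme penalty
                continue
            if not res.converged:
                continue
            edf = self._edf(gam, res, alpha)
            denom = max(n - edf, 1e-8)
            gcv = n * res.deviance / denom**2
            if gcv < best_gcv:
                best_alpha, best_gcv = alpha, gcv
        if best_alpha is None:
            raise RuntimeError("occupancy GAM failed to converge at every alpha")
        return float(best_alpha)


def fit_all_groups(
    table: AsvTable,
    metadata: pd.DataFrame,
    grouping=("host_type", "stage"),
    **fit_kwargs,
) -> dict:
    """Fit the occupancy model for every level combination of ``grouping``.

    Returns a dict mapping group label (e.g. ``"conifer-juvenile"``) to a
    :class:`NeutralFitResult`, or to the raised exception for groups that
    fail (too few ASVs, non-convergence); other groups are still fitted.
    """
    grouping = list(grouping)
    results: dict = {}
    for levels, sub in metadata.groupby(grouping, sort=True):
        if not isinstance(levels, tuple):
            levels = (levels,)
        label = "-".join(str(v) for v in levels)
        samples = [s for s in sub["sample_id"] if s in set(table.sample_ids)]
        try:
            model = NeutralOccupancyGAM.from_table(table, samples, **fit_kwargs)
            results[label] = model.fit()
        except Exception as exc:  # propagate per-group, keep going
            results[label] = exc
    return results
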