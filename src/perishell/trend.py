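"""Centrifugal-gradient analysis via orthogonal polynomial contrasts.

The scientific question: does CVR magnitude recover linearly (or with
higher-order curvature) moving outward from a lesion cluster through its
concentric shells?  Observations are CVR values at ordered spatial
levels (cluster = 0, shells 1..3), repeated within clusters, so the test
is a linear mixed model with a random intercept per cluster and fixed
effects given by orthonormal polynomial contrast scores of the level.
Inference is Wald (normal) on each contrast; a pooled model adds a
group x linear interaction to compare the gradient between cavitation
strata.

With 4 levels only linear, quadratic and cubic trends are estimable; a
quartic contrast would require a fifth level and is rejected with an
explicit message.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["orth_poly", "fit_trend", "CentrifugalTrendModel", "TrendResult",
           "TrendResults"]

_DEGREE_NAMES = ("linear", "quadratic", "cubic", "quartic")
_Z95 = 1.96  # Wald 95% multiplier; results report ci = est +/- 1.96*SE exactly


def orth_poly(n_levels: int, max_degree: int | None = None) -> np.ndarray:
    """Orthonormal polynomial contrast matrix over equally spaced levels.

    Returns an array of shape ``(n_levels - 1, n_levels)`` whose row
    ``d-1`` is the degree-``d`` contrast: rows sum to zero, are pairwise
    orthogonal, and have unit norm.  Signs are fixed so the last element
    of each contrast is positive (the linear contrast is increasing).

    ``max_degree`` must be at most ``n_levels - 1``: a degree-``d``
    polynomial contrast needs at least ``d + 1`` distinct levels.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if max_degree is None:
        max_degree = n_levels - 1
    if max_degree >= n_levels:
        raise ValueError(
            f"degree {max_degree} is not estimable with {n_levels} levels: a "
            f"degree-d contrast requires d+1 levels; at most degree "
            f"{n_levels - 1} is available")
    x = np.arange(n_levels, dtype=float)
    vander = np.vander(x, N=n_levels, increasing=True)
    q, _ = np.linalg.qr(vander)
    contrasts = q[:, 1:max_degree + 1].T
    for row in contrasts:
        if row[-1] < 0:
            row *= -1.0
    return contrasts


@dataclass
class TrendResult:
    """One polynomial contrast estimate from the mixed model."""

    group: str
    degree: str
    contrast_estimate: float
    se: float
    ci95: tuple[float, float]
    z_statistic: float
    p_value: float
    interaction_p: float | None = None  # group x linear term, pooled model
    converged: bool = True
    singular: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        assert lo - 1e-12 <= self.contrast_estimate <= hi + 1e-12


class TrendResults:
    """Results container for :class:`CentrifugalTrendModel`.

    Attributes
    ----------
    results : list of TrendResult
        Per-stratum, per-degree contrast estimates.
    interaction_p : float or None
        Wald p for the group x linear interaction in the pooled model
        (None when only one stratum is present).
    """

    def __init__(self, results: list[TrendResult], interaction_p: float | None,
                 n_levels: int, groups: list[str]):
        self.results = results
        self.interaction_p = interaction_p
        self.n_levels = n_levels
        self.groups = groups

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({"group": r.group, "degree": r.degree,
                         "estimate": r.contrast_estimate, "se": r.se,
                         "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                         "z": r.z_statistic, "p_value": r.p_value,
                         "converged": r.converged, "singular": r.singular})
        df = pd.DataFrame(rows)
        df.attrs["interaction_p"] = self.interaction_p
        return df

    def get(self, group: str, degree: str) -> TrendResult:
        for r in self.results:
            if r.group == group and r.degree == degree:
                return r
        raise KeyError(f"no result for ({group}, {degree})")

    def summary(self) -> str:
        lines = [f"Centrifugal trend analysis ({self.n_levels} ordered levels; "
                 "mixed model, random intercept per cluster, ML, Wald z)",
                 "-" * 78,
                 f"{'group':<14}{'degree':<11}{'estimate':>10}{'se':>9}"
                 f"{'ci95':>22}{'z':>8}{'p':>9}"]
        for r in self.results:
            ci = f"[{r.ci95[0]:+.4f}, {r.ci95[1]:+.4f}]"
            flag = " (singular)" if r.singular else ""
            lines.append(f"{r.group:<14}{r.degree:<11}{r.contrast_estimate:>+10.4f}"
                         f"{r.se:>9.4f}{ci:>22}{r.z_statistic:>8.2f}"
                         f"{_fmt_p(r.p_value):>9}{flag}")
        if self.interaction_p is not None:
            lines.append(f"group x linear interaction p = {_fmt_p(self.interaction_p)}")
        return "\n".join(lines)

    def plot(self, data: pd.DataFrame | None = None, ax=None):
        """Level-profile plot (mean value per level and stratum)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if data is not None:
            for g, sub in data.groupby("group"):
                prof = sub.groupby("level_idx")["value"].mean()
                ax.plot(prof.index, prof.values, marker="o", label=str(g))
            ax.legend()
        ax.set_xlabel("level (0 = cluster, 1..3 = shells)")
        ax.set_ylabel("CVR magnitude")
        return ax


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


class CentrifugalTrendModel:
    """Mixed model for the centrifugal CVR gradient.

    Parameters
    ----------
    data : DataFrame
        Long format with columns ``cluster_id``, ``level_idx`` (ordered
        integers, 0-based or 1-based) and ``value``; optional ``group``
        column giving the cavitation stratum.
    max_degree : int, optional
        Highest polynomial degree to estimate; capped at
        ``n_levels - 1`` with a warning when a higher degree is asked
        for.

    ``fit()`` returns a :class:`TrendResults`.
    """

    REQUIRED = ("cluster_id", "level_idx", "value")

    def __init__(self, data: pd.DataFrame, max_degree: int | None = None):
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValueError(f"data must have a {col!r} column")
        self.data = data.copy()
        if "group" not in self.data.columns:
            self.data["group"] = "all"
        levels = np.sort(self.data["level_idx"].unique())
        self.n_levels = len(levels)
        if self.n_levels < 2:
            raise ValueError("need at least 2 ordered levels")
        per_cluster = self.data.groupby("cluster_id")["level_idx"].nunique()
        if (per_cluster < 2).any():
            bad = per_cluster[per_cluster < 2].index.tolist()
            raise ValueError(f"every cluster must contribute >= 2 levels; offending: {bad}")
        self._level_pos = {lv: i for i, lv in enumerate(levels)}
        cap = self.n_levels - 1
        if max_degree is None:
            max_degree = min(cap, 4)
        elif max_degree > cap:
            warnings.warn(f"degree {max_degree} not estimable with {self.n_levels} "
                          f"levels; capping at {cap}", stacklevel=2)
            max_degree = cap
        self.max_degree = max_degree
        self.contrasts = orth_poly(self.n_levels, max_degree)

    # -- internals -----------------------------------------------------
    def _scores(self, level_idx: pd.Series) -> np.ndarray:
        pos = level_idx.map(self._level_pos).to_numpy()
        return self.contrasts[:, pos].T  # (n_obs, n_degrees)

    def _stratum_design(self, sub: pd.DataFrame):
        """Contrast scores for one stratum, rebuilt on the levels the
        stratum actually contributes (validity rules can drop a level)."""
        levels = np.sort(sub["level_idx"].unique())
        if len(levels) == self.n_levels:
            return self._scores(sub["level_idx"]), self.max_degree
        n_sub = len(levels)
        degree = min(self.max_degree, n_sub - 1)
        contrasts = orth_poly(n_sub, degree)
        pos = {lv: i for i, lv in enumerate(levels)}
        idx = sub["level_idx"].map(pos).to_numpy()
        return contrasts[:, idx].T, degree

    def _fit_one(self, sub: pd.DataFrame, group: str, reml: bool) -> list[TrendResult]:
        import statsmodels.api as sm

        y = sub["value"].to_numpy(dtype=float)
        scores, degree = self._stratum_design(sub)
        X = np.column_stack([np.ones(len(y)), scores])

        # degenerate data (zero residual variance, e.g. noise-free
        # phantoms or all-constant input): the OLS solution is exact and
        # equals the contrast projection
        beta_ols, res_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(res_ols[0]) if len(res_ols) else float(
            np.sum((y - X @ beta_ols) ** 2))
        if sse < 1e-16 * max(1.0, float(np.sum(y ** 2))):
            out = []
            for d in range(degree):
                est = float(beta_ols[d + 1])
                if abs(est) < 1e-12:
                    est, z, p = 0.0, 0.0, 1.0
                else:
                    z, p = float(np.sign(est) * np.inf), 0.0
                out.append(TrendResult(group=group, degree=_DEGREE_NAMES[d],
                                       contrast_estimate=est, se=0.0,
                                       ci95=(est, est), z_statistic=z, p_value=p))
            return out

        model = sm.MixedLM(y, X, groups=sub["cluster_id"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=reml)
        singular = bool(np.asarray(fit.cov_re).min() <= 1e-10)
        out = []
        for d in range(degree):
            est = float(fit.params[d + 1])
            se = float(fit.bse[d + 1])
            z = est / se if se > 0 else 0.0
            from scipy import stats as sps
            p = float(2.0 * sps.norm.sf(abs(z)))
            out.append(TrendResult(group=group, degree=_DEGREE_NAMES[d],
                                   contrast_estimate=est, se=se,
                                   ci95=(est - _Z95 * se, est + _Z95 * se),
                                   z_statistic=z, p_value=p,
                                   converged=bool(fit.converged), singular=singular))
        return out

    def _interaction(self, reml: bool) -> float | None:
        import statsmodels.api as sm
        from scipy import stats as sps

        groups = sorted(self.data["group"].unique())
        if len(groups) < 2:
            return None
        sub = self.data
        y = sub["value"].to_numpy(dtype=float)
        scores = self._scores(sub["level_idx"])
        gind = (sub["group"] == groups[1]).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(y)), scores, gind, gind * scores[:, 0]])

        beta, res_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(res_ols[0]) if len(res_ols) else float(np.sum((y - X @ beta) ** 2))
        if sse < 1e-16 * max(1.0, float(np.sum(y ** 2))):
            return 1.0 if abs(beta[-1]) < 1e-12 else 0.0
        model = sm.MixedLM(y, X, groups=sub["cluster_id"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=reml)
        j = X.shape[1] - 1  # fit.params appends variance components after fixed effects
        est, se = float(fit.params[j]), float(fit.bse[j])
        z = est / se if np.isfinite(se) and se > 0 else 0.0
        return float(2.0 * sps.norm.sf(abs(z)))

    # -- public API ----------------------------------------------------
    def fit(self, reml: bool = False) -> TrendResults:
        """Fit per-stratum mixed models plus the pooled interaction model.

        Maximum likelihood by default so stratum models are comparable;
        pass ``reml=True`` for REML variance estimates.
        """
        groups = sorted(self.data["group"].unique())
        results: list[TrendResult] = []
        for g in groups:
            results.extend(self._fit_one(self.data[self.data["group"] == g], g, reml))
        interaction_p = self._interaction(reml)
        if interaction_p is not None:
            for r in results:
                if r.degree == "linear":
                    r.interaction_p = interaction_p
        return TrendResults(results, interaction_p, self.n_levels, groups)


def fit_trend(data: pd.DataFrame, max_degree: int | None = None,
              reml: bool = False) -> TrendResults:
    """Convenience wrapper: ``CentrifugalTrendModel(data).fit()``."""
    return CentrifugalTrendModel(data, max_degree=max_degree).fit(reml=reml)
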