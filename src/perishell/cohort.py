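"""Per-patient analysis layer.

Covers the cohort statistics around the vessel-cluster sign: interrater
agreement (Cohen's kappa, unweighted or quadratic-weighted, with
large-sample CI), univariable screening of covariates against cluster
presence at p < 0.1, multivariable logistic regression with
variance-inflation-factor handling of collinear covariate pairs, and a
proportional-odds model for the per-patient cluster count with the
"4 or more" top category collapsed.

Model fitting is delegated to statsmodels (Logit, OrderedModel, OLS);
the kappa coefficient and its standard error are computed here since no
installed package provides weighted kappa with a CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KappaResult", "kappa",
    "screen_univariable",
    "EffectEstimate", "CollinearityReport", "vif",
    "LogisticModel", "OrdinalModel", "RegressionResults",
    "fit_logistic", "fit_ordinal",
    "SeparationError",
]

_Z95 = 1.96


class SeparationError(RuntimeError):
    """Perfect separation in a logistic fit: coefficients diverge."""


# ----------------------------------------------------------------------
# interrater agreement
# ----------------------------------------------------------------------

@dataclass
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    weighting: str
    n: int

    def __post_init__(self) -> None:
        assert -1.0 - 1e-9 <= self.kappa <= 1.0 + 1e-9


def _kappa_weights(r: int, weighting: str) -> np.ndarray:
    i = np.arange(r).reshape(-1, 1)
    j = np.arange(r).reshape(1, -1)
    if weighting == "none":
        return (i == j).astype(float)
    if weighting == "quadratic":
        if r == 1:
            return np.ones((1, 1))
        return 1.0 - (i - j) ** 2 / (r - 1) ** 2
    raise ValueError(f"weighting must be 'none' or 'quadratic', got {weighting!r}")


def kappa(table: np.ndarray, weighting: str = "none") -> KappaResult:
    """Cohen's kappa from an R x R rating cross-table.

    kappa = (p_o - p_e) / (1 - p_e) with agreement weights
    w_ij = 1 - (i-j)^2/(R-1)^2 under quadratic weighting (identity
    weights otherwise).  The CI uses the large-sample SE of weighted
    kappa (Fleiss, Cohen & Everitt); the p-value tests kappa = 0 with
    the null-hypothesis SE.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError(f"rating table must be square, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("rating table must be nonnegative")
    n = t.sum()
    if n <= 0:
        raise ValueError("rating table must have a positive total")
    r = t.shape[0]
    w = _kappa_weights(r, weighting)
    p = t / n
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(pi, pj)).sum())
    if pe >= 1.0 - 1e-12:  # e.g. single used category: agreement is trivial
        k = 1.0 if po >= 1.0 - 1e-12 else 0.0
        return KappaResult(kappa=k, se=0.0, ci95=(k, k), p_value=1.0,
                           weighting=weighting, n=int(n))
    k = (po - pe) / (1.0 - pe)

    wbar_i = (w * pj.reshape(1, -1)).sum(axis=1)   # row-margin expected weights
    wbar_j = (w * pi.reshape(-1, 1)).sum(axis=0)
    # SE of the estimate
    term = (w - (wbar_i.reshape(-1, 1) + wbar_j.reshape(1, -1)) * (1.0 - k)) ** 2
    var = (float((p * term).sum()) - (k - pe * (1.0 - k)) ** 2) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    # SE under kappa = 0 for the test
    term0 = (w - (wbar_i.reshape(-1, 1) + wbar_j.reshape(1, -1))) ** 2
    var0 = (float((np.outer(pi, pj) * term0).sum()) - pe ** 2) / (n * (1.0 - pe) ** 2)
    se0 = float(np.sqrt(max(var0, 0.0)))
    if se0 > 0:
        z = k / se0
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p_value = 1.0 if k == 0 else 0.0
    lo = max(-1.0, k - _Z95 * se)
    hi = min(1.0, k + _Z95 * se)
    return KappaResult(kappa=float(k), se=se, ci95=(lo, hi), p_value=p_value,
                       weighting=weighting, n=int(n))


# ----------------------------------------------------------------------
# univariable screening
# ----------------------------------------------------------------------

def _is_categorical(s: pd.Series) -> bool:
    if s.dtype == bool or s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        return True
    return s.nunique() <= 2


def screen_univariable(df: pd.DataFrame, outcome: str = "has_cluster",
                       covariates: list[str] | None = None,
                       alpha: float = 0.1) -> pd.DataFrame:
    """Per-covariate two-group tests against a binary outcome.

    Test menu: Student t for continuous (float) covariates, Mann-Whitney
    U for integer-valued ordinal covariates (counts, scores), Pearson
    chi-square for categorical covariates with Fisher's exact fallback
    on sparse 2x2 tables.  Returns a table flagged at ``p < alpha``
    (default 0.1, the screening threshold used to admit covariates into
    the multivariable model).
    """
    y = df[outcome]
    if y.nunique() < 2:
        raise ValueError("outcome must have 2 classes present")
    y = y.astype(bool)
    if covariates is None:
        covariates = [c for c in df.columns if c != outcome]
    rows = []
    for cov in covariates:
        x = df[cov]
        if x.isna().any():  # complete-case analysis
            keep = x.notna()
            x, yy = x[keep], y[keep]
        else:
            yy = y
        if x.nunique() <= 1:
            rows.append({"term": cov, "test": "constant", "p_value": 1.0})
            continue
        if _is_categorical(x):
            table = pd.crosstab(x, yy).to_numpy()
            expected = stats.contingency.expected_freq(table)
            if table.shape == (2, 2) and (expected < 5).any():
                _, p = stats.fisher_exact(table)
                test = "fisher_exact"
            else:
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
                test = "chi2"
        else:
            a, b = x[yy].to_numpy(float), x[~yy].to_numpy(float)
            if np.issubdtype(x.dtype, np.integer):
                _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                test = "mannwhitneyu"
            else:
                if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                    p, test = 1.0, "t"
                else:
                    _, p = stats.ttest_ind(a, b, equal_var=True)
                    test = "t"
        rows.append({"term": cov, "test": test, "p_value": float(p)})
    out = pd.DataFrame(rows).sort_values("term", kind="stable").reset_index(drop=True)
    out["flagged"] = out["p_value"] < alpha
    return out


# ----------------------------------------------------------------------
# collinearity
# ----------------------------------------------------------------------

@dataclass
class CollinearityReport:
    term: str
    vif: float


def vif(design: pd.DataFrame, on_singular: str = "inf") -> list[CollinearityReport]:
    """Variance inflation factors: VIF_j = 1/(1 - R^2_j) from regressing
    covariate j on the other covariates (with intercept).

    ``on_singular='raise'`` raises on rank-deficient designs;
    the default reports the offending term's VIF as infinity.
    """
    import statsmodels.api as sm

    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 covariates for VIF")
    X = design.to_numpy(dtype=float)
    if len(X) <= len(cols):
        raise ValueError("need n > p observations for VIF")
    out = []
    for j, name in enumerate(cols):
        yj = X[:, j]
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(yj, others).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            if on_singular == "raise":
                raise np.linalg.LinAlgError(
                    f"design is rank deficient: {name} is a linear combination "
                    "of the other covariates")
            v = float("inf")
        else:
            v = float(1.0 / (1.0 - r2))
        out.append(CollinearityReport(term=name, vif=v))
    return out


# ----------------------------------------------------------------------
# regression models
# ----------------------------------------------------------------------

@dataclass
class EffectEstimate:
    term: str
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    coef: float = 0.0
    se: float = 0.0
    scale_note: str = "per unit"
    source_model: str = "full"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        assert lo > 0 and lo - 1e-12 <= self.odds_ratio <= hi + 1e-12


class RegressionResults:
    """OR-style results container with a text ``summary()``."""

    def __init__(self, effects: list[EffectEstimate],
                 collinearity: list[CollinearityReport] | None = None,
                 model_kind: str = "logistic", n: int = 0,
                 notices: list[str] | None = None, llf: float | None = None):
        self.effects = effects
        self.collinearity = collinearity or []
        self.model_kind = model_kind
        self.n = n
        self.notices = notices or []
        self.llf = llf

    def effect(self, term: str) -> EffectEstimate:
        for e in self.effects:
            if e.term == term:
                return e
        raise KeyError(f"no effect for term {term!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"term": e.term, "odds_ratio": e.odds_ratio,
                              "ci_low": e.ci95[0], "ci_high": e.ci95[1],
                              "p_value": e.p_value, "coef": e.coef, "se": e.se,
                              "source_model": e.source_model}
                             for e in self.effects])

    def summary(self) -> str:
        lines = [f"{self.model_kind} regression (n = {self.n}, Wald 95% CI)",
                 "-" * 72,
                 f"{'term':<22}{'OR':>8}{'ci95':>22}{'p':>9}  source"]
        for e in self.effects:
            ci = f"[{e.ci95[0]:.2f}, {e.ci95[1]:.2f}]"
            lines.append(f"{e.term:<22}{e.odds_ratio:>8.2f}{ci:>22}"
                         f"{('<0.001' if e.p_value < 0.001 else f'{e.p_value:.3f}'):>9}"
                         f"  {e.source_model}")
        if self.collinearity:
            vifs = ", ".join(f"{c.term}={c.vif:.2f}" for c in self.collinearity)
            lines.append(f"VIF: {vifs}")
        lines.extend(self.notices)
        return "\n".join(lines)


def _check_separation(params: np.ndarray, mlefit) -> None:
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 15.0:
        raise SeparationError(
            "perfect (or quasi-complete) separation detected: coefficient "
            "estimates diverge; no finite odds ratios exist for this design")


def _wald_effects(params, bse, names, source: str) -> list[EffectEstimate]:
    out = []
    for name, b, s in zip(names, params, bse):
        if name == "const":
            continue
        z = b / s if s > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(EffectEstimate(term=name, odds_ratio=float(np.exp(b)),
                                  ci95=(float(np.exp(b - _Z95 * s)),
                                        float(np.exp(b + _Z95 * s))),
                                  p_value=p, coef=float(b), se=float(s),
                                  source_model=source))
    return out


class LogisticModel:
    """Multivariable logistic regression for vessel-cluster presence.

    Statsmodels-style: construct from a patient table and term list,
    ``fit()`` returns :class:`RegressionResults` with odds ratios, Wald
    CIs, a VIF report, and the collinear-pair handling described below.

    Collinearity policy: covariate pairs whose VIF exceeds
    ``vif_threshold`` are both retained in the full model (their mutual
    adjustment is wanted when estimating *other* terms), but each member's
    own effect is re-estimated from a reduced model that drops its
    high-VIF partners.  Missing covariate values are handled by
    complete-case analysis.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, terms: list[str],
                 vif_threshold: float = 5.0):
        self.terms = list(terms)
        cols = [outcome] + self.terms
        self.data = data[cols].dropna()
        self.outcome = outcome
        self.vif_threshold = vif_threshold

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, terms: list[str],
                       **kw) -> "LogisticModel":
        return cls(data, outcome, terms, **kw)

    def _design(self, terms: list[str]) -> pd.DataFrame:
        X = pd.get_dummies(self.data[terms], drop_first=True)
        return X.astype(float)

    def _fit_core(self, terms: list[str], source: str):
        import statsmodels.api as sm

        X = self._design(terms)
        y = self.data[self.outcome].astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
            except np.linalg.LinAlgError as exc:
                # diverging coefficients make the Hessian numerically singular
                raise SeparationError(
                    f"logistic fit failed ({exc}); this is typically perfect "
                    "separation or a rank-deficient design") from exc
            except Exception as exc:  # statsmodels PerfectSeparationError et al.
                if "separation" in str(exc).lower() or "Perfect" in type(exc).__name__:
                    raise SeparationError(str(exc)) from exc
                raise
        params = np.asarray(fit.params)
        _check_separation(params, fit)
        names = list(sm.add_constant(X).columns)
        return fit, _wald_effects(np.asarray(fit.params), np.asarray(fit.bse),
                                  names, source)

    def fit(self) -> RegressionResults:
        fit_full, effects_full = self._fit_core(self.terms, "full")
        X = self._design(self.terms)
        vif_report = vif(X) if X.shape[1] >= 2 else []
        high = {c.term for c in vif_report if c.vif > self.vif_threshold}
        notices = []
        effects = {e.term: e for e in effects_full}
        for term_col in sorted(high):
            # map the design column back to its source term
            src_terms = [t for t in self.terms if term_col == t or term_col.startswith(t + "_")]
            partners = [t for t in self.terms
                        if any(h != term_col and (h == t or h.startswith(t + "_"))
                               for h in high)]
            reduced = [t for t in self.terms if t not in partners or t in src_terms]
            if set(reduced) == set(self.terms):
                continue
            _, eff_red = self._fit_core(reduced, f"reduced (drops {sorted(set(partners) - set(src_terms))})")
            for e in eff_red:
                if e.term == term_col:
                    effects[term_col] = e
            notices.append(
                f"high VIF for {term_col}: own effect re-estimated excluding its "
                f"collinear partner(s); partners retained in the full model for "
                f"other terms' adjustment")
        ordered = [effects[e.term] for e in effects_full]
        return RegressionResults(ordered, vif_report, "logistic",
                                 n=len(self.data), notices=notices,
                                 llf=float(fit_full.llf))


class OrdinalModel:
    """Proportional-odds model for the per-patient vessel-cluster count.

    Counts at or above ``collapse_at`` (default 4, i.e. "4 or more") are
    collapsed into one top category before fitting.  With fewer than 3
    categories after collapsing the model falls back to logistic
    regression with a warning.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, terms: list[str],
                 collapse_at: int = 4):
        self.data = data[[outcome] + list(terms)].dropna()
        self.outcome = outcome
        self.terms = list(terms)
        self.collapse_at = collapse_at

    @classmethod
    def from_dataframe(cls, data, outcome, terms, **kw) -> "OrdinalModel":
        return cls(data, outcome, terms, **kw)

    def fit(self) -> RegressionResults:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y = self.data[self.outcome].clip(upper=self.collapse_at)
        n_cat = y.nunique()
        if n_cat < 3:
            warnings.warn("fewer than 3 outcome categories after collapsing; "
                          "falling back to logistic regression", stacklevel=2)
            df = self.data.assign(_binary=(y == y.max()).astype(int))
            res = LogisticModel(df, "_binary", self.terms).fit()
            res.model_kind = "logistic (ordinal fallback)"
            return res
        X = pd.get_dummies(self.data[self.terms], drop_first=True).astype(float)
        y_ord = pd.Categorical(y, categories=np.sort(y.unique()), ordered=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(y_ord, X, distr="logit")
            fit = model.fit(method="bfgs", disp=0, maxiter=500)
        k = X.shape[1]
        params = np.asarray(fit.params)[:k]
        bse = np.asarray(fit.bse)[:k]
        _check_separation(params, fit)
        effects = _wald_effects(params, bse, list(X.columns), "proportional-odds")
        return RegressionResults(effects, [], "proportional-odds", n=len(self.data),
                                 llf=float(fit.llf))


def fit_logistic(data: pd.DataFrame, outcome: str, terms: list[str],
                 vif_threshold: float = 5.0) -> RegressionResults:
    """Convenience wrapper over :class:`LogisticModel`."""
    return LogisticModel(data, outcome, terms, vif_threshold=vif_threshold).fit()


def fit_ordinal(data: pd.DataFrame, outcome: str, terms: list[str],
                collapse_at: int = 4) -> RegressionResults:
    """Convenience wrapper over :class:`OrdinalModel`."""
    return OrdinalModel(data, outcome, terms, collapse_at=collapse_at).fit()
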