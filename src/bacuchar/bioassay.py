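"""Dose-mortality and time-mortality statistics for droplet-feeding
bioassays.

Dose-mortality data (k doses, n larvae per dose, observed deaths) are fit
by maximum-likelihood probit regression on x = log10(dose),

    p(x) = C + (1 - C) * Phi(alpha + beta * x),

with natural (control) mortality C fixed at 0 by default.  The median
lethal concentration is LC50 = 10^(-alpha/beta) and its 95% fiducial
limits come from Fieller's theorem on the ratio -alpha/beta, with the
covariance matrix inflated by the heterogeneity factor h = chi2/(k-2) and
a t quantile on k-2 degrees of freedom whenever the Pearson chi-square
exceeds its 5% critical value (the classic Finney/PoloPlus convention).
Parallelism (common slope) and equality (common slope and intercept) of
several dose-response lines are tested by likelihood ratio.

Median lethal times are estimated from death times of responding larvae
only ("survivors excluded"): with no censoring the Kaplan-Meier curve is
the empirical survival function, LT50 is the first observation time where
S(t) <= 0.5, and the 95% CI inverts the log-log Greenwood band
(Brookmeyer-Crowley).  Groups are compared with the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

__all__ = [
    "DoseResponseData",
    "ProbitDoseResponse",
    "ProbitResults",
    "SeparationError",
    "LineComparison",
    "SurvivalEstimate",
    "fit_probit",
    "lc50_fiducial",
    "compare_probit_lines",
    "km_lt50",
    "logrank_test",
    "letter_groups",
]


class SeparationError(ValueError):
    """All-or-nothing mortality at every dose: the probit MLE is infinite."""


@dataclass(frozen=True)
class DoseResponseData:
    """Grouped dose-mortality counts for one treatment."""

    dose: tuple[float, ...]
    n: tuple[int, ...]
    dead: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not (len(self.dose) == len(self.n) == len(self.dead)):
            raise ValueError("dose, n and dead must have equal length")
        if any(d <= 0 for d in self.dose):
            raise ValueError("doses must be positive")
        if any(k < 0 or k > m for k, m in zip(self.dead, self.n)):
            raise ValueError("dead counts must lie in [0, n]")
        if len(set(self.dose)) < 3:
            raise ValueError("need at least 3 distinct doses to fit")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "DoseResponseData":
        return cls(dose=tuple(df["dose"].astype(float)),
                   n=tuple(df["n"].astype(int)),
                   dead=tuple(df["dead"].astype(int)),
                   label=label or str(df.get("group", pd.Series([""])).iloc[0]))

    @property
    def log10_dose(self) -> np.ndarray:
        return np.log10(np.asarray(self.dose, dtype=float))


def _probit_loglik(params: np.ndarray, x: np.ndarray, n: np.ndarray,
                   dead: np.ndarray, natural: float) -> float:
    a, b = params
    p = natural + (1.0 - natural) * stats.norm.cdf(a + b * x)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(np.sum(dead * np.log(p) + (n - dead) * np.log1p(-p)))


def _newton_probit(x: np.ndarray, n: np.ndarray, dead: np.ndarray,
                   natural: float, tol: float = 1e-10,
                   max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson ML probit; returns (params, observed-information
    covariance)."""
    obs = dead / n
    # starting values from an unweighted regression of empirical probits
    z = stats.norm.ppf(np.clip((obs - natural) / max(1 - natural, 1e-9),
                               0.02, 0.98))
    b0, a0 = np.polyfit(x, z, 1)
    if not np.isfinite(b0) or b0 == 0:
        a0, b0 = 0.0, 1.0
    params = np.array([a0, b0], dtype=float)
    for _ in range(max_iter):
        a, b = params
        eta = a + b * x
        phi = stats.norm.pdf(eta)
        Phi = stats.norm.cdf(eta)
        p = natural + (1.0 - natural) * Phi
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        dp = (1.0 - natural) * phi  # dp/deta
        w = dp / (p * (1.0 - p))
        resid = dead - n * p
        score = np.array([np.sum(w * resid),
                          np.sum(w * resid * x)])
        # expected (Fisher) information
        info_w = n * dp * dp / (p * (1.0 - p))
        info = np.array([[np.sum(info_w), np.sum(info_w * x)],
                         [np.sum(info_w * x), np.sum(info_w * x * x)]])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix; no finite "
                                  "probit MLE") from exc
        # step halving to keep the log-likelihood increasing
        ll0 = _probit_loglik(params, x, n, dead, natural)
        scale = 1.0
        for _ in range(30):
            trial = params + scale * step
            if _probit_loglik(trial, x, n, dead, natural) >= ll0 - 1e-12:
                break
            scale /= 2.0
        new = params + scale * step
        if np.max(np.abs(new - params) / np.maximum(np.abs(params), 1.0)) < tol:
            params = new
            break
        params = new
    else:
        raise SeparationError("probit fit did not converge; the data may "
                              "show complete separation")
    a, b = params
    eta = a + b * x
    phi = stats.norm.pdf(eta)
    Phi = stats.norm.cdf(eta)
    p = np.clip(natural + (1.0 - natural) * Phi, 1e-12, 1 - 1e-12)
    info_w = n * ((1 - natural) * phi) ** 2 / (p * (1.0 - p))
    info = np.array([[np.sum(info_w), np.sum(info_w * x)],
                     [np.sum(info_w * x), np.sum(info_w * x * x)]])
    cov = np.linalg.inv(info)
    return params, cov


@dataclass
class ProbitDoseResponse:
    """Probit dose-mortality model for one treatment group.

    Follows the model/results idiom: construct from data (or a DataFrame
    with columns dose, n, dead), call :meth:`fit`, and read estimates off
    the returned :class:`ProbitResults`.
    """

    data: DoseResponseData
    natural_response: float = 0.0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "",
                       natural_response: float = 0.0) -> "ProbitDoseResponse":
        return cls(DoseResponseData.from_dataframe(df, label=label),
                   natural_response=natural_response)

    def fit(self, tol: float = 1e-10) -> "ProbitResults":
        d = self.data
        if all(k == 0 or k == m for k, m in zip(d.dead, d.n)):
            raise SeparationError(
                "every dose shows 0% or 100% mortality; no finite MLE"
            )
        x = d.log10_dose
        n = np.asarray(d.n, dtype=float)
        dead = np.asarray(d.dead, dtype=float)
        if not np.all(np.diff(dead[np.argsort(x)] / n[np.argsort(x)]) >= -0.5):
            pass  # grossly non-monotone data still fit, by design
        params, cov = _newton_probit(x, n, dead, self.natural_response,
                                     tol=tol)
        a, b = params
        eta = a + b * x
        p = np.clip(self.natural_response
                    + (1 - self.natural_response) * stats.norm.cdf(eta),
                    1e-12, 1 - 1e-12)
        expected = n * p
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = float(np.sum((dead - expected) ** 2
                                / (n * p * (1.0 - p))))
        df_het = len(d.dose) - 2
        h = chi2 / df_het if df_het > 0 else np.nan
        heterogeneous = (df_het > 0
                         and chi2 > stats.chi2.ppf(0.95, df_het))
        if heterogeneous:
            cov = cov * h
        loglik = _probit_loglik(params, x, n, dead, self.natural_response)
        return ProbitResults(
            model=self, alpha=float(a), beta=float(b), cov=cov,
            chi2=chi2, df_het=df_het, heterogeneity=float(h),
            heterogeneous=heterogeneous, loglik=float(loglik),
        )


@dataclass
class ProbitResults:
    """Estimates, uncertainty and diagnostics from a probit fit."""

    model: ProbitDoseResponse
    alpha: float
    beta: float
    cov: np.ndarray
    chi2: float
    df_het: int
    heterogeneity: float
    heterogeneous: bool
    loglik: float
    _fid_cache: dict = field(default_factory=dict, repr=False)

    @property
    def se_alpha(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def se_beta(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    @property
    def log10_lc50(self) -> float:
        return -self.alpha / self.beta

    @property
    def lc50(self) -> float:
        """Median lethal concentration, in the units of the input doses."""
        return float(10.0 ** self.log10_lc50)

    @property
    def g(self) -> float:
        """Fieller's g at the 95% level (interval unbounded when g >= 1)."""
        t = self._quantile(0.95)
        return float(t * t * self.cov[1, 1] / (self.beta * self.beta))

    def _quantile(self, level: float) -> float:
        if self.heterogeneous and self.df_het > 0:
            return float(stats.t.ppf(0.5 + level / 2.0, self.df_het))
        return float(stats.norm.ppf(0.5 + level / 2.0))

    def fiducial_limits(self, level: float = 0.95) -> tuple[float, float]:
        """Fieller fiducial limits for LC50, back-transformed to dose units.

        Raises ``ValueError`` when g >= 1 (the fiducial set is unbounded);
        the condition is reported, never silently truncated.
        """
        if level in self._fid_cache:
            return self._fid_cache[level]
        if self.beta == 0:
            raise ValueError("zero slope: LC50 undefined")
        t = self._quantile(level)
        v11 = float(self.cov[0, 0])
        v12 = float(self.cov[0, 1])
        v22 = float(self.cov[1, 1])
        b = self.beta
        m = self.log10_lc50
        g = t * t * v22 / (b * b)
        if v11 == v12 == v22 == 0.0:
            return (self.lc50, self.lc50)
        if g >= 1.0:
            raise ValueError(
                f"Fieller g = {g:.3f} >= 1: fiducial limits are unbounded"
            )
        # ratio -alpha/beta: numerator N = -alpha, Cov(N, beta) = -v12
        cov_nd = -v12
        var_n = v11
        disc = (var_n - 2.0 * m * cov_nd + m * m * v22
                - g * (var_n - cov_nd * cov_nd / v22))
        half = (t / abs(b)) * np.sqrt(max(disc, 0.0))
        centre = m - g * cov_nd / v22
        lo = (centre - half) / (1.0 - g)
        hi = (centre + half) / (1.0 - g)
        out = (float(10.0 ** lo), float(10.0 ** hi))
        self._fid_cache[level] = out
        return out

    def summary(self) -> pd.DataFrame:
        lo, hi = (np.nan, np.nan)
        try:
            lo, hi = self.fiducial_limits()
        except ValueError:
            pass
        return pd.DataFrame({
            "group": [self.model.data.label],
            "lc50": [self.lc50],
            "fiducial_lower": [lo],
            "fiducial_upper": [hi],
            "slope": [self.beta],
            "se_slope": [self.se_beta],
            "intercept": [self.alpha],
            "chi2": [self.chi2],
            "heterogeneity": [self.heterogeneity],
            "g": [self.g],
        })


def fit_probit(data: DoseResponseData,
               natural_response: float = 0.0) -> ProbitResults:
    """Functional wrapper: fit a probit dose-response model."""
    return ProbitDoseResponse(data, natural_response=natural_response).fit()


def lc50_fiducial(fit: ProbitResults, level: float = 0.95
                  ) -> tuple[float, float]:
    """Fieller fiducial limits of the LC50 (dose units)."""
    return fit.fiducial_limits(level)


def _common_slope_loglik(datasets: Sequence[DoseResponseData],
                         equal_intercept: bool) -> float:
    """Exact ML log-likelihood of the parallel (common slope, free
    intercepts) or equal (one line for all groups) probit model, fitted
    as a probit GLM with group dummies."""
    import statsmodels.api as sm

    x = np.concatenate([d.log10_dose for d in datasets])
    n = np.concatenate([np.asarray(d.n, float) for d in datasets])
    dead = np.concatenate([np.asarray(d.dead, float) for d in datasets])
    if equal_intercept:
        X = np.column_stack([np.ones_like(x), x])
    else:
        blocks = []
        for i, d in enumerate(datasets):
            col = np.zeros_like(x)
            lo = sum(len(dd.dose) for dd in datasets[:i])
            col[lo:lo + len(d.dose)] = 1.0
            blocks.append(col)
        X = np.column_stack(blocks + [x])
    glm = sm.GLM(np.column_stack([dead, n - dead]), X,
                 family=sm.families.Binomial(sm.families.links.Probit()))
    res = glm.fit(maxiter=200, tol=1e-10)
    params = np.asarray(res.params)
    # evaluate the binomial log-likelihood on the original scale
    eta = X @ params
    p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(dead * np.log(p) + (n - dead) * np.log1p(-p)))


@dataclass(frozen=True)
class LineComparison:
    hypothesis: str
    lr_statistic: float
    df: int
    p_value: float
    letters: dict[str, str]


def letter_groups(labels: Sequence[str], ranking: Sequence[float],
                  differs: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display: groups that do not differ pairwise share a
    letter, assigned greedily in ranking order (descending)."""
    order = [l for _, l in sorted(zip(ranking, labels), reverse=True)]
    letters: dict[str, str] = {l: "" for l in labels}
    next_letter = 0
    clusters: list[list[str]] = []
    for label in order:
        placed = False
        for cluster in clusters:
            if all(not differs.get(tuple(sorted((label, other))), False)
                   for other in cluster):
                cluster.append(label)
                placed = True
                break
        if not placed:
            clusters.append([label])
    for cluster in clusters:
        ch = chr(ord("a") + next_letter)
        next_letter += 1
        for label in cluster:
            letters[label] += ch
    return letters


def compare_probit_lines(datasets: Sequence[DoseResponseData],
                         alpha_level: float = 0.05) -> list[LineComparison]:
    """Likelihood-ratio tests of parallelism and equality of probit lines.

    Parallelism: common slope vs free slopes (df = k - 1).  Equality:
    common intercept and slope vs free (df = 2(k - 1)).  Letters mark
    groups whose LC50s do not differ in pairwise equality tests at
    ``alpha_level``; any group that cannot be fitted individually is
    excluded with a diagnostic.
    """
    usable = []
    for d in datasets:
        try:
            fit_probit(d)
            usable.append(d)
        except (SeparationError, ValueError) as exc:
            import logging
            logging.getLogger(__name__).warning(
                "group %s excluded from line comparison: %s", d.label, exc)
    if len(usable) < 2:
        raise ValueError("need at least two fittable groups")
    k = len(usable)
    free_ll = sum(fit_probit(d).loglik for d in usable)
    par_ll = _common_slope_loglik(usable, equal_intercept=False)
    eq_ll = _common_slope_loglik(usable, equal_intercept=True)
    lr_par = max(0.0, 2.0 * (free_ll - par_ll))
    lr_eq = max(0.0, 2.0 * (free_ll - eq_ll))
    p_par = float(stats.chi2.sf(lr_par, k - 1))
    p_eq = float(stats.chi2.sf(lr_eq, 2 * (k - 1)))

    labels = [d.label or f"group{i}" for i, d in enumerate(usable)]
    lc50s = [fit_probit(d).lc50 for d in usable]
    differs: dict[tuple[str, str], bool] = {}
    for i in range(k):
        for j in range(i + 1, k):
            pair = [usable[i], usable[j]]
            ll_free = sum(fit_probit(d).loglik for d in pair)
            ll_eq = _common_slope_loglik(pair, equal_intercept=True)
            lr = max(0.0, 2.0 * (ll_free - ll_eq))
            p = float(stats.chi2.sf(lr, 2))
            key = tuple(sorted((labels[i], labels[j])))
            differs[key] = p < alpha_level
    letters = letter_groups(labels, lc50s, differs)
    return [
        LineComparison("parallelism", lr_par, k - 1, p_par, letters),
        LineComparison("equality", lr_eq, 2 * (k - 1), p_eq, letters),
    ]


@dataclass(frozen=True)
class SurvivalEstimate:
    """Kaplan-Meier estimate of the death-time distribution (no censoring:
    survivors were excluded before estimation)."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    lt50: float
    ci95: tuple[float, float]
    n_dead: int
    n_excluded_survivors: int

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_lt50(death_times: Sequence[float],
            n_excluded_survivors: int = 0) -> SurvivalEstimate:
    """Median lethal time from death times of responders only.

    With survivors excluded there is no censoring, so the Kaplan-Meier
    curve coincides with the empirical survival function; LT50 is the
    first observed time where S(t) <= 0.5 and the 95% CI inverts the
    log-log Greenwood confidence band (Brookmeyer-Crowley).
    """
    times = np.asarray(list(death_times), dtype=float)
    if times.size == 0:
        raise ValueError("no death times supplied")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=np.ones_like(times))
    lt50 = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo = float(ci.iloc[0, 0])
    hi = float(ci.iloc[0, 1])
    sf = kmf.survival_function_
    grid = [float(t) for t in sf.index if t > 0]
    surv = [float(sf.loc[t].iloc[0]) for t in sf.index if t > 0]
    return SurvivalEstimate(
        times=tuple(grid), survival=tuple(surv), lt50=lt50,
        ci95=(lo, hi), n_dead=int(times.size),
        n_excluded_survivors=n_excluded_survivors,
    )


def logrank_test(groups: dict[str, Sequence[float]],
                 alpha_level: float = 0.05
                 ) -> tuple[float, int, float, dict[str, str]]:
    """Log-rank comparison of death-time distributions.

    Returns (chi2, df, p, letters); letters come from pairwise log-rank
    tests at ``alpha_level`` with groups ranked by median death time.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = list(groups)
    durations = np.concatenate([np.asarray(list(groups[l]), float)
                                for l in labels])
    if durations.size == 0 or any(len(list(groups[l])) == 0 for l in labels):
        raise ValueError("every group must contain at least one death time")
    membership = np.concatenate([
        np.full(len(list(groups[l])), i) for i, l in enumerate(labels)
    ])
    res = multivariate_logrank_test(durations, membership,
                                    np.ones_like(durations))
    chi2 = float(res.test_statistic)
    df = len(labels) - 1
    p = float(res.p_value)
    differs: dict[tuple[str, str], bool] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = np.asarray(list(groups[labels[i]]), float)
            b = np.asarray(list(groups[labels[j]]), float)
            pr = _ll_logrank(a, b, event_observed_A=np.ones_like(a),
                             event_observed_B=np.ones_like(b))
            key = tuple(sorted((labels[i], labels[j])))
            differs[key] = float(pr.p_value) < alpha_level
    medians = [float(np.median(np.asarray(list(groups[l])))) for l in labels]
    letters = letter_groups(labels, medians, differs)
    return chi2, df, p, letters
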