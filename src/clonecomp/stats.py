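"""Cohort-level statistics: exact contingency tests, rank tests,
Kaplan-Meier / log-rank, Cox regression and the Schoenfeld minimum
detectable hazard ratio.

The two-sided Fisher rule is the probability-mass convention: sum the
probabilities of all fixed-margin tables no more probable than the
observed one (relative tolerance 1e-7). For r x c tables this is the
Freeman-Halton generalization by full enumeration. No multiple-testing
correction is applied anywhere; p < 0.05 is the significance convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .datatypes import CohortTable

_REL_TOL = 1.0 + 1e-7


@dataclass
class ContingencyTable:
    """r x c nonnegative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("need at least a 2x2 table")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=1) == 0).any() or (self.counts.sum(axis=0) == 0).any():
            raise ValueError("empty row or column margin")


def _table_logp(table: np.ndarray) -> float:
    """log multivariate hypergeometric probability under fixed margins."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_margins, col_margins):
    """Yield every nonnegative integer table with the given margins."""
    r, c = len(row_margins), len(col_margins)

    def rec(i, remaining_cols, rows):
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all() and last.sum() == row_margins[-1]:
                yield np.vstack(rows + [last])
            return
        target = row_margins[i]

        def fill(j, left, row):
            if j == c - 1:
                if 0 <= left <= remaining_cols[-1]:
                    yield row + [left]
                return
            for v in range(0, min(left, remaining_cols[j]) + 1):
                yield from fill(j + 1, left - v, row + [v])

        for row in fill(0, target, []):
            yield from rec(i + 1, [rc - rv for rc, rv in zip(remaining_cols, row)],
                           rows + [np.asarray(row)])

    yield from rec(0, list(col_margins), [])


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p (2x2) / Freeman-Halton p (r x c).

    Probability-mass rule: p is the total probability of fixed-margin
    tables whose probability is <= the observed one (x (1 + 1e-7)).
    """
    ct = table if isinstance(table, ContingencyTable) else ContingencyTable(np.asarray(table))
    counts = ct.counts
    if counts.shape == (2, 2):
        return float(sps.fisher_exact(counts, alternative="two-sided")[1])
    n = int(counts.sum())
    if n > 200:
        raise ValueError("exact enumeration limited to tables with total <= 200")
    logp_obs = _table_logp(counts)
    cutoff = logp_obs + math.log(_REL_TOL)
    row_m, col_m = counts.sum(axis=1), counts.sum(axis=0)
    p = 0.0
    for t in _enumerate_tables(list(row_m), list(col_m)):
        lp = _table_logp(t)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(p, 1.0)


@dataclass
class CountSummary:
    mean: float
    sd_sample: float      # n-1 denominator
    sd_population: float  # n denominator
    median: float
    min: float
    max: float
    n: int


def summarize_counts(distribution: dict) -> CountSummary:
    """Summarize a value -> count map (e.g. a CC-number histogram).

    Both SD conventions are reported because printed tables rarely say
    which denominator they used.
    """
    if not distribution:
        raise ValueError("empty distribution")
    values = np.repeat(
        np.fromiter(distribution.keys(), dtype=float),
        np.fromiter(distribution.values(), dtype=int),
    )
    return CountSummary(
        mean=float(values.mean()),
        sd_sample=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        sd_population=float(values.std(ddof=0)),
        median=float(np.median(values)),
        min=float(values.min()),
        max=float(values.max()),
        n=len(values),
    )


def _u_statistic(x, y):
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration over all group assignments when n1+n2 <= 20 (valid
    under ties); otherwise normal approximation with midranks,
    tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= 20:
        from itertools import combinations

        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        total = 0
        extreme = 0
        d_obs = abs(u_obs - mu)
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= d_obs - 1e-12:
                extreme += 1
        return extreme / total
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    return min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))


def kruskal_wallis(groups) -> float:
    """Kruskal-Wallis H-test p across >= 2 groups (tie-corrected)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    return float(sps.kruskal(*groups)[1])


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p); raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class SurvivalSample:
    """Right-censored survival data: times (days), event flags, group labels."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if (self.time < 0).any():
            raise ValueError("negative survival time")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event flags must be 0/1")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if len(self.group) != len(self.time):
                raise ValueError("group length mismatch")


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray    # Greenwood

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function starting at 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(sample: SurvivalSample) -> KMCurve:
    """Kaplan-Meier product-limit estimator (one group)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(sample.time, sample.event)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    times = tab.index.to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n)
    green = surv**2 * np.cumsum(d / (n * (n - d)))
    return KMCurve(times=times, survival=surv, at_risk=n, n_events=d, variance=green)


def logrank(sample: SurvivalSample) -> float:
    """Log-rank test p across the sample's groups (chi-square, k-1 df)."""
    if sample.group is None:
        raise ValueError("log-rank needs group labels")
    labels = np.unique(sample.group)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    for g in labels:
        if (sample.group == g).sum() == 0:
            raise ValueError(f"group {g} has zero subjects")
    if sample.event.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(sample.time, sample.group, sample.event)
    return float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Efron tie handling, Wald CIs)."""

    covariates: list[str]
    log_hr: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray   # 95% on the HR scale
    ci_high: np.ndarray
    p: np.ndarray
    converged: bool = True
    diagnostic: str = ""

    def __post_init__(self) -> None:
        if self.converged and not (
            (self.ci_low <= self.hr + 1e-12).all() and (self.hr <= self.ci_high + 1e-12).all()
        ):
            raise ValueError("confidence interval does not bracket the estimate")


def cox_fit(df: pd.DataFrame | CohortTable, duration_col: str, event_col: str,
            covariates: list[str], strata: list[str] | None = None) -> CoxFit:
    """Univariate/multivariable Cox PH fit via partial likelihood.

    Efron approximation for tied event times; monotone likelihood
    (perfect separation) is flagged as non-convergence rather than
    silently reported.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    data = df.df if isinstance(df, CohortTable) else df
    cols = [duration_col, event_col] + covariates + list(strata or [])
    data = data[cols].copy()
    if data[event_col].sum() < 1:
        raise ValueError("need at least one event")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col, strata=strata)
    except ConvergenceError as exc:
        return CoxFit(
            covariates=covariates,
            log_hr=np.full(len(covariates), np.nan),
            hr=np.full(len(covariates), np.nan),
            ci_low=np.full(len(covariates), np.nan),
            ci_high=np.full(len(covariates), np.nan),
            p=np.full(len(covariates), np.nan),
            converged=False,
            diagnostic=f"partial likelihood did not converge: {exc}",
        )
    summ = cph.summary
    return CoxFit(
        covariates=list(summ.index),
        log_hr=summ["coef"].to_numpy(),
        hr=summ["exp(coef)"].to_numpy(),
        ci_low=summ["exp(coef) lower 95%"].to_numpy(),
        ci_high=summ["exp(coef) upper 95%"].to_numpy(),
        p=summ["p"].to_numpy(),
    )


def min_detectable_hr(n1: int, n2: int, n_events: int, power: float = 0.8,
                      alpha: float = 0.05) -> float:
    """Schoenfeld minimum detectable hazard ratio for a two-group design.

    ``HR = exp((z_{1-alpha/2} + z_power) / sqrt(D * p * (1 - p)))`` with
    ``p = n1/(n1+n2)`` and D the number of events.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    p = n1 / (n1 + n2)
    z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
    return float(math.exp(z / math.sqrt(n_events * p * (1 - p))))


def compare_groups(cohort: CohortTable, group_col: str = "cc_class",
                   categorical: list[str] | None = None,
                   numeric: list[str] | None = None) -> pd.DataFrame:
    """Table-1-style group comparison: Fisher exact for categorical
    covariates, Kruskal-Wallis for numeric ones."""
    df = cohort.df
    groups = sorted(df[group_col].dropna().unique())
    rows = []
    for col in categorical or []:
        sub = df[[group_col, col]].dropna()
        tab = pd.crosstab(sub[col], sub[group_col])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue
        rows.append({"covariate": col, "test": "fisher", "p": fisher_exact(tab.to_numpy())})
    for col in numeric or []:
        vals = [df.loc[df[group_col] == g, col].dropna().to_numpy() for g in groups]
        if any(len(v) == 0 for v in vals):
            continue
        rows.append({"covariate": col, "test": "kruskal", "p": kruskal_wallis(vals)})
    return pd.DataFrame(rows)
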