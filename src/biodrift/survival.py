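"""Downstream clinical-utility evaluation of a biomarker panel.

Each candidate gene is screened with a univariate Cox proportional-hazards
fit against overall survival; genes passing |beta| > 0.2 and p < 0.01 form
a risk score  score = sum_i exp_i * beta_i  per patient. Splitting patients
at the median score defines high- and low-risk groups whose Kaplan-Meier
curves are compared with the two-group log-rank test.

The univariate Cox fit is a 1-D Newton maximization of the partial
likelihood with Breslow handling of ties; the Wald statistic (beta/se)^2
against chi-square(1) gives the p-value. Kaplan-Meier estimation and the
log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import chi2

from .features import FeatureSet
from .synthetic import SurvivalTable

_BETA_CAP = 10.0  # monotone-likelihood guard: |beta| capped here


@dataclass
class CoxResult:
    """One gene's univariate Cox fit: log hazard ratio per Z-unit."""

    gene: str
    beta: float
    se: float
    p_value: float
    converged: bool = True
    capped: bool = False


def fit_univariate_cox(expr: np.ndarray, time: np.ndarray, event: np.ndarray,
                       gene: str = "", max_iter: int = 50,
                       tol: float = 1e-8) -> CoxResult:
    """Fit one covariate against survival by Newton's method.

    Breslow partial likelihood:
        l(b) = sum_{i: event} [ b x_i - log sum_{j: t_j >= t_i} exp(b x_j) ].
    Monotone likelihood (perfect separation) is flagged and beta capped.
    """
    x = np.asarray(expr, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if not len(x) == len(t) == len(e):
        raise ValueError("column lengths differ")
    if e.sum() < 2:
        raise ValueError("need at least two events for a Cox fit")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: Cox fit is degenerate")

    # sort by descending time so risk sets are cumulative prefixes
    order = np.argsort(-t, kind="stable")
    x, e = x[order], e[order]

    beta, capped = 0.0, False
    info = 1.0
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x)
        s2 = np.cumsum(w * x * x)
        idx = e == 1
        grad = float((x[idx] - s1[idx] / s0[idx]).sum())
        info = float((s2[idx] / s0[idx] - (s1[idx] / s0[idx]) ** 2).sum())
        if info <= 0:
            break
        step = grad / info
        beta += np.clip(step, -2.0, 2.0)  # damped for stability
        if abs(beta) > _BETA_CAP:
            beta = float(np.sign(beta) * _BETA_CAP)
            capped = True
            warnings.warn(f"monotone partial likelihood for {gene or 'gene'};"
                          f" beta capped at ±{_BETA_CAP}", stacklevel=2)
            break
        if abs(grad) < tol:
            break
    converged = abs(grad) < tol and not capped
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    wald = (beta / se) ** 2 if np.isfinite(se) and se > 0 else 0.0
    p = float(chi2.sf(wald, df=1))
    return CoxResult(gene=gene, beta=float(beta), se=se, p_value=p,
                     converged=converged, capped=capped)


def fit_cox_per_gene(table: SurvivalTable) -> list[CoxResult]:
    """Univariate screen of every gene in a survival table."""
    return [fit_univariate_cox(table.expression[:, j], table.time, table.event,
                               gene=g)
            for j, g in enumerate(table.gene_names)]


def select_prognostic_genes(results: list[CoxResult], coef_thr: float = 0.2,
                            p_thr: float = 0.01) -> FeatureSet:
    """Genes with |beta| > coef_thr AND p < p_thr, original order kept.

    No multiple-testing correction is applied to the raw threshold; treat
    the resulting list as a screen, not an inference.
    """
    if coef_thr <= 0 or p_thr <= 0:
        raise ValueError("thresholds must be positive")
    return FeatureSet([r.gene for r in results
                       if abs(r.beta) > coef_thr and r.p_value < p_thr],
                      origin="prognostic")


def risk_score(expr_row: dict | "np.ndarray", betas: list[CoxResult],
               gene_names: list[str] | None = None) -> float:
    """score = sum over prognostic genes of expression x beta."""
    if isinstance(expr_row, dict):
        lookup = expr_row
    else:
        if gene_names is None:
            raise ValueError("gene_names required with an array expr_row")
        lookup = dict(zip(gene_names, np.asarray(expr_row, dtype=float)))
    missing = [r.gene for r in betas if r.gene not in lookup]
    if missing:
        raise KeyError(f"expression row is missing genes: {missing}")
    return float(sum(lookup[r.gene] * r.beta for r in betas))


def risk_scores(table: SurvivalTable, betas: list[CoxResult]) -> np.ndarray:
    col = {g: j for j, g in enumerate(table.gene_names)}
    missing = [r.gene for r in betas if r.gene not in col]
    if missing:
        raise KeyError(f"expression table is missing genes: {missing}")
    idx = [col[r.gene] for r in betas]
    b = np.array([r.beta for r in betas])
    return table.expression[:, idx] @ b


def split_by_median(scores: np.ndarray) -> np.ndarray:
    """Group labels: 'high' where score > median, else 'low' (ties low)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least two patients to split")
    med = float(np.median(scores))
    return np.where(scores > med, "high", "low")


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate evaluated at the event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time

    def __call__(self, t: float) -> float:
        """Right-continuous step evaluation of S(t); S(0) = 1."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_estimate(time: np.ndarray, event: np.ndarray) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator.

    Censored-only times reduce the risk set without producing a step.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(t) == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_times = np.unique(t[e == 1])
    if len(event_times) == 0:
        return KaplanMeierCurve(times=np.array([]), survival=np.array([]))
    surv = np.array([float(kmf.survival_function_at_times(u).iloc[0])
                     for u in event_times])
    return KaplanMeierCurve(times=event_times, survival=surv)


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value."""
    if len(np.asarray(time_a)) == 0 or len(np.asarray(time_b)) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a,
                      event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalReport:
    cox_results: list[CoxResult]
    prognostic: FeatureSet
    scores: np.ndarray
    groups: np.ndarray
    km_high: KaplanMeierCurve | None
    km_low: KaplanMeierCurve | None
    logrank_statistic: float | None
    logrank_p: float | None


def evaluate_panel_survival(table: SurvivalTable, genes=None,
                            coef_thr: float = 0.2,
                            p_thr: float = 0.01) -> SurvivalReport:
    """The full pipeline: per-gene Cox screen, prognostic filter, risk score,
    median split, Kaplan-Meier per group, log-rank comparison."""
    if genes is not None:
        keep = [g for g in genes if g in table.gene_names]
        col = {g: j for j, g in enumerate(table.gene_names)}
        idx = [col[g] for g in keep]
        table = SurvivalTable(time=table.time, event=table.event,
                              expression=table.expression[:, idx],
                              gene_names=keep)
    cox = fit_cox_per_gene(table)
    prog = select_prognostic_genes(cox, coef_thr, p_thr)
    chosen = [r for r in cox if r.gene in prog]
    if not chosen:
        return SurvivalReport(cox, prog, np.zeros(len(table.time)),
                              np.array(["low"] * len(table.time)),
                              None, None, None, None)
    scores = risk_scores(table, chosen)
    groups = split_by_median(scores)
    hi, lo = groups == "high", groups == "low"
    km_hi = km_estimate(table.time[hi], table.event[hi])
    km_lo = km_estimate(table.time[lo], table.event[lo])
    stat, p = logrank_test(table.time[hi], table.event[hi],
                           table.time[lo], table.event[lo])
    return SurvivalReport(cox, prog, scores, groups, km_hi, km_lo, stat, p)
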