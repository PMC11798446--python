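"""Per-gene discriminative and prognostic validation.

Discriminative power of a single gene is its ROC AUC over case/control
samples, computed by pair counting (ties count one half) — for a single
covariate this equals the AUC of the univariate logistic model, since the
logistic score is monotone in the covariate.  Prognostic value uses a
survival cohort: samples are split at the cohort median of the gene's
expression into low/high-risk groups, compared with Kaplan-Meier curves and
the log-rank test, and modeled with a univariate Cox proportional-hazards
fit (Breslow tie handling, Newton-Raphson on the partial likelihood with
analytic gradient and Hessian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "ROCResult",
    "LogRankResult",
    "CoxResult",
    "auc_single_gene",
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
]


@dataclass
class ROCResult:
    gene: str
    auc: float
    n_case: int
    n_control: int


def auc_single_gene(
    case_values: np.ndarray, control_values: np.ndarray, gene: str = ""
) -> ROCResult:
    """Pair-counting AUC: P(case > control) + half P(tie)."""
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must contain at least one sample")
    # rank-sum identity: U / (n1 * n0)
    combined = np.concatenate([case, ctrl])
    ranks = stats.rankdata(combined)
    r_case = ranks[: case.size].sum()
    u = r_case - case.size * (case.size + 1) / 2.0
    auc = u / (case.size * ctrl.size)
    return ROCResult(gene=gene, auc=float(auc), n_case=case.size, n_control=ctrl.size)


def median_split(expression: pd.Series) -> pd.Series:
    """Assign each sample to "high" (> median) or "low" (<= median)."""
    x = expression.astype(float)
    if x.size < 2:
        raise ValueError("median split needs at least two samples")
    if x.nunique() == 1:
        raise ValueError("all expression values identical; degenerate median split")
    med = x.median()
    return pd.Series(np.where(x > med, "high", "low"), index=x.index, name="risk_group")


def km_estimate(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a (time, survival) step table."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ValueError("survival times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


@dataclass
class LogRankResult:
    chi_sq: float
    p: float
    observed: dict[str, float]
    expected: dict[str, float]


def logrank_test(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
    labels: tuple[str, str] = ("a", "b"),
) -> LogRankResult:
    """Two-group log-rank test with hypergeometric variance at each event time."""
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_a = e_a = var = 0.0
    for t in event_times:
        n1 = float((ta >= t).sum())
        n2 = float((tb >= t).sum())
        n = n1 + n2
        d1 = float(((ta == t) & (ea == 1)).sum())
        d2 = float(((tb == t) & (eb == 1)).sum())
        d = d1 + d2
        o_a += d1
        e_a += d * n1 / n
        # hypergeometric variance; zero when one group has left the risk set
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var <= 0:
        raise ValueError("log-rank variance is zero; groups are degenerate")
    chi = (o_a - e_a) ** 2 / var
    p = float(stats.chi2.sf(chi, df=1))
    total_events = float(ea.sum() + eb.sum())
    return LogRankResult(
        chi_sq=float(chi),
        p=p,
        observed={labels[0]: o_a, labels[1]: total_events - o_a},
        expected={labels[0]: e_a, labels[1]: total_events - e_a},
    )


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    wald_p: float
    converged: bool
    n_iter: int = 0

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


def _cox_derivatives(
    beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> tuple[float, float, float]:
    """Breslow partial log-likelihood, score and information at ``beta``.

    Risk sets are handled by sorting times descending and accumulating the
    running sums of exp(beta x), x exp(beta x) and x^2 exp(beta x); tied
    event times share one risk-set denominator (Breslow).
    """
    order = np.argsort(-time, kind="mergesort")
    t, e, xv = time[order], event[order], x[order]
    w = np.exp(beta * xv)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * xv)
    s2 = np.cumsum(w * xv * xv)
    # index of the last subject with time >= t_i is the risk set boundary
    loglik = score = info = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # subjects i..j-1 share this time; risk set = everyone up to j-1
        denom0, denom1, denom2 = s0[j - 1], s1[j - 1], s2[j - 1]
        d_idx = [k for k in range(i, j) if e[k] == 1]
        d = len(d_idx)
        if d:
            sx = float(xv[d_idx].sum())
            loglik += beta * sx - d * np.log(denom0)
            mean = denom1 / denom0
            score += sx - d * mean
            info += d * (denom2 / denom0 - mean * mean)
        i = j
    return loglik, score, info


def cox_score_test(time: np.ndarray, event: np.ndarray, covariate: np.ndarray) -> float:
    """Score chi-square statistic at beta = 0 (equals the log-rank statistic
    for a binary covariate)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(covariate, float)
    _, score, info = _cox_derivatives(0.0, time, event, x)
    return float(score * score / info)


def cox_univariate(
    time: np.ndarray,
    event: np.ndarray,
    covariate: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Breslow ties, Newton-Raphson).

    Non-convergence — including the monotone-likelihood case where the risk
    ordering perfectly separates events — is reported via ``converged=False``
    rather than raised.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(covariate, float)
    if event.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    if np.unique(x).size < 2:
        raise ValueError("covariate is constant")

    beta = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        _, score, info = _cox_derivatives(beta, time, event, x)
        if info <= 0 or not np.isfinite(score):
            break
        step = score / info
        # dampen huge steps (monotone likelihood escapes to infinity)
        if abs(step) > 5.0:
            step = np.sign(step) * 5.0
        beta += step
        if abs(beta) > 50:
            break
        if abs(step) < tol:
            converged = True
            break
    _, _, info = _cox_derivatives(beta, time, event, x)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    wald = beta / se if se and np.isfinite(se) and se > 0 else float("nan")
    wald_p = float(2.0 * stats.norm.sf(abs(wald))) if np.isfinite(wald) else float("nan")
    return CoxResult(
        beta=float(beta),
        hr=float(np.exp(beta)),
        se=se,
        wald_p=wald_p,
        converged=converged,
        n_iter=n_iter,
    )


def validate_gene_survival(
    expression: pd.Series, survival: pd.DataFrame
) -> dict:
    """Median-split KM curves, log-rank p and univariate Cox for one gene.

    ``survival`` needs columns sample/time/event; ``expression`` is indexed
    by sample.
    """
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    common = [s for s in surv.index if s in expression.index]
    surv = surv.loc[common]
    expr = expression.loc[common].astype(float)
    groups = median_split(expr)
    hi = groups == "high"
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    lr = logrank_test(
        time[hi.to_numpy()], event[hi.to_numpy()],
        time[~hi.to_numpy()], event[~hi.to_numpy()],
        labels=("high", "low"),
    )
    cox = cox_univariate(time, event, expr.to_numpy())
    return {
        "logrank": lr,
        "cox": cox,
        "km_high": km_estimate(time[hi.to_numpy()], event[hi.to_numpy()]),
        "km_low": km_estimate(time[~hi.to_numpy()], event[~hi.to_numpy()]),
    }
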