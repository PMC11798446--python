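"""Per-dataset preprocessing and moderated differential expression.

Each case/control expression matrix is log2-transformed (when it arrives on a
linear scale), quantile-normalized, and tested probe-by-probe with an
empirical-Bayes moderated two-sample t-statistic: the probe-wise residual
variance is shrunk toward a prior variance whose strength (prior degrees of
freedom ``d0``) and location (``s0_sq``) are estimated from all probes by the
closed-form moment estimator of the log residual variances.  P-values are
Benjamini-Hochberg adjusted per dataset, probes are collapsed to gene symbols
by minimum adjusted p, and genes passing ``|log2FC| >= 1.2`` and
``adj_p < 0.01`` are flagged as DEGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .combine import GeneSet

__all__ = [
    "ExpressionDataset",
    "EBayesHyperparams",
    "preprocess",
    "quantile_normalize",
    "moderated_t_test",
    "bh_adjust",
    "collapse_probes",
    "filter_degs",
]

CASE = "case"
CONTROL = "control"

#: default DEG thresholds
FC_THRESHOLD = 1.2
P_THRESHOLD = 0.01


@dataclass
class ExpressionDataset:
    """A probe x sample expression matrix with two-group labels.

    ``values`` is indexed by probe id with one column per sample; ``groups``
    maps each sample to ``"case"`` or ``"control"``.  After :func:`preprocess`
    the values are on the log2 scale.
    """

    values: pd.DataFrame
    groups: pd.Series
    platform: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"missing group labels for samples: {missing}")
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        counts = self.groups.value_counts()
        if counts.get(CASE, 0) < 2 or counts.get(CONTROL, 0) < 2:
            raise ValueError("need at least 2 samples per group")
        if self.values.index.has_duplicates:
            raise ValueError("probe ids must be unique")

    @property
    def case_columns(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_columns(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])


@dataclass
class EBayesHyperparams:
    """Prior degrees of freedom and prior variance of the shrinkage model."""

    d0: float  # may be math.inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the mean empirical distribution.

    Value of rank r in a column is replaced by the mean, across columns, of
    the r-th order statistic.  Tied values receive the average of the quantile
    means their ranks span, which makes the transform idempotent.
    """
    arr = values.to_numpy(dtype=float)
    sorted_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        qm = np.empty_like(col)
        qm[order] = sorted_means
        # average quantile means within tie blocks
        s = pd.Series(qm).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def preprocess(
    raw: pd.DataFrame,
    groups: pd.Series,
    platform: str = "",
    name: str = "",
    force_log2: bool | None = None,
) -> ExpressionDataset:
    """Log2-transform (if needed) and quantile-normalize a raw matrix.

    The scale is auto-detected: a maximum above 100 is taken to mean linear
    intensities, which are replaced by ``log2(x + 1)``.  ``force_log2``
    overrides the detection (True = always transform, False = never).
    """
    try:
        values = raw.astype(float)
    except (TypeError, ValueError) as exc:
        for probe in raw.index:
            for sample in raw.columns:
                try:
                    float(raw.at[probe, sample])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric expression value at probe {probe!r}, sample {sample!r}"
                    ) from exc
        raise
    if (values.to_numpy() < 0).any() and (force_log2 or values.to_numpy().max() > 100):
        raise ValueError("negative values in a matrix detected as linear scale")
    apply_log = force_log2 if force_log2 is not None else bool(values.to_numpy().max() > 100)
    if apply_log:
        values = np.log2(values + 1.0)
    values = quantile_normalize(values)
    return ExpressionDataset(values=values, groups=groups, platform=platform, name=name)


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorized)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x  # starting value, exact as x -> 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / y) < 1e-10:
            break
    return y


def estimate_hyperparams(s2: np.ndarray, df: float) -> EBayesHyperparams:
    """Moment estimator of (d0, s0^2) from probe-wise residual variances.

    Matches the first two moments of ``log s_g^2`` to the scaled-F model:
    ``e_g = log s_g^2 - digamma(df/2) + log(df/2)`` has mean
    ``log s0^2 + digamma(d0/2) - log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` beyond ``trigamma(df/2)``.  When the excess is not
    positive the prior degrees of freedom are infinite and the prior variance
    is ``exp(mean(e))``.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all probes have zero within-group variance; cannot estimate prior")
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_bar = e.mean()
    n = e.size
    if n < 2:
        return EBayesHyperparams(d0=math.inf, s0_sq=float(np.exp(e_bar)))
    excess = ((e - e_bar) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return EBayesHyperparams(d0=math.inf, s0_sq=float(np.exp(e_bar)))
    d0 = 2.0 * float(_trigamma_inverse(excess)[0])
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return EBayesHyperparams(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    ds: ExpressionDataset,
    hyperparams: EBayesHyperparams | None = None,
) -> tuple[pd.DataFrame, EBayesHyperparams]:
    """Empirical-Bayes moderated two-group t-test, one row per probe.

    Returns a frame with columns ``log2fc`` (case mean minus control mean),
    ``t_mod``, ``df_total`` and two-sided ``p``, plus the hyperparameters
    used.  Pass ``hyperparams`` to fix the prior instead of estimating it.
    """
    case = ds.values[ds.case_columns].to_numpy(dtype=float)
    ctrl = ds.values[ds.control_columns].to_numpy(dtype=float)
    n1, n0 = case.shape[1], ctrl.shape[1]
    df_resid = n1 + n0 - 2

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if hyperparams is None:
        hyperparams = estimate_hyperparams(s2, df_resid)
    d0, s0_sq = hyperparams.d0, hyperparams.s0_sq

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    stderr = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(stderr > 0, log2fc / stderr, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
        },
        index=ds.values.index,
    )
    return result, hyperparams


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def collapse_probes(
    per_probe: pd.DataFrame,
    annotation: pd.Series,
) -> pd.DataFrame:
    """Collapse probe-level results to one record per gene symbol.

    ``annotation`` maps probe id to gene symbol; probes with blank symbols are
    dropped.  When several probes map to one symbol the probe with the
    smallest adjusted p-value represents the gene (ties go to the
    lexicographically smallest probe id), so that probe's expression row also
    stands for the gene downstream.
    """
    if "adj_p" not in per_probe.columns:
        raise ValueError("per-probe results must contain an 'adj_p' column")
    ann = annotation.reindex(per_probe.index).fillna("").astype(str).str.strip().str.upper()
    keep = ann != ""
    df = per_probe.loc[keep].copy()
    df["gene"] = ann[keep]
    df["probe"] = df.index.astype(str)
    df = df.sort_values(["gene", "adj_p", "probe"], kind="mergesort")
    collapsed = df.drop_duplicates(subset="gene", keep="first").set_index("gene")
    return collapsed


def filter_degs(
    records: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    name: str = "DEGs",
) -> GeneSet:
    """Genes with ``|log2fc| >= fc_threshold`` and ``adj_p < p_threshold``."""
    mask = (records["log2fc"].abs() >= fc_threshold) & (records["adj_p"] < p_threshold)
    selected = records.loc[mask]
    direction = {
        str(g): ("up" if fc > 0 else "down") for g, fc in selected["log2fc"].items()
    }
    return GeneSet(name=name, genes=set(map(str, selected.index)), direction=direction)


def deg_table(
    ds: ExpressionDataset,
    annotation: pd.Series,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    hyperparams: EBayesHyperparams | None = None,
) -> tuple[pd.DataFrame, GeneSet]:
    """Full per-dataset DEG analysis: test, adjust, collapse, threshold."""
    per_probe, _ = moderated_t_test(ds, hyperparams=hyperparams)
    per_probe = per_probe.copy()
    per_probe["adj_p"] = bh_adjust(per_probe["p"].to_numpy())
    collapsed = collapse_probes(per_probe, annotation)
    collapsed["is_deg"] = (collapsed["log2fc"].abs() >= fc_threshold) & (
        collapsed["adj_p"] < p_threshold
    )
    collapsed["direction"] = np.where(collapsed["log2fc"] > 0, "up", "down")
    genes = filter_degs(collapsed, fc_threshold, p_threshold, name=ds.name or "DEGs")
    return collapsed, genes
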