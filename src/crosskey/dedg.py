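"""Per-gene SVM accuracy filter (discriminative-gene selection).

Every candidate gene is scored, one dataset at a time, by how well its
expression alone separates cases from controls: an RBF-kernel SVM is grid
searched (cost C, kernel width gamma) with stratified 5-fold cross-validation
on a stratified 80% training split, and the gene's score for that dataset is
the best cross-validated accuracy.  Genes measured in several datasets get
the arithmetic mean of their per-dataset scores; genes whose (mean) accuracy
strictly exceeds 95% are kept as discriminative genes.

Fold and split assignment are derived from ``(seed, gene symbol)``, so each
gene's evaluation is reproducible and independent of evaluation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .combine import GeneSet
from .deg import ExpressionDataset

__all__ = [
    "SvmSettings",
    "GeneAccuracyRecord",
    "split_train_test",
    "evaluate_gene",
    "aggregate_and_select",
    "select_discriminative_genes",
]


@dataclass
class SvmSettings:
    """Grid, fold and threshold settings for the per-gene SVM filter."""

    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    cv_folds: int = 5
    train_fraction: float = 0.8
    accuracy_threshold: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass
class GeneAccuracyRecord:
    gene: str
    per_dataset_accuracy: dict[str, float] = field(default_factory=dict)
    holdout_accuracy: dict[str, float] = field(default_factory=dict)

    @property
    def n_datasets(self) -> int:
        return len(self.per_dataset_accuracy)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.per_dataset_accuracy.values())))


def _gene_seed(settings: SvmSettings, gene: str) -> int:
    digest = hashlib.sha256(f"{settings.seed}:{gene}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def split_train_test(
    ds: ExpressionDataset, settings: SvmSettings, gene: str = ""
) -> tuple[list[str], list[str]]:
    """Stratified train/test sample split keyed to (seed, gene)."""
    # canonical sample order by id: permuting the input leaves the split fixed
    ordered = sorted(ds.groups.index)
    y = ds.groups.loc[ordered].to_numpy()
    samples = np.array(ordered)
    train, test = train_test_split(
        samples,
        train_size=settings.train_fraction,
        stratify=y,
        random_state=_gene_seed(settings, gene),
    )
    n_per_group = min(
        (ds.groups.loc[train] == "case").sum(), (ds.groups.loc[train] == "control").sum()
    )
    if n_per_group < settings.cv_folds:
        raise ValueError(
            f"too few training samples per group ({n_per_group}) for "
            f"{settings.cv_folds}-fold stratified CV"
        )
    return list(train), list(test)


def evaluate_gene(
    gene: str,
    values: pd.DataFrame,
    groups: pd.Series,
    settings: SvmSettings,
) -> tuple[float, float] | None:
    """Best 5-fold CV accuracy of a single-feature RBF SVM for one gene.

    ``values`` is a gene x sample matrix (collapsed to symbols).  Returns
    ``(cv_accuracy, holdout_accuracy)``; ``None`` when the gene is not
    measured in this dataset.  Features are standardized on the training
    folds (RBF kernels are scale-sensitive).  The hold-out accuracy on the
    20% split is reported for logging but plays no role in selection.
    """
    if gene not in values.index:
        return None
    ds = ExpressionDataset(values=values, groups=groups)
    train, test = split_train_test(ds, settings, gene=gene)
    train, test = sorted(train), sorted(test)
    x_train = values.loc[[gene], train].to_numpy().T
    y_train = groups.loc[train].to_numpy()
    x_test = values.loc[[gene], test].to_numpy().T
    y_test = groups.loc[test].to_numpy()

    seed = _gene_seed(settings, gene)
    cv = StratifiedKFold(n_splits=settings.cv_folds, shuffle=True, random_state=seed)
    model = Pipeline([("scale", StandardScaler()), ("svm", SVC(kernel="rbf"))])
    grid = GridSearchCV(
        model,
        param_grid={
            "svm__C": list(settings.c_grid),
            "svm__gamma": list(settings.gamma_grid),
        },
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
    )
    grid.fit(x_train, y_train)
    holdout = float(grid.best_estimator_.score(x_test, y_test))
    return float(grid.best_score_), holdout


def aggregate_and_select(
    records: Iterable[GeneAccuracyRecord],
    settings: SvmSettings,
) -> tuple[pd.DataFrame, GeneSet]:
    """Rank genes by mean accuracy and keep those strictly above threshold.

    Sorted by mean accuracy descending; ties broken by number of datasets
    (more first), then symbol.  Selection requires ``mean > threshold``
    strictly, so a gene at exactly the threshold is excluded.
    """
    rows = []
    for rec in records:
        if rec.n_datasets == 0:
            continue
        rows.append(
            {
                "gene": rec.gene,
                "mean_accuracy": rec.mean_accuracy,
                "n_datasets": rec.n_datasets,
                "per_dataset": dict(sorted(rec.per_dataset_accuracy.items())),
                "selected": rec.mean_accuracy > settings.accuracy_threshold,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "mean_accuracy", "n_datasets", "per_dataset", "selected"])
    if not table.empty:
        table = table.sort_values(
            by=["mean_accuracy", "n_datasets", "gene"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    selected = set(table.loc[table["selected"], "gene"]) if not table.empty else set()
    return table, GeneSet(name="DEDGs", genes=selected)


def select_discriminative_genes(
    candidates: GeneSet,
    datasets: Mapping[str, tuple[pd.DataFrame, pd.Series]],
    settings: SvmSettings | None = None,
) -> tuple[pd.DataFrame, GeneSet]:
    """Score every candidate gene in every dataset that measures it.

    ``datasets`` maps dataset name to ``(gene x sample matrix, groups)``.
    """
    settings = settings or SvmSettings()
    records = []
    for gene in sorted(candidates.genes):
        rec = GeneAccuracyRecord(gene=gene)
        for name, (values, groups) in datasets.items():
            result = evaluate_gene(gene, values, groups, settings)
            if result is not None:
                rec.per_dataset_accuracy[name] = result[0]
                rec.holdout_accuracy[name] = result[1]
        if rec.n_datasets:
            records.append(rec)
    return aggregate_and_select(records, settings)
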