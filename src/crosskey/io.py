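"""Readers and writers for the pipeline's plain-text formats (all TSV)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_expression",
    "read_labels",
    "read_annotation",
    "read_survival",
    "read_gene_list",
    "write_gene_list",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column probe/gene id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_labels(path: str | Path) -> pd.Series:
    """Labels TSV with columns (sample, group in {case, control})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(), name="group")
    return s.str.strip().str.lower()


def read_annotation(path: str | Path) -> pd.Series:
    """Annotation TSV with columns (probe, symbol); symbol may be empty."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(), name="symbol")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival TSV with columns (sample, time, event)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table lacks columns: {sorted(missing)}")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blanks skipped, uppercased."""
    out = []
    for line in Path(path).read_text().splitlines():
        g = line.strip().upper()
        if g:
            out.append(g)
    return out


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(set(genes))) + "\n")
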