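"""Hypergeometric over-representation analysis against GMT collections.

For a query gene set of size n drawn from a universe of N genes, a term with
K members has overlap k with the query; the enrichment p-value is the upper
hypergeometric tail P(X >= k).  Benjamini-Hochberg adjustment is applied
within each collection; the significance flag follows the raw p-value
cutoff, with the adjusted value reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .combine import GeneSet
from .deg import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeometric_ora",
]


@dataclass
class GeneSetCollection:
    """Named annotation sets plus the background universe."""

    name: str
    terms: dict[str, set[str]]  # term id -> member symbols
    term_names: dict[str, str]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = {g.strip().upper() for g in self.universe if g.strip()}
        self.terms = {
            t: {g.strip().upper() for g in members if g.strip()}
            for t, members in self.terms.items()
        }
        for t, members in self.terms.items():
            if not members:
                raise ValueError(f"term {t!r} is empty")


def read_gmt(path: str | Path, universe: set[str] | None = None, name: str = "") -> GeneSetCollection:
    """Parse a GMT file (term, description, members...), tab-separated.

    The universe defaults to the union of all term members; analyses should
    normally pass the set of genes actually measured.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed GMT line: {line[:80]!r}")
        term, desc, members = parts[0], parts[1], parts[2:]
        terms[term] = {m for m in members if m.strip()}
        term_names[term] = desc
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    return GeneSetCollection(
        name=name or path.stem, terms=terms, term_names=term_names, universe=universe
    )


def hypergeometric_ora(
    query: GeneSet,
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term hypergeometric upper-tail enrichment of a query gene set.

    Query genes outside the universe are dropped with a warning.  Returns a
    frame with one row per term (term, term_name, k, K, n, N, p, adj_p,
    significant), sorted by p ascending.
    """
    if not collection.universe:
        raise ValueError("enrichment universe is empty")
    q = query.genes & collection.universe
    dropped = query.genes - collection.universe
    if dropped:
        import warnings

        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe dropped", stacklevel=2
        )
    n = len(q)
    big_n = len(collection.universe)
    rows = []
    for term, members in collection.terms.items():
        members_in = members & collection.universe
        big_k = len(members_in)
        k = len(q & members_in)
        # P(X >= k), X ~ Hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if n else 1.0
        rows.append(
            {
                "term": term,
                "term_name": collection.term_names.get(term, ""),
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["adj_p"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["p"] < alpha
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
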