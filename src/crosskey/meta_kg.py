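"""Meta-hub genes from curated literature and the final key-gene intersection.

A curated table of prior studies' hub-gene lists ships with the package
(one row per study, gene symbols semicolon-separated, raw tokens preserved
exactly as published, typos included).  Loading applies a human-reviewed
alias map that normalizes evident typographical variants; fragments that
cannot be resolved to a symbol (e.g. a stray single letter) are flagged, not
silently dropped.  The meta-hub set is the union of all studies' normalized
lists, and the key genes are the three-way intersection of the hub genes,
the hub-module genes, and the meta-hub genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .combine import GeneSet

__all__ = [
    "LiteratureHubTable",
    "KGReport",
    "packaged_literature_path",
    "packaged_alias_path",
    "load_alias_map",
    "load_literature_table",
    "meta_hub_union",
    "identify_kgs",
]


def packaged_literature_path() -> Path:
    """Path of the curated literature hub-gene snapshot shipped in the package."""
    return Path(str(resources.files("crosskey").joinpath("data/literature_hubs.tsv")))


def packaged_alias_path() -> Path:
    return Path(str(resources.files("crosskey").joinpath("data/alias_map.tsv")))


def load_alias_map(path: str | Path | None = None) -> dict[str, tuple[str, ...]]:
    """Raw token -> normalized symbol(s); a value may expand to several
    symbols (semicolon-separated) when a typo fused two gene names."""
    path = Path(path) if path is not None else packaged_alias_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        str(r).strip().upper(): tuple(s.strip().upper() for s in str(n).split(";") if s.strip())
        for r, n in zip(df["raw"], df["normalized"])
    }


@dataclass
class LiteratureHubTable:
    """Parsed literature table: per-study raw and normalized gene lists."""

    studies: pd.DataFrame  # study_id, platform, raw_tokens, symbols
    unresolved: dict[str, list[str]] = field(default_factory=dict)

    @property
    def raw_token_count(self) -> int:
        """Unique raw tokens across all studies (typos counted as distinct)."""
        tokens: set[str] = set()
        for toks in self.studies["raw_tokens"]:
            tokens |= set(toks)
        return len(tokens)

    @property
    def normalized_count(self) -> int:
        """Unique normalized symbols across all studies."""
        symbols: set[str] = set()
        for syms in self.studies["symbols"]:
            symbols |= set(syms)
        return len(symbols)


def _tokenize(raw: str) -> list[str]:
    out = []
    for chunk in str(raw).replace(",", ";").split(";"):
        for tok in chunk.split():
            tok = tok.strip().upper()
            if tok:
                out.append(tok)
    return out


def load_literature_table(
    path: str | Path | None = None,
    alias_map: dict[str, tuple[str, ...]] | None = None,
) -> LiteratureHubTable:
    """Load a (study_id, platform, genes) table and normalize its symbols.

    Tokens are split on commas, semicolons and whitespace, uppercased, and
    passed through the alias map.  Tokens shorter than two characters are
    reported as unresolved fragments for that study.  A row with an empty
    gene list is an error.
    """
    path = Path(path) if path is not None else packaged_literature_path()
    if not path.exists():
        raise FileNotFoundError(path)
    if alias_map is None:
        alias_map = load_alias_map()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["study_id"].duplicated().any():
        raise ValueError("study ids must be unique")
    rows = []
    unresolved: dict[str, list[str]] = {}
    for rec in df.itertuples(index=False):
        tokens = _tokenize(rec.genes)
        if not tokens:
            raise ValueError(f"study {rec.study_id} has an empty gene list")
        symbols: list[str] = []
        for tok in tokens:
            if tok in alias_map:
                symbols.extend(alias_map[tok])
            elif len(tok) < 2:
                unresolved.setdefault(rec.study_id, []).append(tok)
            else:
                symbols.append(tok)
        rows.append(
            {
                "study_id": rec.study_id,
                "platform": getattr(rec, "platform", ""),
                "raw_tokens": tokens,
                "symbols": sorted(set(symbols)),
            }
        )
    return LiteratureHubTable(studies=pd.DataFrame(rows), unresolved=unresolved)


def meta_hub_union(table: LiteratureHubTable) -> GeneSet:
    """Union of every study's normalized hub-gene list."""
    if table.studies.empty:
        raise ValueError("literature table contains no studies")
    genes: set[str] = set()
    for syms in table.studies["symbols"]:
        genes |= set(syms)
    return GeneSet(name="meta", genes=genes)


@dataclass
class KGReport:
    """The key-gene intersection with per-gene source membership flags."""

    kgs: GeneSet
    source_sizes: dict[str, int]
    membership: dict[str, dict[str, bool]]

    def to_dict(self) -> dict:
        return {
            "key_genes": sorted(self.kgs.genes),
            "source_sizes": self.source_sizes,
            "membership": self.membership,
        }


def identify_kgs(hub: GeneSet, module: GeneSet, meta: GeneSet) -> KGReport:
    """Key genes = hub genes ∩ hub-module genes ∩ meta-hub genes.

    Empty inputs yield an empty key-gene set with a warning rather than an
    exception, so a pipeline run on data with no dense module still produces
    a (vacuous) report.
    """
    sources = {"hub": hub, "module": module, "meta": meta}
    if any(len(s) == 0 for s in sources.values()):
        import warnings

        empty = [n for n, s in sources.items() if len(s) == 0]
        warnings.warn(f"empty source set(s) {empty}; key-gene set is empty", stacklevel=2)
        kg_genes: set[str] = set()
    else:
        kg_genes = hub.genes & module.genes & meta.genes
    kgs = GeneSet(name="key_genes", genes=kg_genes)
    membership = {
        g: {name: g in s for name, s in sources.items()} for g in sorted(kg_genes)
    }
    return KGReport(
        kgs=kgs,
        source_sizes={name: len(s) for name, s in sources.items()},
        membership=membership,
    )
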