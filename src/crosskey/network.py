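"""Protein-interaction network analysis: MCC hub ranking and MCODE modules.

The interaction graph is built from a weighted edge list (STRING-style
0-1000 scores are rescaled to [0, 1]) keeping edges at or above a confidence
threshold (default 0.70).  Hub genes are the top-k nodes by Maximal Clique
Centrality: ``MCC(v) = sum over maximal cliques C containing v of
(|C| - 1)!``, computed by Bron-Kerbosch enumeration with pivoting.  Dense
modules are detected with a from-scratch MCODE: vertices are weighted by the
k-core level times the density of the highest k-core of their closed
neighborhood, complexes grow outward from high-weight seeds including
neighbors whose weight is within ``node_score_cutoff`` of the seed's, and a
"haircut" trims singly-connected vertices (2-core of the complex).

A module's score is its node count times its density; density is equivalently
stated over ordered vertex pairs (2e / (n (n-1))), so a complete module on n
nodes scores exactly n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .combine import GeneSet

__all__ = [
    "MCODEParams",
    "ModuleRecord",
    "build_graph",
    "mcc_scores",
    "top_k_hubs",
    "mcode_vertex_weights",
    "mcode_find_complexes",
    "select_hub_modules",
]

CONFIDENCE_THRESHOLD = 0.70


class CliqueBudgetExceeded(RuntimeError):
    """Raised when maximal-clique enumeration exceeds the configured budget."""


@dataclass
class MCODEParams:
    """The four published MCODE knobs plus the haircut/fluff flags."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self) -> None:
        if self.degree_cutoff < 1 or self.k_core < 1 or self.max_depth < 1:
            raise ValueError("MCODE cutoffs must be positive")
        if not 0.0 < self.node_score_cutoff < 1.0:
            raise ValueError("node_score_cutoff must lie in (0, 1)")


@dataclass
class ModuleRecord:
    """One detected complex with the ordered-pair scoring convention."""

    nodes: list[str]
    undirected_edge_count: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def ordered_pair_count(self) -> int:
        return 2 * self.undirected_edge_count

    @property
    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return self.ordered_pair_count / (n * (n - 1))

    @property
    def score(self) -> float:
        return self.density * self.n_nodes


def build_graph(
    edges: pd.DataFrame | str | Path,
    confidence_threshold: float = CONFIDENCE_THRESHOLD,
) -> nx.Graph:
    """Simple undirected graph from a (gene_a, gene_b, confidence) table.

    Confidences above 1 anywhere mean the STRING 0-1000 scale; the whole
    column is then divided by 1000.  Self-loops are dropped, duplicate pairs
    keep their maximum confidence, and the threshold is inclusive.
    """
    if not isinstance(edges, pd.DataFrame):
        path = Path(edges)
        edges = pd.read_csv(path, sep="\t")
        try:
            edges.iloc[:, 2].astype(float)
        except (TypeError, ValueError):
            for i, v in enumerate(edges.iloc[:, 2]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: malformed confidence on data line {i + 1}: {v!r}"
                    ) from None
    cols = list(edges.columns[:3])
    df = edges[cols].copy()
    df.columns = ["gene_a", "gene_b", "confidence"]
    df["confidence"] = df["confidence"].astype(float)
    if (df["confidence"] < 0).any():
        raise ValueError("edge confidences must be nonnegative")
    if (df["confidence"] > 1).any():
        df["confidence"] = df["confidence"] / 1000.0
    df["gene_a"] = df["gene_a"].astype(str).str.strip().str.upper()
    df["gene_b"] = df["gene_b"].astype(str).str.strip().str.upper()

    g = nx.Graph()
    for a, b, c in df.itertuples(index=False):
        if a == b or c < confidence_threshold:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], c)
        else:
            g.add_edge(a, b, confidence=c)
    return g


def mcc_scores(g: nx.Graph, max_cliques: int = 10**6) -> dict[str, float]:
    """Maximal Clique Centrality of every node.

    Sums ``(|C| - 1)!`` over the maximal cliques containing each node,
    counting only cliques of size >= 2 (isolated maximal "cliques" of one
    node contribute nothing, so such nodes score 0).
    """
    scores: dict[str, float] = {v: 0.0 for v in g.nodes}
    seen = 0
    for clique in nx.find_cliques(g):
        seen += 1
        if seen > max_cliques:
            raise CliqueBudgetExceeded(
                f"more than {max_cliques} maximal cliques; raise max_cliques explicitly"
            )
        if len(clique) < 2:
            continue
        contribution = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contribution
    return scores


def top_k_hubs(scores: dict[str, float], g: nx.Graph, k: int = 20) -> GeneSet:
    """The k highest-MCC nodes; ties by degree descending, then symbol."""
    ranked = sorted(
        scores.items(), key=lambda item: (-item[1], -g.degree(item[0]), item[0])
    )
    if len(ranked) < k:
        import warnings

        warnings.warn(
            f"only {len(ranked)} scored nodes available for top-{k} hub selection",
            stacklevel=2,
        )
    return GeneSet(name="hub", genes={v for v, _ in ranked[:k]})


def hub_table(scores: dict[str, float], g: nx.Graph) -> pd.DataFrame:
    """Full MCC ranking as a frame (gene, mcc, degree, rank)."""
    ranked = sorted(
        scores.items(), key=lambda item: (-item[1], -g.degree(item[0]), item[0])
    )
    return pd.DataFrame(
        {
            "gene": [v for v, _ in ranked],
            "mcc": [s for _, s in ranked],
            "degree": [g.degree(v) for v, _ in ranked],
            "rank": range(1, len(ranked) + 1),
        }
    )


def _core_subgraph_density(sub: nx.Graph, k_floor: int) -> tuple[int, float]:
    """Highest k-core level of ``sub`` and that core's undirected density."""
    if sub.number_of_edges() == 0:
        return 0, 0.0
    core_numbers = nx.core_number(sub)
    k_max = max(core_numbers.values())
    if k_max < k_floor:
        return 0, 0.0
    core_nodes = [v for v, c in core_numbers.items() if c >= k_max]
    core = sub.subgraph(core_nodes)
    n = core.number_of_nodes()
    density = 2 * core.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    return k_max, density


def mcode_vertex_weights(g: nx.Graph, params: MCODEParams | None = None) -> dict[str, float]:
    """MCODE vertex weighting: k-core level x density of the closed
    neighborhood's highest core; 0 for low-degree vertices or when the
    neighborhood has no core at the ``k_core`` floor."""
    params = params or MCODEParams()
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = set(g.neighbors(v)) | {v}
        k_max, density = _core_subgraph_density(g.subgraph(closed), params.k_core)
        weights[v] = float(k_max) * density
    return weights


def mcode_find_complexes(
    g: nx.Graph,
    weights: dict[str, float] | None = None,
    params: MCODEParams | None = None,
) -> list[ModuleRecord]:
    """Seeded complex detection from high-weight vertices.

    Seeds are unvisited vertices in decreasing weight order; breadth-first
    expansion up to ``max_depth`` admits unvisited neighbors whose weight is
    at least ``(1 - node_score_cutoff)`` times the seed's.  Each vertex joins
    at most one complex.  The haircut keeps the 2-core of the complex (it
    removes singly-connected vertices, repeatedly).  Complexes are returned
    sorted by score descending, then size descending.
    """
    params = params or MCODEParams()
    if weights is None:
        weights = mcode_vertex_weights(g, params)
    visited: set[str] = set()
    complexes: list[ModuleRecord] = []
    threshold_of = lambda seed: (1.0 - params.node_score_cutoff) * weights[seed]

    seeds = sorted(g.nodes, key=lambda v: (-weights[v], v))
    for seed in seeds:
        if seed in visited or weights[seed] <= 0.0:
            continue
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        cutoff = threshold_of(seed)
        for _ in range(params.max_depth):
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w in visited or w in members:
                        continue
                    if weights[w] >= cutoff and weights[w] > 0.0:
                        members.add(w)
                        visited.add(w)
                        nxt.append(w)
            if not nxt:
                break
            frontier = nxt
        sub = g.subgraph(members).copy()
        if params.haircut and sub.number_of_nodes() > 2:
            core = nx.k_core(sub, 2)
            if core.number_of_nodes() >= 2:
                sub = core
        if sub.number_of_nodes() < 2:
            continue
        complexes.append(
            ModuleRecord(
                nodes=sorted(sub.nodes),
                undirected_edge_count=sub.number_of_edges(),
            )
        )
    complexes.sort(key=lambda m: (-m.score, -m.n_nodes, m.nodes))
    return complexes


def select_hub_modules(
    modules: list[ModuleRecord],
    score_min: float = 6.0,
    nodes_min: int = 6,
) -> GeneSet:
    """Union of the node sets of modules meeting both cutoffs."""
    genes: set[str] = set()
    kept = 0
    for m in modules:
        if m.score >= score_min and m.n_nodes >= nodes_min:
            genes |= set(m.nodes)
            kept += 1
    if kept == 0:
        import warnings

        warnings.warn("no module met the score/node cutoffs; empty module gene set", stacklevel=2)
    return GeneSet(name="module", genes=genes)
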