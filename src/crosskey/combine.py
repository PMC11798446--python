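"""Set algebra across datasets and platforms.

The pipeline's central argument is that unioning differentially expressed
genes (DEGs) within a platform ("individual combined" DEGs, icDEGs) and then
across platforms ("grand combined" DEGs, gcDEGs) loses no candidate gene,
whereas the common practice of intersecting DEG lists across cohorts discards
genes that are detectable only on some platforms.  This module implements the
union/intersection algebra, Venn region summaries, and the necessity analysis
that contrasts the two strategies for a final key-gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneSet",
    "VennSummary",
    "union_within_platform",
    "union_across_platforms",
    "intersect_sets",
    "venn_counts",
    "necessity_analysis",
]

#: direction label used when member sets disagree on a gene's regulation
DISCORDANT = "discordant"


def _normalize(genes: Iterable[str]) -> set[str]:
    out = set()
    for g in genes:
        g = str(g).strip().upper()
        if g:
            out.add(g)
    return out


@dataclass
class GeneSet:
    """A named set of uppercase gene symbols with optional per-gene direction.

    ``name`` records provenance (dataset / platform / pipeline stage) so
    downstream reports can say where each set came from.  ``direction`` maps
    a subset of ``genes`` to ``"up"``/``"down"`` (or ``"discordant"`` after a
    conflicting union).
    """

    name: str
    genes: set[str]
    direction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be nonempty")
        self.genes = _normalize(self.genes)
        self.direction = {
            k.strip().upper(): v for k, v in self.direction.items() if k.strip().upper() in self.genes
        }

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return str(gene).strip().upper() in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


def _merge_directions(sets: Sequence[GeneSet], genes: set[str]) -> dict[str, str]:
    """Union per-gene directions; conflicting annotations become discordant."""
    merged: dict[str, str] = {}
    for gs in sets:
        for g, d in gs.direction.items():
            if g not in genes:
                continue
            if g in merged and merged[g] != d:
                merged[g] = DISCORDANT
            else:
                merged.setdefault(g, d)
    return merged


def union_within_platform(deg_sets: Sequence[GeneSet], platform: str | None = None) -> GeneSet:
    """Union the DEG sets of one platform's datasets into its icDEG set."""
    if not deg_sets:
        raise ValueError("union_within_platform requires at least one gene set")
    genes: set[str] = set()
    for gs in deg_sets:
        genes |= gs.genes
    name = f"icDEGs[{platform}]" if platform else f"icDEGs[{'+'.join(gs.name for gs in deg_sets)}]"
    return GeneSet(name=name, genes=genes, direction=_merge_directions(deg_sets, genes))


def union_across_platforms(ic_sets: Sequence[GeneSet]) -> GeneSet:
    """Union per-platform icDEG sets into the grand combined (gcDEG) set."""
    if not ic_sets:
        raise ValueError("union_across_platforms requires at least one gene set")
    genes: set[str] = set()
    for gs in ic_sets:
        genes |= gs.genes
    return GeneSet(name="gcDEGs", genes=genes, direction=_merge_directions(ic_sets, genes))


def intersect_sets(sets: Sequence[GeneSet], name: str = "common") -> GeneSet:
    """Genes present in every input set (requires >= 2 sets)."""
    if len(sets) < 2:
        raise ValueError("intersect_sets requires at least two gene sets")
    genes = set(sets[0].genes)
    for gs in sets[1:]:
        genes &= gs.genes
    return GeneSet(name=name, genes=genes, direction=_merge_directions(sets, genes))


@dataclass
class VennSummary:
    """Counts of every nonempty membership region of up to six sets.

    ``region_counts`` maps a binary membership pattern (e.g. ``"110"`` =
    present in the first two sets, absent from the third; order follows the
    input list) to the number of genes with exactly that pattern.
    """

    set_names: list[str]
    region_counts: dict[str, int]
    union_size: int

    def __post_init__(self) -> None:
        if sum(self.region_counts.values()) != self.union_size:
            raise ValueError("region counts must partition the union")


def venn_counts(sets: Sequence[GeneSet]) -> VennSummary:
    """Exact region counts for 2-6 gene sets (the regions partition the union)."""
    if not 2 <= len(sets) <= 6:
        raise ValueError("venn_counts supports between 2 and 6 sets")
    union: set[str] = set()
    for gs in sets:
        union |= gs.genes
    counts: dict[str, int] = {}
    for gene in union:
        pattern = "".join("1" if gene in gs.genes else "0" for gs in sets)
        counts[pattern] = counts.get(pattern, 0) + 1
    return VennSummary(
        set_names=[gs.name for gs in sets],
        region_counts=counts,
        union_size=len(union),
    )


def necessity_analysis(
    kgs: GeneSet,
    deg_sets_by_platform: Mapping[str, Sequence[GeneSet]],
) -> dict:
    """Check which key genes survive intersection-based alternatives.

    Five constructions are contrasted: the per-platform common DEGs
    (intersection of each platform's datasets), the all-dataset common DEGs,
    and the union-based gcDEG set.  For every key gene and construction a
    present/absent flag is reported, plus the number of key genes each
    construction recovers.  Union-based combining can never lose a gene that
    any single dataset detected; intersections can and typically do.
    """
    constructions: dict[str, GeneSet] = {}
    all_sets: list[GeneSet] = []
    ic_sets: list[GeneSet] = []
    for platform, dsets in deg_sets_by_platform.items():
        dsets = list(dsets)
        all_sets.extend(dsets)
        ic_sets.append(union_within_platform(dsets, platform=platform))
        if len(dsets) >= 2:
            constructions[f"common[{platform}]"] = intersect_sets(dsets, name=f"common[{platform}]")
        else:
            constructions[f"common[{platform}]"] = GeneSet(
                name=f"common[{platform}]", genes=set(dsets[0].genes)
            )
    if len(all_sets) >= 2:
        constructions["common[all]"] = intersect_sets(all_sets, name="common[all]")
    else:
        constructions["common[all]"] = GeneSet(name="common[all]", genes=set(all_sets[0].genes))
    constructions["gcDEGs"] = union_across_platforms(ic_sets)

    membership = {
        kg: {cname: kg in cset for cname, cset in constructions.items()}
        for kg in sorted(kgs.genes)
    }
    recovered = {
        cname: sum(1 for kg in kgs.genes if kg in cset) for cname, cset in constructions.items()
    }
    return {
        "kg_membership": membership,
        "recovered_per_construction": recovered,
        "construction_sizes": {cname: len(cset) for cname, cset in constructions.items()},
    }
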