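"""Self-contained synthetic multi-platform case/control studies.

The generator emulates the layout of a multi-cohort microarray study: several
"platforms" with distinct but overlapping gene universes, two datasets per
platform, probes mapping many-to-one onto gene symbols (with a fraction of
blank annotations), planted differentially expressed genes with a configured
log2 effect, a planted near-clique module inside a sparse background
protein-interaction network, survival times whose hazard depends on a planted
gene, and a small "literature" table of pseudo-studies listing hub genes.
Every artifact is reproducible: its random stream is derived from the master
seed and the artifact's name, so artifacts are independent and reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_platform_universes",
    "generate_expression_dataset",
    "generate_ppi_edges",
    "generate_survival_cohort",
    "generate_literature_table",
    "generate_study",
    "write_study",
]

#: planted log2 effects (case minus control); the first seven genes form the
#: planted interaction module and are the expected key genes.
DEFAULT_PLANTED_EFFECTS = {
    "PLNT01": 3.0,
    "PLNT02": 3.0,
    "PLNT03": 3.0,
    "PLNT04": -3.0,
    "PLNT05": 3.0,
    "PLNT06": -3.0,
    "PLNT07": 3.0,
    "PLNT08": 2.5,
    "PLNT09": -2.5,
    "PLNT10": 3.0,
}
DEFAULT_MODULE_GENES = tuple(list(DEFAULT_PLANTED_EFFECTS)[:7])


@dataclass
class SyntheticConfig:
    """Study-design knobs for the synthetic generator.

    Defaults mirror the study layout the pipeline targets: three platforms,
    two datasets each, 30 samples per group, planted effects of three noise
    standard deviations, and a planted 7-gene near-clique.
    """

    n_platforms: int = 3
    datasets_per_platform: int = 2
    universe_size_per_platform: int = 240
    shared_core_size: int = 180
    samples_per_group: int = 30
    planted_de_genes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_EFFECTS)
    )
    planted_module_genes: tuple[str, ...] = DEFAULT_MODULE_GENES
    noise_sd: float = 0.5
    probes_per_gene_max: int = 3
    blank_symbol_fraction: float = 0.1
    background_edge_prob: float = 0.003
    planted_edge_prob: float = 1.0
    survival_beta: float = 0.7
    survival_gene: str = "PLNT01"
    n_survival_samples: int = 374
    censor_rate: float = 0.3
    n_literature_studies: int = 10
    n_literature_decoys: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shared_core_size > self.universe_size_per_platform:
            raise ValueError("shared core cannot exceed the platform universe size")
        planted = set(self.planted_de_genes)
        if not set(self.planted_module_genes) <= planted:
            raise ValueError("planted module genes must be a subset of planted DE genes")
        if self.survival_gene not in planted:
            raise ValueError("survival gene must be a planted DE gene")
        if len(planted) > self.shared_core_size:
            raise ValueError("planted genes must fit in the shared core")

    @property
    def platforms(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_platforms)]


@dataclass
class GroundTruth:
    """What the generator planted, for checking downstream recovery."""

    de_genes: dict[str, float]
    module_genes: list[str]
    literature_genes: list[str]
    expected_kgs: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "de_genes": self.de_genes,
                "module_genes": self.module_genes,
                "literature_genes": self.literature_genes,
                "expected_kgs": self.expected_kgs,
            },
            indent=2,
            sort_keys=True,
        )


def _rng(config: SyntheticConfig, *key: object) -> np.random.Generator:
    """One RNG stream per artifact: master seed + SHA-256 of the artifact key."""
    tag = ":".join(str(k) for k in key)
    digest = hashlib.sha256(tag.encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, *words]))


def generate_platform_universes(config: SyntheticConfig) -> dict[str, set[str]]:
    """Per-platform gene universes: a shared core plus private symbols.

    All planted genes sit in the shared core, so every platform measures
    them; each platform additionally carries private genes no other platform
    has, which is what makes intersection-based combining lossy.
    """
    core_extra = config.shared_core_size - len(config.planted_de_genes)
    core = sorted(config.planted_de_genes) + [f"CORE{i:04d}" for i in range(core_extra)]
    n_private = config.universe_size_per_platform - config.shared_core_size
    if n_private < 1:
        # degenerate: identical universes
        return {p: set(core) for p in config.platforms}
    universes = {}
    for p in config.platforms:
        private = [f"{p}PRIV{i:04d}" for i in range(n_private)]
        universes[p] = set(core) | set(private)
    return universes


def _probe_annotation(
    config: SyntheticConfig, platform: str, genes: list[str]
) -> pd.Series:
    """Probe -> symbol map with 1..probes_per_gene_max probes per gene.

    A ``blank_symbol_fraction`` of probes loses its symbol (emulating
    unannotated array probes); planted genes are exempt so the ground truth
    stays recoverable, and blanks are dropped downstream anyway.
    """
    rng = _rng(config, "annotation", platform)
    probes: list[str] = []
    symbols: list[str] = []
    counts = rng.integers(1, config.probes_per_gene_max + 1, size=len(genes))
    for gene, k in zip(genes, counts):
        for j in range(int(k)):
            probes.append(f"{platform}_{gene}_pr{j}")
            symbols.append(gene)
    ann = pd.Series(symbols, index=probes, name="symbol")
    planted = set(config.planted_de_genes)
    eligible = np.array([s not in planted for s in symbols])
    n_blank = int(round(config.blank_symbol_fraction * len(probes)))
    idx = np.flatnonzero(eligible)
    if n_blank > 0 and idx.size > 0:
        chosen = rng.choice(idx, size=min(n_blank, idx.size), replace=False)
        ann.iloc[chosen] = ""
    return ann


def generate_expression_dataset(
    config: SyntheticConfig, platform: str, replicate: int
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """One probe x sample matrix plus group labels and probe annotation.

    Per-gene baselines are drawn once per platform on the log2 scale
    (Uniform(4, 10)) so platforms differ in absolute level; case columns of
    planted probes are shifted by the gene's configured log2 effect; Gaussian
    noise with sd ``noise_sd`` is added everywhere.
    """
    universes = generate_platform_universes(config)
    if platform not in universes:
        raise KeyError(f"unknown platform id: {platform!r}")
    genes = sorted(universes[platform])
    base_rng = _rng(config, "baseline", platform)
    baseline = pd.Series(base_rng.uniform(4.0, 10.0, size=len(genes)), index=genes)

    annotation = _probe_annotation(config, platform, genes)
    probes = list(annotation.index)
    # a probe's gene is encoded in its id so blanked annotations do not lose it
    probe_gene = [p.split("_")[1] for p in probes]

    n = config.samples_per_group
    samples = [f"{platform}D{replicate}_case{i:03d}" for i in range(n)] + [
        f"{platform}D{replicate}_ctrl{i:03d}" for i in range(n)
    ]
    groups = pd.Series(["case"] * n + ["control"] * n, index=samples, name="group")

    rng = _rng(config, "expression", platform, replicate)
    mat = np.empty((len(probes), 2 * n))
    for i, gene in enumerate(probe_gene):
        mat[i, :] = baseline[gene]
        effect = config.planted_de_genes.get(gene, 0.0)
        mat[i, :n] += effect
    mat += rng.normal(0.0, config.noise_sd, size=mat.shape)
    values = pd.DataFrame(mat, index=probes, columns=samples)
    return values, groups, annotation


def generate_ppi_edges(config: SyntheticConfig) -> pd.DataFrame:
    """Weighted undirected edge list over the union of all universes.

    Planted module genes are pairwise connected with probability
    ``planted_edge_prob`` and confidence in [0.9, 1.0); background pairs
    appear with probability ``background_edge_prob`` and confidence
    Uniform(0.2, 0.95).  No self-loops, no duplicate pairs.
    """
    universes = generate_platform_universes(config)
    all_genes = sorted(set().union(*universes.values()))
    module = sorted(config.planted_module_genes)
    module_set = set(module)
    rng = _rng(config, "ppi")

    rows: list[tuple[str, str, float]] = []
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            if rng.random() < config.planted_edge_prob:
                rows.append((a, b, float(rng.uniform(0.9, 1.0))))
    # background: vectorized Bernoulli over the remaining unordered pairs
    n = len(all_genes)
    idx_a, idx_b = np.triu_indices(n, k=1)
    gene_arr = np.array(all_genes)
    both_module = np.array(
        [ga in module_set and gb in module_set for ga, gb in zip(gene_arr[idx_a], gene_arr[idx_b])]
    )
    draw = rng.random(idx_a.size) < config.background_edge_prob
    keep = draw & ~both_module
    confs = rng.uniform(0.2, 0.95, size=int(keep.sum()))
    for ga, gb, c in zip(gene_arr[idx_a[keep]], gene_arr[idx_b[keep]], confs):
        rows.append((str(ga), str(gb), float(c)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])


def generate_survival_cohort(
    config: SyntheticConfig, expression: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survival table plus the gene x sample expression of the cohort.

    Event times are exponential with log-hazard ``survival_beta`` times the
    centered expression of the designated planted gene.  Censoring times are
    independent Uniform(0, T_max) with T_max solved numerically so the
    expected censoring fraction approximates ``censor_rate``.
    """
    rng = _rng(config, "survival")
    n = config.n_survival_samples
    samples = [f"SURV{i:04d}" for i in range(n)]
    if expression is None:
        universes = generate_platform_universes(config)
        genes = sorted(set().union(*universes.values()))
        expression = pd.DataFrame(
            rng.normal(7.0, 1.0, size=(len(genes), n)), index=genes, columns=samples
        )
    else:
        samples = list(expression.columns)
        n = len(samples)
    if config.survival_gene not in expression.index:
        raise ValueError(f"expression lacks the designated survival gene {config.survival_gene}")

    x = expression.loc[config.survival_gene].to_numpy(dtype=float)
    x = x - x.mean()
    hazard = 0.1 * np.exp(config.survival_beta * x)
    event_times = rng.exponential(1.0 / hazard)

    if config.censor_rate <= 0:
        time, event = event_times, np.ones(n, dtype=int)
    else:
        u = rng.random(n)

        def censored_fraction(t_max: float) -> float:
            cens = u * t_max
            return float(np.mean(cens < event_times)) - config.censor_rate

        lo, hi = 1e-6, float(event_times.max()) * 100
        if censored_fraction(hi) > 0:
            t_max = hi
        else:
            t_max = brentq(censored_fraction, lo, hi)
        cens = u * t_max
        event = (event_times <= cens).astype(int)
        time = np.minimum(event_times, cens)

    table = pd.DataFrame(
        {"sample": samples, "time": np.maximum(time, 1e-9), "event": event}
    )
    return table, expression


def generate_literature_table(config: SyntheticConfig) -> pd.DataFrame:
    """Pseudo-studies whose hub-gene lists cover every planted DE gene.

    Decoy symbols absent from all platform universes pad each study, so the
    meta-hub union is a strict superset of the planted genes but contributes
    nothing spurious to the final intersection.
    """
    rng = _rng(config, "literature")
    planted = sorted(config.planted_de_genes)
    decoys = [f"DECOY{i:03d}" for i in range(config.n_literature_decoys)]
    rows = []
    for s in range(config.n_literature_studies):
        k_planted = int(rng.integers(1, len(planted) + 1))
        chosen = list(rng.choice(planted, size=k_planted, replace=False))
        k_decoy = int(rng.integers(1, 6))
        chosen += list(rng.choice(decoys, size=min(k_decoy, len(decoys)), replace=False))
        rows.append(
            {
                "study_id": f"STUDY{s + 1:02d}",
                "platform": rng.choice(["P1", "P2", "P3"]),
                "genes": ";".join(chosen),
            }
        )
    # guarantee full coverage of planted genes in at least one study
    covered = set()
    for r in rows:
        covered |= set(r["genes"].split(";"))
    missing = [g for g in planted if g not in covered]
    if missing:
        rows[0]["genes"] = ";".join(sorted(set(rows[0]["genes"].split(";")) | set(missing)))
    return pd.DataFrame(rows, columns=["study_id", "platform", "genes"])


@dataclass
class SyntheticStudy:
    """All artifacts of one synthetic multi-platform study."""

    config: SyntheticConfig
    universes: dict[str, set[str]]
    datasets: dict[tuple[str, int], tuple[pd.DataFrame, pd.Series, pd.Series]]
    ppi_edges: pd.DataFrame
    survival: pd.DataFrame
    survival_expression: pd.DataFrame
    literature: pd.DataFrame
    truth: GroundTruth


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate every artifact of a study from one config."""
    config = config or SyntheticConfig()
    universes = generate_platform_universes(config)
    datasets = {
        (p, d): generate_expression_dataset(config, p, d)
        for p in config.platforms
        for d in range(1, config.datasets_per_platform + 1)
    }
    ppi = generate_ppi_edges(config)
    survival, surv_expr = generate_survival_cohort(config)
    literature = generate_literature_table(config)
    lit_genes = sorted(
        {g for row in literature["genes"] for g in str(row).split(";") if g}
    )
    expected = sorted(
        set(config.planted_de_genes)
        & set(config.planted_module_genes)
        & set(lit_genes)
    )
    truth = GroundTruth(
        de_genes=dict(config.planted_de_genes),
        module_genes=sorted(config.planted_module_genes),
        literature_genes=lit_genes,
        expected_kgs=expected,
    )
    return SyntheticStudy(
        config=config,
        universes=universes,
        datasets=datasets,
        ppi_edges=ppi,
        survival=survival,
        survival_expression=surv_expr,
        literature=literature,
        truth=truth,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write every artifact as TSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (platform, rep), (values, groups, annotation) in study.datasets.items():
        stem = f"{platform}_d{rep}"
        values.to_csv(out / f"{stem}_expression.tsv", sep="\t", index_label="probe")
        groups.rename("group").to_csv(out / f"{stem}_labels.tsv", sep="\t", index_label="sample")
        annotation.rename("symbol").to_csv(
            out / f"{stem}_annotation.tsv", sep="\t", index_label="probe"
        )
    study.ppi_edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
    study.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
    study.survival_expression.to_csv(
        out / "survival_expression.tsv", sep="\t", index_label="gene"
    )
    study.literature.to_csv(out / "literature.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(study.truth.to_json())
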