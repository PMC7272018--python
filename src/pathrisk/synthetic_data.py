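"""Synthetic case/control cohorts with planted pathway-level signal.

Generates everything the downstream pipeline consumes — a gene×sample
expression matrix, sample annotations with clinical covariates, directional
gene sets, a protein-interaction edge list with a heavy-tailed degree
distribution — together with the ground truth (which genes were shifted up or
down in cases, and which terms carry them), so every stage can be tested
against a known answer without external downloads.

The default configuration mirrors a bronchial-epithelium smoking cohort:
85 control smokers vs 78 case (lung cancer) smokers, a minority of genes
shifted up or down in cases, gene sets that mix both directions, and clinical
covariates (age, smoking history, nodule size, lymphadenopathy) that are
themselves mildly informative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLINICAL_FIELDS = (
    "age",
    "gender",
    "smoking_duration",
    "smoking_index",
    "nodule_size",
    "lymphadenopathy",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``effect_size`` is the case-vs-control mean shift of planted genes in
    units of the within-group standard deviation ``noise_sd``; planted "up"
    genes are shifted +effect_size·noise_sd in cases, "down" genes the
    opposite.  ``graph_attach_edges`` is the preferential-attachment parameter
    (edges added per new node), which yields the heavy-tailed degree
    distribution typical of interaction networks.  ``clinical_effect`` shifts
    case clinical covariates in units of their own spread.
    """

    n_case: int = 78
    n_control: int = 85
    n_genes: int = 2000
    n_planted_up: int = 150
    n_planted_down: int = 120
    effect_size: float = 1.5
    noise_sd: float = 1.0
    n_terms: int = 20
    genes_per_term: tuple[int, int] = (10, 30)
    planted_fraction_per_term: float = 0.5
    graph_attach_edges: int = 3
    clinical_effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("sample counts must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.genes_per_term
        if hi > self.n_genes:
            raise ValueError("genes_per_term exceeds n_genes")
        if lo < 1 or lo > hi:
            raise ValueError("genes_per_term range invalid")
        if not 0.0 <= self.planted_fraction_per_term <= 1.0:
            raise ValueError("planted_fraction_per_term must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    expression: pd.DataFrame          # genes × samples
    annotations: pd.DataFrame         # samples × (group + clinical fields)
    gene_sets: dict[str, list[str]]   # term -> member genes
    ppi_edges: list[tuple[str, str]]  # undirected edge list
    truth: dict = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort from ``config``.

    One master seed spawns independent child streams for expression, gene
    sets, the interaction graph and clinical covariates, so that adding or
    re-parameterising one component never perturbs the draws of another.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_expr, rng_sets, rng_graph, rng_clin = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    genes = _gene_names(config.n_genes)
    n_samples = config.n_control + config.n_case
    samples = [f"S{i:04d}" for i in range(n_samples)]
    group = np.array(["control"] * config.n_control + ["case"] * config.n_case)
    is_case = group == "case"

    up_genes = genes[: config.n_planted_up]
    down_genes = genes[config.n_planted_up : config.n_planted_up + config.n_planted_down]

    # Gene-specific baselines; rows are Z-scored downstream, so Gaussian
    # intensities suffice — a log-normal marginal would be standardised away.
    baseline = rng_expr.normal(loc=7.0, scale=2.0, size=config.n_genes)
    values = baseline[:, None] + rng_expr.normal(
        scale=config.noise_sd, size=(config.n_genes, n_samples)
    )
    shift = config.effect_size * config.noise_sd
    values[: config.n_planted_up, is_case] += shift
    values[config.n_planted_up : config.n_planted_up + config.n_planted_down, is_case] -= shift
    expression = pd.DataFrame(values, index=genes, columns=samples)

    gene_sets, informative_terms = _draw_gene_sets(
        config, rng_sets, genes, up_genes, down_genes
    )
    ppi_edges = _draw_ppi_edges(config, rng_graph, genes)
    annotations = _draw_annotations(config, rng_clin, samples, group)

    truth = {
        "up_genes": list(up_genes),
        "down_genes": list(down_genes),
        "informative_terms": informative_terms,
    }
    return SyntheticCohort(expression, annotations, gene_sets, ppi_edges, truth)


def _draw_gene_sets(config, rng, genes, up_genes, down_genes):
    """Informative terms mix planted genes of both directions with filler;
    the remaining terms are pure background draws.

    Each informative term draws its planted members from a single direction,
    alternating up-regulated and down-regulated terms across the collection,
    mirroring gene sets discovered by per-direction enrichment.  A term with
    planted genes on both sides carries no pathway-level signal: the squared
    deviation is direction-blind, so both sums inflate by the same factor in
    cases and the log-ratio's mean is unchanged.
    """
    n_informative = max(1, config.n_terms // 4)
    lo, hi = config.genes_per_term
    planted_pool = list(up_genes) + list(down_genes)
    background = genes[len(planted_pool):]

    gene_sets: dict[str, list[str]] = {}
    informative: list[str] = []
    for t in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        term = f"TERM{t:03d}"
        if t < n_informative and planted_pool:
            n_planted = min(
                len(planted_pool),
                max(1, int(round(config.planted_fraction_per_term * size))),
            )
            if t % 2 == 0:
                n_up = min(len(up_genes), n_planted)
                n_down = 0
            else:
                n_down = min(len(down_genes), n_planted)
                n_up = 0
            members = list(rng.choice(up_genes, size=n_up, replace=False)) + list(
                rng.choice(down_genes, size=n_down, replace=False)
            )
            n_fill = max(0, size - len(members))
            members += list(rng.choice(background, size=n_fill, replace=False))
            informative.append(term)
        else:
            members = list(rng.choice(background, size=min(size, len(background)), replace=False))
        gene_sets[term] = members
    return gene_sets, informative


def _draw_ppi_edges(config, rng, genes):
    m = min(config.graph_attach_edges, max(1, config.n_genes - 1))
    graph = nx.barabasi_albert_graph(config.n_genes, m, seed=int(rng.integers(2**31)))
    # shuffle the node→gene assignment so planted genes are not systematically hubs
    perm = rng.permutation(config.n_genes)
    relabel = {node: genes[perm[node]] for node in graph.nodes}
    return [(relabel[a], relabel[b]) for a, b in graph.edges]


def _draw_annotations(config, rng, samples, group):
    n = len(samples)
    is_case = group == "case"
    e = config.clinical_effect
    age = rng.normal(55.0, 10.0, n) + np.where(is_case, e * 10.0, 0.0)
    duration = np.clip(rng.normal(25.0, 8.0, n) + np.where(is_case, e * 8.0, 0.0), 1.0, None)
    index = np.clip(rng.normal(400.0, 150.0, n) + np.where(is_case, e * 150.0, 0.0), 10.0, None)
    gender = rng.binomial(1, 0.6, n)
    lymph_p = np.where(is_case, min(0.9, 0.1 + 0.2 * e), 0.1)
    lymphadenopathy = rng.binomial(1, lymph_p)
    nodule = np.where(is_case, np.clip(rng.normal(2.0, 0.8, n), 0.2, None), 0.0)
    return pd.DataFrame(
        {
            "group": group,
            "age": np.round(age, 1),
            "gender": gender,
            "smoking_duration": np.round(duration, 1),
            "smoking_index": np.round(index, 1),
            "nodule_size": np.round(nodule, 2),
            "lymphadenopathy": lymphadenopathy,
        },
        index=pd.Index(samples, name="sample"),
    )


# ---------------------------------------------------------------- writers

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as the pipeline's standard input files.

    Emits expression TSV (rows = genes, columns = samples), metadata CSV, a
    GMT gene-set file, a two-column edge-list TSV and a JSON truth file;
    returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.csv",
        "gene_sets": outdir / "gene_sets.gmt",
        "ppi_edges": outdir / "ppi_edges.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
    cohort.annotations.to_csv(paths["metadata"])
    with open(paths["gene_sets"], "w") as fh:
        for term, members in cohort.gene_sets.items():
            fh.write("\t".join([term, "synthetic"] + list(members)) + "\n")
    with open(paths["ppi_edges"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in cohort.ppi_edges:
            fh.write(f"{a}\t{b}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    logger.info("wrote synthetic cohort to %s", outdir)
    return paths
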