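"""Hypergeometric over-representation of DEG lists against GMT gene sets.

Up- and down-regulated DEG lists are tested separately against each gene-set
collection; the union of all significant terms forms the feature space, with
each term carrying its up- and down-regulated member genes for the deviation
score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass
class TermResult:
    term_id: str
    count: int        # overlap of the tested list with the gene set
    p_value: float    # upper-tail hypergeometric probability P(X >= count)
    source_list: str  # "up" or "down"


@dataclass
class DirectionalGeneSet:
    """Significant term with its DEG members split by direction."""

    term_id: str
    up_members: list[str] = field(default_factory=list)
    down_members: list[str] = field(default_factory=list)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT file → term → member genes (description column discarded)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def hypergeom_enrich(
    gene_list,
    background,
    gene_sets: dict[str, list[str]],
    p_max: float = 0.05,
    source_list: str = "up",
) -> list[TermResult]:
    """One-sided over-representation test of ``gene_list`` per term.

    With population N = |background|, K = |set ∩ background| successes,
    n = |gene_list| draws and observed overlap k, the p-value is the
    hypergeometric upper tail P(X ≥ k).  Terms with p < ``p_max`` are
    returned, sorted ascending by p (ties by term id).
    """
    background = set(background)
    genes = set(gene_list)
    if not background or not genes:
        raise ValueError("background and gene_list must be non-empty")
    if not genes <= background:
        raise ValueError("gene_list must be a subset of the background")
    N, n = len(background), len(genes)
    results = []
    for term, members in gene_sets.items():
        in_bg = set(members) & background
        k = len(genes & in_bg)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, len(in_bg), n))
        if p < p_max:
            results.append(TermResult(term, k, p, source_list))
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def build_feature_terms(
    up_results: list[TermResult],
    down_results: list[TermResult],
    up_degs,
    down_degs,
    gene_sets: dict[str, list[str]],
) -> dict[str, DirectionalGeneSet]:
    """Union the significant terms of both runs into the feature space.

    Every retained term carries ``up_members`` and ``down_members`` computed
    against the full up/down DEG lists, regardless of which direction's run
    made the term significant; terms found by both runs appear once.
    """
    up_degs, down_degs = set(up_degs), set(down_degs)
    feature_terms: dict[str, DirectionalGeneSet] = {}
    for res in list(up_results) + list(down_results):
        if res.term_id in feature_terms:
            continue
        members = set(gene_sets.get(res.term_id, []))
        term = DirectionalGeneSet(
            term_id=res.term_id,
            up_members=sorted(members & up_degs),
            down_members=sorted(members & down_degs),
        )
        if not term.down_members or not term.up_members:
            logger.info(
                "term %s has an empty %s side; pseudocount will apply",
                res.term_id, "down" if not term.down_members else "up",
            )
        feature_terms[res.term_id] = term
    logger.info("feature space: %d terms", len(feature_terms))
    return feature_terms


def write_term_results(results: list[TermResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tcount\tp_value\tsource_list\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.count}\t{r.p_value:.6g}\t{r.source_list}\n")
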