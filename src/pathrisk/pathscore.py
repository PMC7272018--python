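"""Functional deviation score: the per-(term, sample) pathway statistic.

For a term with up-regulated member genes i = 1..m and down-regulated member
genes j = 1..n, the score of sample s is the log-ratio of degree-weighted
squared deviations from the control-group means,

    score(P, s) = log[ (ε + Σᵢ ωᵢ (d_{i,s} − d̄ᵢ)²) /
                       (ε + Σⱼ ωⱼ (d_{j,s} − d̄ⱼ)²) ],

where d_{g,s} is the sample's (Z-scored) expression of gene g, d̄_g is the
mean of gene g over the control samples only, and ω_g is the gene's degree
in the full interaction network.  A positive score means the term's
deviation in that sample is dominated by its up-regulated members.  The
weighted deviation is a sum of squares without a square root; ε is a small
symmetric pseudocount that keeps the ratio finite when a term has no members
(or no weight) on one side, and preserves the score's antisymmetry under
swapping the up and down member lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import DirectionalGeneSet

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-8


@dataclass
class PathScoreMatrix:
    scores: pd.DataFrame        # term × sample
    control_means: pd.Series    # gene -> mean over control samples (d̄)
    epsilon: float


def _weighted_dev(expr, sample, members, control_means, weights, min_weight):
    total = 0.0
    for g in members:
        if g not in expr.index:
            logger.warning("member gene %s absent from expression matrix; skipped", g)
            continue
        w = max(float(weights.get(g, 0)), min_weight)
        if w == 0:
            continue
        dev = float(expr.at[g, sample]) - float(control_means[g])
        total += w * dev * dev
    return total


def term_score(
    expr: pd.DataFrame,
    sample: str,
    up_members,
    down_members,
    control_means,
    weights,
    epsilon: float = DEFAULT_EPSILON,
    min_weight: float = 0.0,
) -> float:
    """Score of one (term, sample) cell; natural log of the weighted ratio.

    ``min_weight`` > 0 floor-weights members absent from the interaction
    network instead of dropping their contribution (sensitivity analysis).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    up = _weighted_dev(expr, sample, up_members, control_means, weights, min_weight)
    down = _weighted_dev(expr, sample, down_members, control_means, weights, min_weight)
    # log(num) - log(den) rather than log(num/den): exact antisymmetry under
    # swapping the up and down member lists
    return float(np.log(epsilon + up) - np.log(epsilon + down))


def score_matrix(
    expr: pd.DataFrame,
    terms: dict[str, DirectionalGeneSet],
    control_ids,
    weights,
    epsilon: float = DEFAULT_EPSILON,
    min_weight: float = 0.0,
) -> PathScoreMatrix:
    """Term×sample score matrix over all samples of ``expr``.

    The reference d̄ is computed per member gene as the mean over the control
    samples only; control samples themselves are scored against it too.
    Terms with no scorable member on either side are dropped with a warning.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control_ids must be non-empty")
    missing = [s for s in control_ids if s not in expr.columns]
    if missing:
        raise ValueError(f"control samples absent from matrix: {missing[:5]}")

    control_means = expr[control_ids].mean(axis=1)
    values = expr.to_numpy(float)
    dev_sq = (values - control_means.to_numpy()[:, None]) ** 2
    gene_pos = {g: i for i, g in enumerate(expr.index)}

    rows, kept_terms = [], []
    for term_id, term in terms.items():
        if not term.up_members and not term.down_members:
            logger.warning("term %s has no members on either side; dropped", term_id)
            continue
        num = np.full(expr.shape[1], epsilon)
        den = np.full(expr.shape[1], epsilon)
        for members, acc in ((term.up_members, num), (term.down_members, den)):
            for g in members:
                if g not in gene_pos:
                    logger.warning("member gene %s absent from expression matrix; skipped", g)
                    continue
                w = max(float(weights.get(g, 0)), min_weight)
                if w > 0:
                    acc += w * dev_sq[gene_pos[g]]
        rows.append(np.log(num) - np.log(den))
        kept_terms.append(term_id)

    scores = pd.DataFrame(rows, index=kept_terms, columns=expr.columns)
    return PathScoreMatrix(scores=scores, control_means=control_means, epsilon=epsilon)
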