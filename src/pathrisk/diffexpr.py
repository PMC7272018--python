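"""Two-group differential expression with empirical-Bayes moderated t.

Per gene, the statistic is the group-mean difference divided by a shrunken
standard error: the gene's pooled residual variance s²_g (d residual degrees
of freedom) is shrunk toward a prior variance s₀² estimated across all genes,

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),

with the prior degrees of freedom d₀ and s₀² obtained by a method-of-moments
fit on the log variances (matching the scaled-F model of the classic
empirical-Bayes linear-model approach).  Two-sided p-values come from the t
distribution with d + d₀ degrees of freedom and are Benjamini–Hochberg
adjusted over all genes.  ``logFC`` is the case-minus-control difference of
group means on the analysis (Z-scored) matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def estimate_prior(variances: np.ndarray, residual_df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior df d₀, prior variance s₀²).

    Works on e_g = log(s²_g) − ψ(d/2) + log(d/2); the excess of var(e) over
    ψ′(d/2) determines d₀ via the inverse trigamma.  Returns (inf, s₀²) when
    the log-variances are under-dispersed (no evidence against a common
    variance).  Raises if no finite log variance exists.
    """
    z = np.log(variances[variances > 0])
    if z.size < 2:
        raise ValueError("too few positive gene variances to fit a prior")
    d = residual_df
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(_trigamma(d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderated_t(
    matrix: pd.DataFrame,
    labels,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group test for every gene row of ``matrix``.

    Parameters
    ----------
    matrix : gene×sample DataFrame (the Z-scored analysis matrix).
    labels : per-sample group assignment, values "case"/"control"; either a
        Series indexed by sample ID or an array in column order.
    prior_df : override the estimated prior degrees of freedom; ``0`` gives
        the ordinary pooled-variance two-sample t.

    Returns a DataFrame indexed by gene with columns ``logFC``, ``t``,
    ``p_value``, ``adj_p`` and ``direction`` (filled in by
    :func:`select_degs`; ``"none"`` here).
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    if isinstance(labels.index, pd.Index) and labels.index.inferred_type != "integer":
        missing = matrix.columns.difference(labels.index)
        if len(missing):
            raise ValueError(f"labels missing for samples: {list(missing)[:5]}")
        labels = labels.reindex(matrix.columns)
    elif len(labels) != matrix.shape[1]:
        raise ValueError("labels length does not match matrix columns")
    groups = set(labels.unique())
    if groups != {"case", "control"}:
        raise ValueError(f"labels must be 'case'/'control', got {sorted(groups)}")

    case = matrix.loc[:, (labels == "case").values].to_numpy(float)
    ctrl = matrix.loc[:, (labels == "control").values].to_numpy(float)
    n1, n0 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 samples")

    mean_diff = case.mean(axis=1) - ctrl.mean(axis=1)
    d = n1 + n0 - 2
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n0 - 1)
    s_sq = ss / d

    if prior_df is None:
        try:
            d0, s0_sq = estimate_prior(s_sq, d)
        except ValueError:
            logger.warning("prior fit failed; falling back to ordinary t")
            d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s0_sq = estimate_prior(s_sq, d)[1] if d0 > 0 else 0.0

    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d + d0

    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_diff / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "logFC": mean_diff,
            "t": t,
            "p_value": p,
            "adj_p": adj_p,
            "direction": "none",
        },
        index=matrix.index,
    )


@dataclass
class DEGSelection:
    up: list[str]
    down: list[str]
    table: pd.DataFrame  # copy of the input with the direction column filled


def select_degs(
    table: pd.DataFrame,
    adj_p_max: float = 0.01,
    abs_lfc_min: float = 0.6,
) -> DEGSelection:
    """Select DEGs by strict thresholds: adj_p < adj_p_max and |logFC| > abs_lfc_min."""
    if adj_p_max <= 0 or abs_lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    sig = table["adj_p"] < adj_p_max
    up = table.index[sig & (table["logFC"] > abs_lfc_min)].tolist()
    down = table.index[sig & (table["logFC"] < -abs_lfc_min)].tolist()
    annotated = table.copy()
    annotated["direction"] = "none"
    annotated.loc[up, "direction"] = "up"
    annotated.loc[down, "direction"] = "down"
    logger.info("selected %d up and %d down DEGs", len(up), len(down))
    return DEGSelection(up=up, down=down, table=annotated)


def write_deg_table(selection: DEGSelection, path) -> None:
    out = selection.table.rename(columns={"p_value": "p"})
    out.to_csv(path, sep="\t", index_label="gene")
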