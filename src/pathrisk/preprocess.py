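"""Probe→gene collapsing and per-gene Z-score normalisation.

The analysis matrix is a gene×sample DataFrame.  Probes mapping to the same
gene symbol are averaged; each retained gene row is then standardised to mean
0 and (sample) standard deviation 1 across samples, removing differences in
intrinsic expression level between genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CollapseResult:
    matrix: pd.DataFrame
    n_unmapped: int      # probes with no map entry
    n_multi: int         # probes mapping to multiple symbols ("///"), dropped


@dataclass
class ZScoreResult:
    matrix: pd.DataFrame
    n_zero_sd: int       # constant rows dropped


def read_probe_map(path) -> pd.Series:
    """Two-column TSV (probe ID, gene symbol) → probe-indexed Series."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path!r} needs two columns (probe, symbol)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.Series) -> CollapseResult:
    """Average probe rows that share a gene symbol.

    Probes absent from the map are dropped, as are probes whose map entry
    names several symbols (``A /// B`` style) — expanding those would count
    one measurement twice.  Column order is preserved.
    """
    probe_map = probe_map.dropna().astype(str)
    multi = probe_map.index[probe_map.str.contains("///")]
    n_multi = int(probe_matrix.index.isin(multi).sum())
    clean_map = probe_map.drop(index=multi)

    mapped = probe_matrix.index.intersection(clean_map.index)
    if len(mapped) == 0:
        raise ValueError(
            "no probe of the expression matrix is present in the probe map; "
            "check that the matrix row IDs and the map's first column agree"
        )
    n_unmapped = probe_matrix.shape[0] - len(mapped) - n_multi

    symbols = clean_map.loc[mapped].str.strip()
    collapsed = probe_matrix.loc[mapped].groupby(symbols.values, sort=True).mean()
    collapsed.index.name = "gene"
    logger.info(
        "collapsed %d probes to %d genes (%d unmapped dropped, %d multi-symbol dropped)",
        probe_matrix.shape[0], collapsed.shape[0], n_unmapped, n_multi,
    )
    return CollapseResult(collapsed, n_unmapped=n_unmapped, n_multi=n_multi)


def zscore_rows(matrix: pd.DataFrame) -> ZScoreResult:
    """Standardise each gene row: X' = (X − mean) / SD across samples.

    SD is the sample standard deviation (n−1 denominator).  Rows with zero
    SD carry no information after standardisation and are dropped.
    """
    if matrix.shape[1] < 2:
        raise ValueError("Z-scoring needs at least 2 samples")
    sd = matrix.std(axis=1, ddof=1)
    keep = sd > 0
    n_zero = int((~keep).sum())
    if n_zero:
        logger.info("dropped %d zero-variance gene rows", n_zero)
    kept = matrix.loc[keep]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[keep], axis=0)
    return ZScoreResult(z, n_zero_sd=n_zero)
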