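"""Expression analysis: FPKM, z-scaling, pattern grouping and qPCR ratios.

FPKM is fragments per kilobase of transcript per million mapped reads:
``fpkm(g, s) = counts(g, s) * 1e9 / (length(g) * total(s))``.  Heatmap-style
standardization z-scales each gene's row to mean 0 and unit (sample,
n-1) variance.  Expression patterns are grouped by cutting a UPGMA tree
built on Euclidean distances between z-scaled rows.

qPCR fold changes use the efficiency-corrected ratio
``E_target^(dCt_target) / NF`` where ``dCt = Ct(control) - Ct(treated)``
and ``NF`` is the geometric mean of the reference genes' own
``E_r^(dCt_r)`` terms.  Technical replicate Cts are arithmetic-averaged
before use; amplification efficiency defaults to a perfect doubling
(E = 2) and may be set per gene.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .msa_phylo import DistanceMatrix, cut_groups, upgma

logger = logging.getLogger(__name__)

QPCR_COLUMNS = ["gene", "sample", "replicate", "ct", "role", "efficiency"]


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         totals: pd.Series | None = None) -> pd.DataFrame:
    """FPKM matrix from raw counts (genes x samples) and lengths in bp."""
    counts = counts.astype(float)
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero library size in samples {bad}")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def drop_silent_genes(mat: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero expression in every sample (logged)."""
    silent = (mat == 0).all(axis=1)
    if silent.any():
        logger.info("dropping %d genes with zero expression in all samples: %s",
                    int(silent.sum()), ", ".join(mat.index[silent]))
    return mat.loc[~silent]


def zscale_rows(mat: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores with sample (n-1) sd; constant rows become zeros."""
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant rows z-scaled to zeros",
            stacklevel=2)
    sd = sd.replace(0, 1.0)
    return mat.sub(mean, axis=0).div(sd, axis=0)


def group_expression_patterns(zmat: pd.DataFrame, k: int = 3) -> dict[str, int]:
    """Cluster genes on Euclidean row distance (UPGMA), cut to k groups.

    Returns gene -> 1-based group number; groups are numbered by their
    smallest gene id, so the labeling is deterministic.
    """
    ids = list(zmat.index)
    if len(ids) == 1:
        return {ids[0]: 1}
    x = zmat.to_numpy()
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    tree = upgma(DistanceMatrix(ids, d))
    groups = cut_groups(tree, k)
    return {g: i for i, grp in enumerate(groups, 1) for g in grp}


# ---------------------------------------------------------------------------
# qPCR (efficiency-corrected ddCt)
# ---------------------------------------------------------------------------

def _validate_qpcr(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(QPCR_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    eff = table["efficiency"]
    if ((eff <= 1) | (eff > 2)).any():
        raise ValueError("efficiencies must lie in (1, 2]")
    return table


def _mean_ct(table: pd.DataFrame, gene: str, sample: str) -> tuple[float, float]:
    rows = table[(table["gene"] == gene) & (table["sample"] == sample)]
    if rows.empty:
        raise ValueError(f"no Ct for gene {gene!r} in sample {sample!r}")
    return float(rows["ct"].mean()), float(rows["efficiency"].iloc[0])


def ddct_ratio(table: pd.DataFrame, target: str,
               treated: str, control: str) -> float:
    """Efficiency-corrected relative expression of `target` in `treated`
    vs `control`, normalized to the geometric mean of the reference genes."""
    table = _validate_qpcr(table)
    refs = sorted(table.loc[table["role"] == "reference", "gene"].unique())
    if not refs:
        raise ValueError("no reference genes in table")
    ct_ctrl, e_t = _mean_ct(table, target, control)
    ct_trt, _ = _mean_ct(table, target, treated)
    target_term = e_t ** (ct_ctrl - ct_trt)
    log_nf = 0.0
    for r in refs:
        rc_ctrl, e_r = _mean_ct(table, r, control)
        rc_trt, _ = _mean_ct(table, r, treated)
        log_nf += (rc_ctrl - rc_trt) * math.log(e_r)
    nf = math.exp(log_nf / len(refs))
    return target_term / nf


def ddct_table(table: pd.DataFrame, control: str) -> pd.DataFrame:
    """Fold change of every target gene in every non-control sample."""
    table = _validate_qpcr(table)
    targets = sorted(table.loc[table["role"] == "target", "gene"].unique())
    samples = sorted(s for s in table["sample"].unique() if s != control)
    out = pd.DataFrame(index=targets, columns=samples, dtype=float)
    for g in targets:
        for s in samples:
            out.loc[g, s] = ddct_ratio(table, g, s, control)
    return out


def replicate_anova(table: pd.DataFrame, gene: str) -> tuple[float, float]:
    """One-way ANOVA of a gene's replicate Cts across samples -> (F, p)."""
    table = _validate_qpcr(table)
    groups = [grp["ct"].to_numpy()
              for _, grp in table[table["gene"] == gene].groupby("sample")]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two samples")
    f, p = _scipy_stats.f_oneway(*groups)
    return float(f), float(p)
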