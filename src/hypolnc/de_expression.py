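"""Negative-binomial Wald test for differential expression.

A deliberately small caller in the spirit of count-based DE methods:
median-of-ratios size factors, a gene-wise fold change on normalized
means, a method-of-moments negative-binomial dispersion, and a Wald
z-test on the log2 fold change. Genes are called up if the fold change
exceeds 2, down if it is under 0.5, in both cases requiring raw
p < 0.05 (Benjamini-Hochberg adjustment is available as an option).

Dispersion can be estimated per gene (pooled over the two contrast
groups) or shared across all genes ("pooled", the default): with two or
three replicates per group a per-gene moment estimate is so noisy that
the Wald test is anticonservative, while the across-gene estimate is
precise and matches a generative model with a common dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, norm

from .core_io import ExpressionMatrix

logger = logging.getLogger("hypolnc")

LOG2 = np.log(2.0)
PSEUDO_MEAN = 0.5  # pseudo-count on the normalized-mean scale
DISPERSION_FLOOR = 1e-8


@dataclass
class DEResult:
    transcript_id: str
    contrast: tuple
    log2fc: float
    p_value: float
    direction: str  # up | down | ns


def size_factors(counts: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Each sample's factor is the median over genes (restricted to genes
    with a nonzero geometric mean) of the ratio of the sample's count to
    the gene's geometric mean across samples. A single sample, or columns
    that are all equal, yield factors of 1.
    """
    df = counts.values if isinstance(counts, ExpressionMatrix) else counts
    mat = df.to_numpy(dtype=float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=df.columns)
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        return pd.Series(np.ones(mat.shape[1]), index=df.columns)
    ratios = np.log(mat[usable]) - log_geo[usable, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=df.columns)


def _group_columns(em: ExpressionMatrix, group: tuple[str, float]) -> list[str]:
    tissue, oxygen = group
    mask = (em.samples["tissue"] == tissue) & (
        em.samples["oxygen_pct"].astype(float) == float(oxygen))
    return list(em.samples.index[mask])


def _mom_dispersion(values: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion from residual variance around group
    means: var = m + alpha * m^2."""
    var = values.var(axis=1, ddof=1)
    m = np.maximum(means, 1e-8)
    return (var - m) / m ** 2  # may be negative; floored after pooling


def nb_wald_test(
    counts: ExpressionMatrix,
    contrast: tuple[tuple[str, float], tuple[str, float]],
    dispersion: str = "pooled",
) -> list[DEResult]:
    """Wald test of group A vs group B for every gene.

    ``contrast`` is ``((tissue, oxygen), (tissue, oxygen))``; the fold
    change is A over B on normalized counts with a 0.5 pseudo-mean.
    ``dispersion`` is ``'pooled'`` (one moment estimate shared across
    genes), ``'per-gene'``, or a fixed non-negative number used as the
    known dispersion.
    """
    group_a, group_b = contrast
    cols_a = _group_columns(counts, group_a)
    cols_b = _group_columns(counts, group_b)
    if not cols_a or not cols_b:
        missing = group_a if not cols_a else group_b
        raise ValueError(f"group {missing!r} absent from sample metadata")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each contrast group needs at least 2 replicates")

    sf = size_factors(counts.values[cols_a + cols_b])
    norm_counts = counts.values[cols_a + cols_b] / sf
    a = norm_counts[cols_a].to_numpy(dtype=float)
    b = norm_counts[cols_b].to_numpy(dtype=float)
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    n_a, n_b = a.shape[1], b.shape[1]

    # per-gene dispersion pooled across the two groups (weighted by df)
    alpha_a = _mom_dispersion(a, m_a)
    alpha_b = _mom_dispersion(b, m_b)
    alpha_gene = ((n_a - 1) * alpha_a + (n_b - 1) * alpha_b) / (n_a + n_b - 2)
    if isinstance(dispersion, (int, float)):
        if dispersion < 0:
            raise ValueError("fixed dispersion must be non-negative")
        alpha = np.full(len(alpha_gene), max(float(dispersion), DISPERSION_FLOOR))
    elif dispersion == "pooled":
        # mean of the per-gene moment estimates: with a common generative
        # dispersion this is close to unbiased, where the median of the
        # (right-skewed, few-df) per-gene estimates sits too low
        alpha = np.full_like(alpha_gene, max(float(np.mean(alpha_gene)),
                                             DISPERSION_FLOOR))
    elif dispersion == "per-gene":
        alpha = np.maximum(alpha_gene, DISPERSION_FLOOR)
    else:
        raise ValueError(f"unknown dispersion mode {dispersion!r}")

    log2fc = np.log2((m_a + PSEUDO_MEAN) / (m_b + PSEUDO_MEAN))
    var_ma = (m_a + alpha * m_a ** 2) / n_a
    var_mb = (m_b + alpha * m_b ** 2) / n_b
    se = np.sqrt(var_ma / (m_a + PSEUDO_MEAN) ** 2
                 + var_mb / (m_b + PSEUDO_MEAN) ** 2) / LOG2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2 * norm.sf(np.abs(z))

    results = []
    for tid, lfc, pv in zip(counts.transcript_ids, log2fc, p):
        fc = 2.0 ** lfc
        if fc > 2 and pv < 0.05:
            direction = "up"
        elif fc < 0.5 and pv < 0.05:
            direction = "down"
        else:
            direction = "ns"
        results.append(DEResult(tid, contrast, float(lfc), float(pv), direction))
    return results


def call_de(
    results: list[DEResult],
    fc_up: float = 2.0,
    fc_dn: float = 0.5,
    p_max: float = 0.05,
    fdr: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """Partition results into up/down/ns id lists and a per-contrast
    count summary.

    With ``fdr=True`` the p-value threshold is applied to
    Benjamini-Hochberg adjusted p-values (per contrast) instead of raw
    ones.
    """
    by_contrast: dict[tuple, list[DEResult]] = {}
    for r in results:
        by_contrast.setdefault(r.contrast, []).append(r)

    partitions: dict[tuple, dict[str, list[str]]] = {}
    rows = []
    for contrast, res in by_contrast.items():
        pvals = np.array([r.p_value for r in res])
        padj = false_discovery_control(pvals, method="bh") if fdr else pvals
        up, down = [], []
        for r, pv in zip(res, padj):
            fc = 2.0 ** r.log2fc
            if fc > fc_up and pv < p_max:
                up.append(r.transcript_id)
            elif fc < fc_dn and pv < p_max:
                down.append(r.transcript_id)
        all_de = up + down
        partitions[contrast] = {"up": up, "down": down, "all": all_de}
        rows.append({
            "contrast": f"{contrast[0]}_vs_{contrast[1]}",
            "all_de": len(all_de), "upregulated": len(up),
            "downregulated": len(down),
        })
    summary = pd.DataFrame(rows, columns=["contrast", "all_de",
                                          "upregulated", "downregulated"])
    return partitions, summary


def results_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "transcript_id": r.transcript_id,
        "group_a": str(r.contrast[0]),
        "group_b": str(r.contrast[1]),
        "log2fc": r.log2fc,
        "p_value": r.p_value,
        "direction": r.direction,
    } for r in results])
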