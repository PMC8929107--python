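"""lncRNA-mRNA co-expression network and function transfer.

Pipeline: keep transcripts whose expression variance ranks in the top
75%; compute Pearson's correlation (Pcc) for every pair on
log2(FPKM + 1); attach a p-value from Fisher's asymptotic test
(z = atanh(r), p = 2 * Phi(-|z| * sqrt(n - 3))); Bonferroni-adjust over
the tested pairs; keep edges with adjusted p below 0.05 whose r also
falls in the top or bottom 5% of all computed correlations. Functions
are transferred to a differentially expressed lncRNA from the mRNAs it
co-expresses with, and the pooled mRNA set is tested for annotation-term
enrichment with an upper-tail hypergeometric test and Benjamini-Hochberg
q-values.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom, norm

from .core_io import ExpressionMatrix

logger = logging.getLogger("hypolnc")

_ATANH_CLAMP = 1 - 1e-15


def variance_filter(matrix: ExpressionMatrix, top_frac: float = 0.75) -> ExpressionMatrix:
    """Keep the ceil(top_frac * n) transcripts with highest sample variance.

    Ties are resolved deterministically by transcript id.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    var = matrix.values.var(axis=1, ddof=1)
    k = math.ceil(top_frac * len(var))
    order = sorted(var.index, key=lambda t: (-var[t], t))
    keep = sorted(order[:k], key=list(matrix.values.index).index)
    return matrix.subset(keep)


def corr_fisher_p(x, y) -> tuple[float, float]:
    """Pearson correlation with Fisher's asymptotic two-sided p-value.

    p = 2 * Phi(-|atanh(r)| * sqrt(n - 3)). atanh is clamped at
    |r| = 1 - 1e-15; p-values underflowing to zero are reported as 0.0
    (below 1e-300).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    z = np.arctanh(np.clip(r, -_ATANH_CLAMP, _ATANH_CLAMP))
    p = float(2 * norm.sf(abs(z) * math.sqrt(len(x) - 3)))
    return r, p


def _pair_class(ca: str, cb: str) -> str:
    pair = tuple(sorted((ca, cb)))
    if pair == ("lncRNA", "lncRNA"):
        return "lncRNA-lncRNA"
    if pair == ("lncRNA", "mRNA"):
        return "lncRNA-mRNA"
    if pair == ("mRNA", "mRNA"):
        return "mRNA-mRNA"
    return f"{pair[0]}-{pair[1]}"


def build_coexpression(
    matrix: ExpressionMatrix,
    classes: dict[str, str],
    alpha: float = 0.05,
    tail_frac: float = 0.05,
    top_frac: float = 0.75,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the co-expression edge set.

    Applies the variance filter, computes all pairwise correlations
    (on log2(x+1) unless ``log_transform`` is False), Bonferroni-adjusts
    Fisher p-values over the tested pairs, and keeps edges passing both
    the adjusted-p gate and the top/bottom ``tail_frac`` Pcc quantile
    gate (quantiles taken over all tested pairs). Constant transcripts
    are skipped with a warning. Returns (edges, summary) where edges has
    one row per kept pair with canonical id order id_a < id_b.
    """
    filtered = variance_filter(matrix, top_frac)
    data = filtered.values.to_numpy(dtype=float)
    if log_transform:
        data = np.log2(data + 1.0)
    ids = list(filtered.values.index)
    n_samples = data.shape[1]
    if n_samples < 4:
        raise ValueError("need at least 4 samples for Fisher's asymptotic test")

    sd = data.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("skipping %d constant transcripts in correlation",
                       int(constant.sum()))
    keep_idx = np.nonzero(~constant)[0]
    data = data[keep_idx]
    ids = [ids[i] for i in keep_idx]
    n = len(ids)
    if n < 2:
        return (pd.DataFrame(columns=["id_a", "id_b", "r", "p_raw", "p_adj",
                                      "sign", "pair_class"]),
                pd.DataFrame(columns=["pair_class", "sign", "n_edges"]))

    rmat = np.corrcoef(data)
    iu = np.triu_indices(n, k=1)
    r = np.clip(rmat[iu], -1.0, 1.0)
    n_tests = len(r)
    z = np.arctanh(np.clip(r, -_ATANH_CLAMP, _ATANH_CLAMP))
    p_raw = 2 * norm.sf(np.abs(z) * math.sqrt(n_samples - 3))
    p_adj = np.minimum(p_raw * n_tests, 1.0)

    hi = np.quantile(r, 1 - tail_frac)
    lo = np.quantile(r, tail_frac)
    kept = (p_adj < alpha) & ((r >= hi) | (r <= lo))

    rows = []
    for flat in np.nonzero(kept)[0]:
        i, j = iu[0][flat], iu[1][flat]
        id_a, id_b = sorted((ids[i], ids[j]))
        rows.append({
            "id_a": id_a, "id_b": id_b, "r": float(r[flat]),
            "p_raw": float(p_raw[flat]), "p_adj": float(p_adj[flat]),
            "sign": "positive" if r[flat] >= 0 else "negative",
            "pair_class": _pair_class(classes.get(id_a, "unknown"),
                                      classes.get(id_b, "unknown")),
        })
    edges = pd.DataFrame(rows, columns=["id_a", "id_b", "r", "p_raw", "p_adj",
                                        "sign", "pair_class"])
    if len(edges):
        summary = (edges.groupby(["pair_class", "sign"]).size()
                   .rename("n_edges").reset_index())
    else:
        summary = pd.DataFrame(columns=["pair_class", "sign", "n_edges"])
    return edges, summary


def transfer_annotations(
    edges: pd.DataFrame,
    de_lncrna_ids: set[str] | list[str],
    term_map: dict[str, set[str]],
    classes: dict[str, str],
) -> tuple[dict[str, set[str]], set[str]]:
    """Transfer annotation terms to DE-lncRNAs from co-expressed mRNAs.

    For each DE-lncRNA, collects its mRNA partners across kept edges and
    unions their terms. Returns (per-lncRNA term sets, pooled deduplicated
    mRNA partner set for enrichment).
    """
    de_set = set(de_lncrna_ids)
    per_lnc: dict[str, set[str]] = {t: set() for t in de_set}
    pooled: set[str] = set()
    for _, row in edges.iterrows():
        for lnc, other in ((row["id_a"], row["id_b"]), (row["id_b"], row["id_a"])):
            if lnc in de_set and classes.get(other) == "mRNA":
                per_lnc[lnc] |= term_map.get(other, set())
                pooled.add(other)
    return per_lnc, pooled


def hypergeom_enrich(
    query: set[str] | list[str],
    background: set[str] | list[str],
    term_map: dict[str, set[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of annotation terms.

    For each term with K annotated genes among N background genes,
    p = P(X >= k) for k query hits out of n query genes; q is the
    Benjamini-Hochberg adjustment over tested terms. Terms absent from
    the background (K = 0) are skipped.
    """
    background = set(background)
    query = set(query) & background
    N, n = len(background), len(query)
    term_genes: dict[str, set[str]] = {}
    for gene in background:
        for term in term_map.get(gene, set()):
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        k = len(term_genes[term] & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k_hits": k, "n_query": n,
                     "K_background": K, "N_background": N, "p": p})
    df = pd.DataFrame(rows, columns=["term", "k_hits", "n_query",
                                     "K_background", "N_background", "p"])
    if len(df):
        df["q"] = false_discovery_control(df["p"].to_numpy(), method="bh")
        df = df.sort_values(["q", "p", "term"]).reset_index(drop=True)
    else:
        df["q"] = []
    return df
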