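"""Sequence and expression characterization of transcript classes.

Covers the descriptive comparisons between lncRNAs and mRNAs: GC content,
length and expression distributions, the tissue/oxygen group in which each
transcript peaks, and a Wilcoxon rank-sum test for class differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core_io import ExpressionMatrix

#: fixed group order for peak-expression tie-breaking: tissue alphabetical,
#: then oxygen ascending
def _group_sort_key(group: tuple[str, float]) -> tuple[str, float]:
    return (group[0], group[1])


def gc_content(sequence: str) -> float:
    """GC fraction: count(G + C) / count(A + T + G + C).

    N and gap characters are excluded from both numerator and denominator;
    an empty denominator raises ``ValueError``.
    """
    seq = sequence.upper().replace("U", "T")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("GC content undefined: no A/C/G/T characters")
    return gc / (gc + at)


@dataclass
class PeakAssignment:
    transcript_id: str
    peak_group: tuple[str, float]
    peak_mean_fpkm: float
    tied: bool


def peak_groups(fpkm: ExpressionMatrix) -> tuple[list[PeakAssignment], pd.DataFrame]:
    """Assign each expressed transcript to the (tissue, oxygen) group where
    its mean FPKM is highest.

    Group summary is the arithmetic mean over replicates. Transcripts with
    no nonzero value are excluded. Ties go to the first group in the fixed
    order (tissue alphabetical, oxygen ascending) and are flagged.
    Returns the assignments and a per-group count table.
    """
    groups = fpkm.groups()
    order = sorted(groups, key=_group_sort_key)
    means = pd.DataFrame(
        {str(g): fpkm.values[groups[g]].mean(axis=1) for g in order})
    assignments: list[PeakAssignment] = []
    for tid, row in means.iterrows():
        if (fpkm.values.loc[tid] == 0).all():
            continue
        best = row.max()
        winners = [g for g, name in zip(order, means.columns) if row[name] == best]
        assignments.append(PeakAssignment(str(tid), winners[0], float(best),
                                          tied=len(winners) > 1))
    counts = pd.Series([a.peak_group for a in assignments]).value_counts()
    table = pd.DataFrame({
        "group": [str(g) for g in order],
        "n_peak": [int(counts.get(g, 0)) for g in order],
    })
    return assignments, table


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses exact enumeration of all group labelings when n_x + n_y <= 12
    (correct under ties), otherwise the normal approximation with tie and
    continuity corrections. Returns ``(U, p)`` where U counts (x > y) pairs
    plus half the ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rx = ranks[:nx].sum()
    u = rx - nx * (nx + 1) / 2.0

    if nx + ny <= 12:
        # exact null distribution by enumerating which pooled values are "x"
        mean_u = nx * ny / 2.0
        obs_dev = abs(u - mean_u)
        n = nx + ny
        count = 0
        total = 0
        for idx in combinations(range(n), nx):
            ru = ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if abs(ru - mean_u) >= obs_dev - 1e-12:
                count += 1
        return u, count / total

    mean_u = nx * ny / 2.0
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    var_u = nx * ny / 12.0 * (n + 1 - tie_term)
    if var_u == 0:
        return u, 1.0
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    return u, float(2 * norm.sf(z))


def class_feature_table(records, classes: dict[str, str]) -> pd.DataFrame:
    """Per-transcript feature table (length, GC, longest ORF, class)."""
    rows = []
    for rec in records:
        rows.append({
            "transcript_id": rec.id,
            "class": classes.get(rec.id, rec.label),
            "length_nt": rec.length_nt,
            "gc_content": rec.gc_content,
            "longest_orf_nt": rec.longest_orf_nt,
        })
    return pd.DataFrame(rows)


def compare_classes(features: pd.DataFrame, column: str,
                    class_a: str = "lncRNA", class_b: str = "mRNA") -> dict:
    """Rank-sum comparison of one feature between two transcript classes."""
    a = features.loc[features["class"] == class_a, column].to_numpy()
    b = features.loc[features["class"] == class_b, column].to_numpy()
    u, p = wilcoxon_rank_sum(a, b)
    return {
        "feature": column,
        f"mean_{class_a}": float(np.mean(a)) if len(a) else math.nan,
        f"mean_{class_b}": float(np.mean(b)) if len(b) else math.nan,
        "U": u,
        "p": p,
    }
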