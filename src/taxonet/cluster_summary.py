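"""Per-sample and per-group summaries of edge-betweenness clusters.

Cluster abundance sums member-taxon relative abundances per sample (with an
"unassigned" remainder row so the rows partition each sample's total);
prevalence is the percentage of samples in which at least one member taxon
is detected; group contrasts use a Welch two-sample t-test by default.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .network import METADATA, TAXON, ClusterAssignment

__all__ = [
    "UNASSIGNED",
    "cluster_abundance",
    "cluster_prevalence",
    "GroupComparison",
    "compare_group_means",
]

UNASSIGNED = "unassigned"


def _taxon_clusters(assign: ClusterAssignment, rel: pd.DataFrame) -> dict[int, list]:
    """Cluster label → member taxon ids, validating ids against ``rel``."""
    members: dict[int, list] = {}
    for node, label in assign.labels.items():
        if assign.kinds.get(node, TAXON) == METADATA:
            continue
        if node not in rel.index:
            raise KeyError(f"taxon node {node!r} not present in the relative abundance table")
        members.setdefault(label, []).append(node)
    return members


def cluster_abundance(rel: pd.DataFrame, assign: ClusterAssignment) -> pd.DataFrame:
    """Summed relative abundance per (cluster, sample), plus a remainder row.

    Metadata nodes contribute nothing; taxa absent from every cluster fall
    into the "unassigned" row, so each sample column sums to one.
    """
    members = _taxon_clusters(assign, rel)
    rows = {}
    for label in sorted(members):
        rows[str(label)] = rel.loc[members[label]].sum(axis=0)
    out = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=rel.columns)
    out = out.reindex(columns=rel.columns, fill_value=0.0)
    assigned = out.sum(axis=0) if not out.empty else pd.Series(0.0, index=rel.columns)
    out.loc[UNASSIGNED] = 1.0 - assigned
    out.index.name = "cluster"
    return out


def cluster_prevalence(rel: pd.DataFrame, assign: ClusterAssignment) -> pd.Series:
    """Percent of samples (0-100) where any member taxon of each cluster is
    detected; a sample counts once however many members it contains."""
    members = _taxon_clusters(assign, rel)
    n_samples = rel.shape[1]
    out = {}
    for label in sorted(members):
        present = (rel.loc[members[label]] > 0).any(axis=0)
        out[str(label)] = 100.0 * present.sum() / n_samples
    return pd.Series(out, name="prevalence_pct")


class GroupComparison(NamedTuple):
    mean1: float
    mean2: float
    t: float
    df: float
    p: float


def compare_group_means(
    abund: pd.DataFrame,
    grouping: Mapping | pd.Series,
    cluster,
    g1,
    g2,
    welch: bool = True,
) -> GroupComparison:
    """Two-sample t-test of a cluster's abundance between two sample groups.

    Welch's unequal-variance test (Welch-Satterthwaite degrees of freedom)
    by default; ``welch=False`` uses the pooled-variance Student's t. Means
    are on the 0-1 proportion scale. When both groups are constant with
    equal means the test degenerates to t = 0, p = 1.
    """
    grouping = pd.Series(dict(grouping)) if not isinstance(grouping, pd.Series) else grouping
    row = abund.loc[str(cluster)]
    x1 = row[[s for s in row.index if grouping.get(s) == g1]].to_numpy(dtype=float)
    x2 = row[[s for s in row.index if grouping.get(s) == g2]].to_numpy(dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError(f"empty group: {g1!r} has {x1.size} samples, {g2!r} has {x2.size}")
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both groups need at least 2 samples")
    m1, m2 = float(x1.mean()), float(x2.mean())
    v1, v2 = float(x1.var(ddof=1)), float(x2.var(ddof=1))
    n1, n2 = x1.size, x2.size
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            if m1 == m2:
                return GroupComparison(m1, m2, 0.0, float(n1 + n2 - 2), 1.0)
            return GroupComparison(m1, m2, float(np.sign(m1 - m2)) * np.inf, float(n1 + n2 - 2), 0.0)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = (m1 - m2) / np.sqrt(se2)
    else:
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = float(n1 + n2 - 2)
        if pooled == 0:
            if m1 == m2:
                return GroupComparison(m1, m2, 0.0, df, 1.0)
            return GroupComparison(m1, m2, float(np.sign(m1 - m2)) * np.inf, df, 0.0)
        t = (m1 - m2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupComparison(m1, m2, float(t), float(df), p)
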