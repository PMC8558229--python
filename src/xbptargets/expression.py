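"""Differential-expression set logic for the XBP1s/XBP1u induction screen.

The screen compares transcriptomes of cells induced to express spliced XBP1
(the active transcription factor) and, as a control, unspliced XBP1 (which
lacks the transactivation domain). Genes passing the fold/p thresholds in
the XBP1u experiment are removed from the XBP1s candidate sets in both
directions, because any change they show can be attributed to the induction
system rather than XBP1 transcriptional activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import XbpTargetsError
from .motifs import GeneMotifReport

DE_COLUMNS = ["gene_id", "log2_fold_change", "p_value", "q_value"]


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def sorted(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class VennPartition:
    """Disjoint partition of the genes affected in either induction system."""

    xbp1s_only_up: GeneSet
    xbp1s_only_down: GeneSet
    xbp1u_only_up: GeneSet
    xbp1u_only_down: GeneSet
    shared: GeneSet

    def sets(self) -> list[GeneSet]:
        return [
            self.xbp1s_only_up,
            self.xbp1s_only_down,
            self.xbp1u_only_up,
            self.xbp1u_only_down,
            self.shared,
        ]


def select_de(
    table: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    max_p: float = 0.05,
) -> tuple[GeneSet, GeneSet]:
    """Threshold a DE table into up- and down-regulated gene sets.

    Boundary rule: |log2FC| exactly at the threshold is included; p exactly
    at ``max_p`` is excluded. The defaults (a log-fold, i.e. twofold, change
    at p < 0.05) are the screen's selection parameters.
    """
    missing = [c for c in ("gene_id", "log2_fold_change", "p_value") if c not in table.columns]
    if missing:
        raise XbpTargetsError(f"DE table lacks columns {missing}")
    passing = table[table["p_value"] < max_p]
    up = frozenset(passing.loc[passing["log2_fold_change"] >= min_abs_log2fc, "gene_id"])
    down = frozenset(passing.loc[passing["log2_fold_change"] <= -min_abs_log2fc, "gene_id"])
    return GeneSet("up", up), GeneSet("down", down)


def subtract_control(
    spliced_up: GeneSet,
    spliced_down: GeneSet,
    unspliced_up: GeneSet,
    unspliced_down: GeneSet,
) -> VennPartition:
    """Remove XBP1u-affected genes from the XBP1s sets; report the overlap.

    A gene significant in the unspliced experiment in *either* direction is
    excluded from the XBP1s-specific sets (conservative: any sensitivity to
    the induction system disqualifies it as a direct XBP1 candidate). A gene
    listed in both directions of one experiment (possible only for
    degenerate thresholds) counts as up, so the partition is disjoint for
    any input.
    """
    s_up, s_down = spliced_up.members, spliced_down.members - spliced_up.members
    u_up = unspliced_up.members
    u_down = unspliced_down.members - u_up
    s = s_up | s_down
    u = u_up | u_down
    shared = s & u
    return VennPartition(
        xbp1s_only_up=GeneSet("xbp1s_only_up", s_up - u),
        xbp1s_only_down=GeneSet("xbp1s_only_down", s_down - u),
        xbp1u_only_up=GeneSet("xbp1u_only_up", u_up - s),
        xbp1u_only_down=GeneSet("xbp1u_only_down", u_down - s),
        shared=GeneSet("shared", shared),
    )


def filter_by_motif(
    candidates: GeneSet,
    reports: list[GeneMotifReport] | dict[str, int],
    min_hits: int = 1,
    include_list: GeneSet | None = None,
) -> GeneSet:
    """Keep candidates whose promoter carries >= ``min_hits`` motif instances.

    ``include_list`` genes are retained regardless of motif count — the
    screen force-included HSPA5 and DDIT3 as previously reported XBP1
    targets even though the DDIT3 region carries no consensus instance.
    Candidates without a report are treated as 0 hits.
    """
    if isinstance(reports, dict):
        counts = reports
    else:
        counts = {r.gene_id: r.n_hits for r in reports}
    kept = {g for g in candidates.members if counts.get(g, 0) >= min_hits}
    if include_list is not None:
        kept |= include_list.members
    return GeneSet("motif_filtered", frozenset(kept))


def order_genes_for_heatmap(
    matrix: pd.DataFrame,
    linkage_method: str = "average",
    distance: str = "euclidean",
) -> list[str]:
    """Leaf order of an average-linkage tree over gene expression rows.

    ``matrix`` is genes x conditions; missing values are imputed by the row
    mean. Rows are sorted lexicographically by gene id before linkage so the
    result is deterministic for a given data set regardless of input order.
    ``distance`` is ``euclidean`` or ``one_minus_pearson``.
    """
    if matrix.empty:
        return []
    if len(matrix) == 1:
        return list(matrix.index)
    m = matrix.sort_index()
    values = m.astype(float).apply(lambda row: row.fillna(row.mean()), axis=1).values
    if distance == "euclidean":
        dist = pdist(values, metric="euclidean")
    elif distance == "one_minus_pearson":
        dist = pdist(values, metric="correlation")
    else:
        raise XbpTargetsError(f"unknown distance {distance!r}")
    if np.isnan(dist).any():
        raise XbpTargetsError("distance undefined (constant row under correlation?)")
    tree = linkage(dist, method=linkage_method)
    return [m.index[i] for i in leaves_list(tree)]


def linkage_merge_heights(
    matrix: pd.DataFrame,
    linkage_method: str = "average",
    distance: str = "euclidean",
) -> list[float]:
    """Merge heights of the agglomeration, for cross-checking orderings."""
    m = matrix.sort_index()
    values = m.astype(float).apply(lambda row: row.fillna(row.mean()), axis=1).values
    metric = "correlation" if distance == "one_minus_pearson" else distance
    tree = linkage(pdist(values, metric=metric), method=linkage_method)
    return [float(h) for h in tree[:, 2]]
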