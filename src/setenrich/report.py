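"""Plot-ready structures derived from an enrichment result table.

Three views of the significant entries (strict ``value < alpha`` cut):

* a ranked significance sub-table (for lollipop/bar charts),
* an enrichment graph whose nodes are significant entries and whose edges
  count the target genes two entries share (network view), and
* a binary membership matrix of target genes versus significant entries
  (heatmap view), annotated with each entry's significance value.

Rendering is left to the caller; these structures serialise to TSV /
edge lists directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .ora import EnrichmentQuery

__all__ = [
    "significant_table",
    "build_graph",
    "build_membership",
    "MembershipMatrix",
]


def significant_table(
    table: pd.DataFrame, column: str = "efdr", alpha: float = 0.05
) -> pd.DataFrame:
    """Rows with ``table[column] < alpha`` (strict), sorted ascending by
    that column.  ``column`` is one of the significance columns present in
    the table (``efdr``, ``p_bh``, ``p_bonferroni``, ``p_raw``, ...)."""
    if column not in table.columns:
        raise KeyError(f"column {column!r} not present in result table")
    sub = table[table[column] < alpha]
    return sub.sort_values(column, kind="stable").reset_index(drop=True)


def build_graph(
    table: pd.DataFrame,
    query: EnrichmentQuery,
    alpha: float = 0.05,
    column: str = "efdr",
) -> nx.Graph:
    """Enrichment network over significant entries.

    One node per significant entry (node attribute = its significance
    value); an edge joins two entries sharing at least one *target* gene,
    weighted by the number of such shared genes.
    """
    sig = significant_table(table, column=column, alpha=alpha)
    target = query.target_set
    graph = nx.Graph()
    entry_targets = {}
    for _, row in sig.iterrows():
        oid = row["ontology_id"]
        entry_targets[oid] = query.collection[oid].member_set & target
        graph.add_node(oid, **{column: float(row[column])})
    for a, b in combinations(entry_targets, 2):
        w = len(entry_targets[a] & entry_targets[b])
        if w >= 1:
            graph.add_edge(a, b, weight=w)
    return graph


@dataclass(frozen=True)
class MembershipMatrix:
    """Binary membership of target genes (columns) in significant entries
    (rows), with each row's significance value alongside.  Every column has
    at least one positive cell by construction."""

    matrix: pd.DataFrame
    row_scores: pd.Series


def build_membership(
    table: pd.DataFrame,
    query: EnrichmentQuery,
    alpha: float = 0.05,
    column: str = "efdr",
) -> MembershipMatrix:
    """Membership matrix behind the heatmap view (see module docstring)."""
    sig = significant_table(table, column=column, alpha=alpha)
    target = query.target_set
    row_ids = list(sig["ontology_id"])
    memberships = {
        oid: query.collection[oid].member_set & target for oid in row_ids
    }
    genes = sorted(set().union(*memberships.values())) if memberships else []
    data = [[int(g in memberships[oid]) for g in genes] for oid in row_ids]
    matrix = pd.DataFrame(data, index=row_ids, columns=genes, dtype=int)
    scores = pd.Series(
        sig[column].to_numpy(), index=row_ids, name=column, dtype=float
    )
    return MembershipMatrix(matrix=matrix, row_scores=scores)
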