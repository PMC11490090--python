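"""Hypergeometric overrepresentation analysis (ORA).

For each ontology entry the test asks whether the target set overlaps the
entry more than expected when the target is a uniform draw from the
background.  With a background of N identifiers, an entry covering K of
them and an effective target of n, the overlap k follows a hypergeometric
distribution and the reported p-value is the upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n),

equal to a one-tailed Fisher exact test on the corresponding 2x2 table.
Only overrepresentation (upper tail) is tested; depletion is out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .gmt import GeneSetCollection

__all__ = [
    "EntryCounts",
    "EnrichmentQuery",
    "validate_query",
    "hypergeom_upper_tail",
    "run_ora",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntryCounts:
    """The 2x2 contingency counts for one entry.

    k: overlap |target ∩ entry|; K: entry size within the background;
    n: effective target size; N: background size.
    """

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid counts: K={self.K}, n={self.n}, N={self.N}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"invalid overlap k={self.k} for K={self.K}, n={self.n}"
            )


@dataclass(frozen=True)
class EnrichmentQuery:
    """A validated ORA query: target ⊆ background, plus the (pre-filtered)
    collection to test.  ``background`` and ``target`` are stored as sorted
    tuples so downstream resampling has a deterministic indexing order.
    ``n_dropped`` counts target identifiers discarded for being absent from
    the background."""

    target: tuple[str, ...]
    background: tuple[str, ...]
    collection: GeneSetCollection
    n_dropped: int = 0

    @property
    def target_set(self) -> frozenset[str]:
        return frozenset(self.target)

    @property
    def background_set(self) -> frozenset[str]:
        return frozenset(self.background)

    @property
    def n(self) -> int:
        return len(self.target)

    @property
    def N(self) -> int:
        return len(self.background)


def validate_query(
    target: Iterable[str],
    background: Iterable[str],
    collection: GeneSetCollection,
) -> EnrichmentQuery:
    """Clean and validate the inputs of an ORA run.

    Duplicates are removed; target identifiers absent from the background
    are dropped with a warning (their count is recorded on the query).  An
    empty target or background after cleaning is an error.
    """
    bg = frozenset(background)
    tg = frozenset(target)
    if not bg:
        raise ValueError("background set is empty")
    effective = tg & bg
    dropped = len(tg) - len(effective)
    if dropped:
        msg = (
            f"{dropped} target identifier(s) absent from the background "
            "were dropped"
        )
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    if not effective:
        raise ValueError("target set is empty after restricting to the background")
    return EnrichmentQuery(
        target=tuple(sorted(effective)),
        background=tuple(sorted(bg)),
        collection=collection,
        n_dropped=dropped,
    )


def hypergeom_upper_tail(counts: EntryCounts) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    return float(hypergeom.sf(counts.k - 1, counts.N, counts.K, counts.n))


def run_ora(query: EnrichmentQuery) -> pd.DataFrame:
    """Test every entry of the query's collection for overrepresentation.

    Returns one row per entry, in collection order, with columns
    ``ontology_id, ontology_name, k, K, n, N, p_raw``.  Entries with zero
    overlap (or even zero background coverage) are retained with p = 1 so
    the rank universe is stable for the empirical FDR; use size filtering
    to remove them beforehand if desired.
    """
    tg = query.target_set
    bg = query.background_set
    n, N = query.n, query.N
    rows = []
    for gs in query.collection:
        covered = gs.member_set & bg
        K = len(covered)
        k = len(covered & tg)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((gs.ontology_id, gs.ontology_name, k, K, n, N, p))
    table = pd.DataFrame(
        rows, columns=["ontology_id", "ontology_name", "k", "K", "n", "N", "p_raw"]
    )
    # sf can produce tiny negative round-off; clamp into (0, 1]
    table["p_raw"] = np.clip(table["p_raw"].to_numpy(), 0.0, 1.0)
    return table
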