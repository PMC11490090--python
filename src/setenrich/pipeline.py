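"""High-level one-call pipelines combining filtering, testing and
correction — the programmatic equivalent of the command-line subcommands."""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .corrections import benjamini_hochberg, bonferroni
from .efdr import EfdrConfig, attach_efdr
from .filtering import FilterSpec, filter_collection
from .gmt import GeneSetCollection
from .ora import EnrichmentQuery, run_ora, validate_query

__all__ = ["ora_analysis"]

ORA_COLUMNS = [
    "ontology_id",
    "ontology_name",
    "k",
    "K",
    "n",
    "N",
    "p_raw",
    "p_bonferroni",
    "p_bh",
    "efdr",
]


def ora_analysis(
    collection: GeneSetCollection,
    target: Iterable[str],
    background: Iterable[str],
    min_members: int = 0,
    max_members: Optional[int] = None,
    correction: str = "all",
    resamples: int = 10_000,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, EnrichmentQuery]:
    """Filter the collection, run ORA and attach the requested corrections.

    ``correction`` is one of ``efdr``, ``bh``, ``bonferroni`` or ``all``;
    columns not requested are filled with NA so the output schema is fixed.
    Returns ``(table, query)``; the query is needed by the report builders.
    """
    if correction not in ("efdr", "bh", "bonferroni", "all"):
        raise ValueError(f"unknown correction {correction!r}")
    bg = frozenset(background)
    spec = FilterSpec(min_members=min_members, max_members=max_members)
    filtered = filter_collection(collection, spec, background=bg)
    query = validate_query(target, bg, filtered)
    table = run_ora(query)

    p = table["p_raw"].to_numpy()
    table["p_bonferroni"] = (
        bonferroni(p) if correction in ("bonferroni", "all") else pd.NA
    )
    table["p_bh"] = benjamini_hochberg(p) if correction in ("bh", "all") else pd.NA
    if correction in ("efdr", "all"):
        table = attach_efdr(table, query, EfdrConfig(resamples=resamples, seed=seed))
    else:
        table["efdr"] = pd.NA
    return table[ORA_COLUMNS], query
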