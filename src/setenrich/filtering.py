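"""Size-based filtering of ontology entries before enrichment testing.

Very small entries give unstable p-values and very large ones are rarely
interpretable, so both ends are commonly excluded (e.g. regulons with fewer
than 3 or more than 400 targets).  Bounds are inclusive: an entry is kept
when ``min_members <= size <= max_members``.

Size can be counted on the raw membership (``scope='raw'``) or after
intersecting members with the analysis background (``scope='background'``),
which is what the test statistics actually see.  When a background is
supplied the background-restricted scope is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Optional

from .gmt import GeneSetCollection

__all__ = ["FilterSpec", "filter_collection"]

SCOPE_RAW = "raw"
SCOPE_BACKGROUND = "background"


@dataclass(frozen=True)
class FilterSpec:
    """Inclusive size bounds and the scope in which size is counted.

    ``scope=None`` selects ``'background'`` when a background set is given
    to :func:`filter_collection` and ``'raw'`` otherwise.
    """

    min_members: int = 0
    max_members: Optional[int] = None
    scope: Optional[str] = None

    def __post_init__(self) -> None:
        if self.min_members < 0:
            raise ValueError("min_members must be non-negative")
        if self.max_members is not None and self.max_members < self.min_members:
            raise ValueError("min_members must not exceed max_members")
        if self.scope not in (None, SCOPE_RAW, SCOPE_BACKGROUND):
            raise ValueError(f"unknown scope {self.scope!r}")


def filter_collection(
    collection: GeneSetCollection,
    spec: FilterSpec,
    background: Optional[AbstractSet[str]] = None,
) -> GeneSetCollection:
    """Return a new collection with only the entries whose counted size lies
    within ``[spec.min_members, spec.max_members]``.

    Entry order and the input collection are untouched, so the operation is
    idempotent and narrowing the bounds can only remove entries.
    """
    scope = spec.scope
    if scope is None:
        scope = SCOPE_BACKGROUND if background is not None else SCOPE_RAW
    if scope == SCOPE_BACKGROUND and background is None:
        raise ValueError("background-restricted filtering requires a background set")

    upper = spec.max_members if spec.max_members is not None else float("inf")
    kept = []
    for gs in collection:
        if scope == SCOPE_BACKGROUND:
            size = len(gs.member_set & background)  # type: ignore[operator]
        else:
            size = len(gs)
        if spec.min_members <= size <= upper:
            kept.append(gs)
    return GeneSetCollection(sets=kept, metadata=dict(collection.metadata))
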