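"""Reading, writing and building gene-set collections in the GMT format.

GMT (Gene Matrix Transposed) stores one gene set per row of a tab-delimited
text file: an identifier, a free-text description, and the member
identifiers.  Two dialects are accepted on read:

* the MSigDB-style dialect, where members occupy the third and following
  tab-separated columns, and
* a three-column dialect where all members sit in the third column,
  separated by spaces (common for curated regulon files).

Lines starting with ``#`` are comment headers carrying collection metadata
(source, species, identifier type, ...) and are preserved on round trip.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "list_to_collection",
]

_KEY_VALUE = re.compile(r"^\s*([A-Za-z_][\w .\-]*?)\s*:\s*(.*\S)\s*$")


class GmtParseError(ValueError):
    """Raised when a GMT file violates the format contract."""


def _dedup(tokens: Iterable[str]) -> tuple[str, ...]:
    """Unique tokens, first occurrence kept. Identifiers are opaque and
    case-sensitive; no mapping or normalisation is applied."""
    return tuple(dict.fromkeys(tokens))


@dataclass(frozen=True)
class GeneSet:
    """One named set of identifiers (an ontology entry).

    ``ontology_id`` is the unique key within a collection; ``ontology_name``
    is a human-readable description; ``members`` are unique identifier
    strings in file order.
    """

    ontology_id: str
    ontology_name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ontology_id:
            raise ValueError("ontology_id must be non-empty")
        if "\t" in self.ontology_id:
            raise ValueError("ontology_id must not contain tabs")
        deduped = _dedup(self.members)
        if deduped != tuple(self.members):
            object.__setattr__(self, "members", deduped)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class GeneSetCollection:
    """Ordered collection of :class:`GeneSet` with header metadata.

    ``metadata`` holds ``key: value`` pairs parsed from ``#`` comment lines;
    free-text comments that do not match the pattern are keyed by their line
    index as ``_comment_<i>``.
    """

    sets: list[GeneSet] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gs in self.sets:
            if gs.ontology_id in seen:
                raise ValueError(f"duplicate ontology_id: {gs.ontology_id!r}")
            seen.add(gs.ontology_id)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, key: int | str) -> GeneSet:
        if isinstance(key, str):
            for gs in self.sets:
                if gs.ontology_id == key:
                    return gs
            raise KeyError(key)
        return self.sets[key]

    @property
    def ids(self) -> list[str]:
        return [gs.ontology_id for gs in self.sets]

    def member_universe(self) -> frozenset[str]:
        """Union of all member identifiers across the collection."""
        out: set[str] = set()
        for gs in self.sets:
            out.update(gs.members)
        return frozenset(out)


def _parse_row(line: str, lineno: int) -> GeneSet:
    fields = line.split("\t")
    if len(fields) < 3:
        raise GmtParseError(
            f"line {lineno}: expected at least 3 tab-separated fields, "
            f"got {len(fields)}"
        )
    if len(fields) == 3 and (" " in fields[2].strip() or not fields[2].strip()):
        members = _dedup(tok for tok in fields[2].split() if tok)
    else:
        members = _dedup(tok.strip() for tok in fields[2:] if tok.strip())
    if not members:
        raise GmtParseError(f"line {lineno}: gene set has no members")
    try:
        return GeneSet(fields[0].strip(), fields[1].strip(), members)
    except ValueError as exc:
        raise GmtParseError(f"line {lineno}: {exc}") from exc


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Both the tab dialect (members in columns 3..end) and the space dialect
    (members space-separated within column 3) are accepted; dialect is
    detected per row.  Duplicate member tokens within a row are dropped,
    keeping the first occurrence.  A duplicate ``ontology_id`` across rows
    is an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    metadata: dict[str, str] = {}
    seen_ids: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                text = line.lstrip()[1:].strip()
                m = _KEY_VALUE.match(text)
                if m:
                    metadata[m.group(1)] = m.group(2)
                else:
                    metadata[f"_comment_{lineno}"] = text
                continue
            gs = _parse_row(line, lineno)
            if gs.ontology_id in seen_ids:
                raise GmtParseError(
                    f"line {lineno}: duplicate ontology_id {gs.ontology_id!r}"
                )
            seen_ids.add(gs.ontology_id)
            sets.append(gs)
    return GeneSetCollection(sets=sets, metadata=metadata)


def write_gmt(
    collection: GeneSetCollection,
    path: str | Path,
    dialect: str = "tab",
) -> None:
    """Write a collection to a GMT file.

    ``dialect='tab'`` writes members in columns 3..end (MSigDB style);
    ``dialect='space'`` writes a single third column with space-separated
    members.  Metadata round-trips as ``#`` comment lines, so
    ``read_gmt(write_gmt(c))`` reproduces the sets, member order and
    metadata of ``c``.
    """
    if dialect not in ("tab", "space"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'tab' or 'space'")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in collection.metadata.items():
            if key.startswith("_comment_"):
                fh.write(f"# {value}\n")
            else:
                fh.write(f"# {key}: {value}\n")
        for gs in collection.sets:
            if dialect == "tab":
                fh.write("\t".join((gs.ontology_id, gs.ontology_name) + gs.members))
            else:
                fh.write(
                    f"{gs.ontology_id}\t{gs.ontology_name}\t{' '.join(gs.members)}"
                )
            fh.write("\n")


def list_to_collection(
    named_lists: Mapping[str, Sequence[str]],
) -> GeneSetCollection:
    """Build a collection from a mapping of name -> identifier list.

    Each entry becomes one gene set whose ``ontology_name`` defaults to its
    ``ontology_id``.  Duplicate identifiers within a list are deduplicated.
    """
    sets = [
        GeneSet(name, name, _dedup(members)) for name, members in named_lists.items()
    ]
    return GeneSetCollection(sets=sets)


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text identifier list (one per line, ``#`` comments and
    blank lines skipped), deduplicated preserving order."""
    out: list[str] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            tok = line.strip()
            if tok and not tok.startswith("#"):
                out.append(tok)
    return list(dict.fromkeys(out))
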