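"""Gene-set collections in GMT format.

Gene sets are named lists of gene symbols (MSigDB C2 canonical-pathway
style).  Before enrichment testing a collection is restricted to the
measured gene universe and sets that fall below a minimum size after
restriction are dropped, since the running-sum statistic is computed on
measured genes only.

Gene identity is by exact, case-sensitive symbol match; alias resolution
is an upstream concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = ["GeneSet", "GeneSetCollection", "read_gmt", "write_gmt", "restrict_and_filter"]

#: Minimum post-restriction set size used throughout the pipeline.
DEFAULT_MIN_SIZE = 10


class GmtParseError(ValueError):
    """Raised for malformed GMT lines."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: unique name, free-text description, member symbols."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of gene sets with unique names.

    ``universe`` records the gene universe the collection was last
    restricted to (None for an unrestricted collection).
    """

    sets: tuple[GeneSet, ...]
    universe: frozenset[str] | None = field(default=None)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate gene set name: {dup!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, key: int | str) -> GeneSet:
        if isinstance(key, str):
            for s in self.sets:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.sets[key]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Duplicate gene symbols within a line are deduplicated; line order is
    preserved.  A line with fewer than three tab-separated fields raises
    :class:`GmtParseError` naming the line number; duplicate set names
    raise ``ValueError``.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise GmtParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets.append(GeneSet(name=name, description=description, genes=genes))
    return GeneSetCollection(sets=tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT (genes sorted for reproducible output)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def restrict_and_filter(
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int | None = None,
) -> GeneSetCollection:
    """Intersect every set with the measured gene universe and drop small sets.

    ``min_size`` counts genes *after* intersection, matching the reference
    GSEA behaviour (statistics are computed on measured genes only).
    ``max_size`` optionally drops sets larger than a cap (no cap by default).
    Idempotent for a fixed universe and thresholds.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    kept: list[GeneSet] = []
    for s in collection:
        genes = s.genes & universe
        if len(genes) < min_size:
            continue
        if max_size is not None and len(genes) > max_size:
            continue
        kept.append(replace(s, genes=genes))
    logger.info(
        "restrict_and_filter: %d/%d sets retained (universe=%d, min_size=%d)",
        len(kept), len(collection), len(universe), min_size,
    )
    return GeneSetCollection(sets=tuple(kept), universe=universe)
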