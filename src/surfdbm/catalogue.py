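"""Surfaceome gene catalogue: the universe of surface/secreted-protein genes.

The catalogue is a 3-column TSV (gene_id, symbol, category) with a closed
category vocabulary. Filtering an expression matrix against it is the first
mining step; matching is by gene_id by default, with optional uppercase
symbol matching to bridge species naming conventions.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from surfdbm.expression import ExpressionMatrix

CATEGORIES = frozenset({"surface", "secreted", "presumptive_surface"})
SPECIES = frozenset({"mouse", "human"})

CATALOGUE_COLUMNS = ("gene_id", "symbol", "category")


class CatalogueError(ValueError):
    """Invalid surfaceome catalogue contents."""


@dataclass(frozen=True)
class SurfaceomeEntry:
    gene_id: str
    symbol: str
    category: str
    species: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise CatalogueError("gene_id must be non-empty")
        if self.category not in CATEGORIES:
            raise CatalogueError(
                f"unknown category {self.category!r} for {self.gene_id}; "
                f"allowed: {sorted(CATEGORIES)}"
            )
        if self.species not in SPECIES:
            raise CatalogueError(f"unknown species {self.species!r}; allowed: {sorted(SPECIES)}")


class SurfaceomeDB:
    """Validated collection of surfaceome entries for one species.

    Membership queries are deterministic; symbol lookups are normalized to
    uppercase so mouse-style ("Cd53") and human-style ("CD53") symbols meet.
    """

    def __init__(self, entries: Iterable[SurfaceomeEntry], species: str):
        if species not in SPECIES:
            raise CatalogueError(f"unknown species {species!r}; allowed: {sorted(SPECIES)}")
        self.species = species
        self.entries: list[SurfaceomeEntry] = list(entries)
        seen: set[str] = set()
        dups: list[str] = []
        for e in self.entries:
            if e.species != species:
                raise CatalogueError(
                    f"entry {e.gene_id} has species {e.species!r}, catalogue is {species!r}"
                )
            if e.gene_id in seen:
                dups.append(e.gene_id)
            seen.add(e.gene_id)
        if dups:
            raise CatalogueError(f"duplicate gene_id in catalogue: {sorted(set(dups))}")
        self._gene_ids = seen
        self._symbols_upper = {e.symbol.upper() for e in self.entries if e.symbol}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SurfaceomeEntry]:
        return iter(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_ids

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._gene_ids

    def has_symbol(self, symbol: str) -> bool:
        return symbol.upper() in self._symbols_upper

    @property
    def gene_ids(self) -> frozenset:
        return frozenset(self._gene_ids)


def load_surfaceome(path: str | Path, species: str) -> SurfaceomeDB:
    """Load and validate a catalogue TSV (header: gene_id, symbol, category)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[SurfaceomeEntry] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != list(CATALOGUE_COLUMNS):
            raise CatalogueError(
                f"{path}: expected header {list(CATALOGUE_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CATALOGUE_COLUMNS):
                raise CatalogueError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            try:
                entries.append(SurfaceomeEntry(row[0], row[1], row[2], species))
            except CatalogueError as exc:
                raise CatalogueError(f"{path}:{lineno}: {exc}") from None
    return SurfaceomeDB(entries, species)


def filter_to_surfaceome(
    matrix: ExpressionMatrix, db: SurfaceomeDB, on: str = "gene_id"
) -> ExpressionMatrix:
    """Row-subset of ``matrix`` to genes in the catalogue; row order preserved.

    ``on`` selects the matching key: ``"gene_id"`` (exact) or ``"symbol"``
    (matrix row names treated as symbols, uppercase-normalized). A species
    mismatch between matrix annotation and catalogue is an error; zero
    overlap yields an empty matrix with a warning.
    """
    if on not in ("gene_id", "symbol"):
        raise ValueError(f"on must be 'gene_id' or 'symbol', got {on!r}")
    if matrix.species is not None and matrix.species != db.species:
        raise CatalogueError(
            f"species mismatch: matrix is {matrix.species!r}, catalogue is {db.species!r}"
        )
    if on == "gene_id":
        keep = [g for g in matrix.gene_ids if db.has_gene(g)]
    else:
        keep = [g for g in matrix.gene_ids if db.has_symbol(g)]
    if not keep and matrix.n_genes > 0:
        warnings.warn("filter_to_surfaceome: zero overlapping genes", stacklevel=2)
    return matrix.subset_genes(keep)
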