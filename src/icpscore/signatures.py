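"""Immune-cell marker gene-set collections and GMT I/O.

Marker catalogues for tumor-infiltrating immune and stromal cell types are
distributed as GMT files (Broad format: ``name<TAB>description<TAB>gene...``).
Collections from different literature sources describing the same cell type
are merged by unioning their marker genes, mirroring how published catalogues
integrate signatures per cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "SignatureCollection",
    "read_gmt",
    "write_gmt",
    "merge_by_cell_type",
    "filter_to_universe",
]


@dataclass
class GeneSet:
    """A named marker gene set for one cell type.

    Parameters
    ----------
    cell_type:
        Label of the immune/stromal cell type (GMT set name).
    genes:
        Marker gene symbols; duplicates are collapsed.
    sources:
        Free-text provenance strings (GMT description fields).
    """

    cell_type: str
    genes: frozenset[str]
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cell_type:
            raise ValueError("cell_type must be non-empty")
        self.genes = frozenset(g.strip() for g in self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.cell_type!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


class SignatureCollection:
    """Ordered, label-unique collection of :class:`GeneSet`.

    Iteration order is input order; it is the canonical catalogue order used
    downstream for deterministic tie-breaking.
    """

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: list[GeneSet] = list(sets)
        labels = [s.cell_type for s in self.sets]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate cell_type labels: {sorted(dupes)}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, cell_type: str) -> GeneSet:
        for s in self.sets:
            if s.cell_type == cell_type:
                return s
        raise KeyError(cell_type)

    def __contains__(self, cell_type: str) -> bool:
        return any(s.cell_type == cell_type for s in self.sets)

    @property
    def cell_types(self) -> list[str]:
        return [s.cell_type for s in self.sets]

    @property
    def universe(self) -> frozenset[str]:
        """All gene symbols seen across the collection."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)

    def membership(self) -> dict[str, frozenset[str]]:
        return {s.cell_type: s.genes for s in self.sets}


def read_gmt(path: str | Path, uppercase: bool = False) -> SignatureCollection:
    """Read a GMT file into a :class:`SignatureCollection`.

    Each non-blank line must carry at least three tab-separated fields:
    set name, description, and one or more gene symbols. Duplicate genes
    within a line are collapsed; symbols are whitespace-trimmed and compared
    case-sensitively unless ``uppercase`` is set (useful when matching GEO
    and TCGA platforms whose symbol case differs).
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"({len(fields)} fields, expected >= 3)"
                )
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if uppercase:
                genes = [g.upper() for g in genes]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets.append(GeneSet(name, frozenset(genes), [desc]))
    try:
        return SignatureCollection(sets)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    """Write a collection to GMT; genes in lexicographic order for stability."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for s in collection:
            desc = ";".join(s.sources) if s.sources else "na"
            fh.write("\t".join([s.cell_type, desc, *sorted(s.genes)]) + "\n")


def merge_by_cell_type(
    collections: Sequence[SignatureCollection],
) -> SignatureCollection:
    """Union gene sets that share a cell-type label across collections.

    The output keeps first-appearance order of labels; sources are
    concatenated. This is the catalogue-integration step: signatures of the
    same cell type from different literatures are combined into one set.
    """
    if not collections:
        raise ValueError("need at least one collection to merge")
    order: list[str] = []
    genes: dict[str, set[str]] = {}
    sources: dict[str, list[str]] = {}
    for coll in collections:
        for s in coll:
            if s.cell_type not in genes:
                order.append(s.cell_type)
                genes[s.cell_type] = set()
                sources[s.cell_type] = []
            genes[s.cell_type] |= s.genes
            sources[s.cell_type].extend(s.sources)
    return SignatureCollection(
        GeneSet(ct, frozenset(genes[ct]), sources[ct]) for ct in order
    )


def filter_to_universe(
    collection: SignatureCollection,
    gene_universe: Iterable[str],
    min_coverage: float = 0.5,
) -> SignatureCollection:
    """Restrict each set to genes present on the platform.

    Sets retaining fewer than ``min_coverage`` of their genes are dropped
    (logged); a signature with most markers missing cannot be scored
    meaningfully. Raises if nothing survives, which usually indicates a gene
    identifier mismatch (e.g. symbols vs Ensembl IDs, case differences).
    """
    if not (0 < min_coverage <= 1):
        raise ValueError("min_coverage must be in (0, 1]")
    universe = frozenset(gene_universe)
    kept: list[GeneSet] = []
    for s in collection:
        retained = s.genes & universe
        frac = len(retained) / len(s.genes)
        if retained and frac >= min_coverage:
            kept.append(GeneSet(s.cell_type, retained, list(s.sources)))
        else:
            logger.warning(
                "dropping signature %r: %d/%d genes in universe (%.0f%% < %.0f%%)",
                s.cell_type, len(retained), len(s.genes),
                100 * frac, 100 * min_coverage,
            )
    if not kept:
        raise ValueError(
            "no signature retained after universe filtering; "
            "check that gene identifiers match between the expression matrix "
            "and the GMT file (symbol type, case)"
        )
    return SignatureCollection(kept)
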