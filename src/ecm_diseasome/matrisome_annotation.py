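"""Intersect gene-bearing records with the matrisome catalog.

The matrisome catalog is the screening universe: any record stream (variants,
PheWAS hits, gene-disease associations) is restricted to genes it contains
and tagged with the gene's division and category.  The composition summary
reports how much of the catalog a gene set covers, the way a two-ring
composition diagram would display it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence, TypeVar

from .data_io import ConfigurationError
from .records import (
    Category,
    Division,
    GeneDiseaseAssociation,
    MatrisomeCatalog,
    MatrisomeGene,
)

R = TypeVar("R")


@dataclass(frozen=True, slots=True)
class Annotated:
    """A record restricted to the matrisome, tagged with its annotation."""

    record: object
    division: Division
    category: Category

    @property
    def gene_symbol(self) -> str:
        return self.record.gene_symbol  # type: ignore[attr-defined]


def annotate_genes(records: Iterable[R], catalog: MatrisomeCatalog) -> list[Annotated]:
    """Keep only records whose gene is in the catalog, tagging each.

    A pure filter: output genes are a subset of the catalog, input order is
    preserved, and applying it twice equals applying it once.  Records whose
    gene attribute is already an :class:`Annotated` pass through unchanged.
    """
    if len(catalog) == 0:
        raise ConfigurationError("matrisome catalog is empty")
    out: list[Annotated] = []
    for record in records:
        if isinstance(record, Annotated):  # idempotence
            if record.gene_symbol in catalog:
                out.append(record)
            continue
        gene = catalog.get(record.gene_symbol)  # type: ignore[attr-defined]
        if gene is not None:
            out.append(Annotated(record=record, division=gene.division,
                                 category=gene.category))
    return out


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (so 32.45 -> 32.5), not banker's rounding."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(slots=True)
class CompositionSummary:
    """Division/category composition of a tagged gene set vs. the catalog."""

    total_genes: int
    catalog_size: int
    by_division: dict[str, int]
    by_category: dict[str, int]
    fraction_of_catalog: float  # percentage, one decimal, half-up

    def to_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "catalog_size": self.catalog_size,
            "by_division": dict(self.by_division),
            "by_category": dict(self.by_category),
            "fraction_of_catalog": self.fraction_of_catalog,
        }


def composition_summary(genes: Iterable[MatrisomeGene], catalog_size: int) -> CompositionSummary:
    """Summarize a set of tagged matrisome genes against the catalog size.

    ``fraction_of_catalog`` is ``100 * total / catalog_size`` rounded half-up
    to one decimal, so the full catalog is exactly 100.0.  Division counts sum
    to the total and category counts sum within their division.
    """
    if catalog_size <= 0:
        raise ConfigurationError("catalog_size must be positive")
    unique: dict[str, MatrisomeGene] = {}
    for gene in genes:
        if not isinstance(gene, MatrisomeGene):
            raise TypeError(f"untagged gene {gene!r}: composition requires MatrisomeGene")
        unique[gene.symbol] = gene
    by_division = {d.value: 0 for d in Division}
    by_category = {c.value: 0 for c in Category}
    for gene in unique.values():
        by_division[gene.division.value] += 1
        by_category[gene.category.value] += 1
    total = len(unique)
    return CompositionSummary(
        total_genes=total,
        catalog_size=catalog_size,
        by_division=by_division,
        by_category=by_category,
        fraction_of_catalog=round_half_up(100.0 * total / catalog_size, 1),
    )


@dataclass(slots=True)
class DiseaseMatrisome:
    """The matrisome part of the diseasome, merged across sources."""

    genes: set[str]
    diseases: set[str]
    associations: list[GeneDiseaseAssociation]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_pairs(self) -> int:
        return len({a.pair for a in self.associations})


def disease_matrisome(association_sets: Sequence[Iterable[GeneDiseaseAssociation]],
                      catalog: MatrisomeCatalog) -> DiseaseMatrisome:
    """Merge association sources, keep matrisome genes, dedup (gene, disease).

    Disease identity is the normalized name string, so merging is associative
    and commutative at the unique-pair level.  The first occurrence of each
    pair (in source order) is retained for provenance.
    """
    if len(catalog) == 0:
        raise ConfigurationError("matrisome catalog is empty")
    seen: set[tuple[str, str]] = set()
    merged: list[GeneDiseaseAssociation] = []
    for source_set in association_sets:
        for assoc in source_set:
            if assoc.gene_symbol not in catalog:
                continue
            if assoc.pair in seen:
                continue
            seen.add(assoc.pair)
            merged.append(assoc)
    return DiseaseMatrisome(
        genes={a.gene_symbol for a in merged},
        diseases={a.disease for a in merged},
        associations=merged,
    )
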