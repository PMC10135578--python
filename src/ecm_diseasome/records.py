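"""Shared domain types for the matrisome diseasome pipeline.

Every reader in :mod:`ecm_diseasome.data_io` normalizes its rows into one of
the record classes defined here.  Identity conventions:

* gene symbols are uppercased and whitespace-trimmed;
* disease names are lowercased, trimmed, and internal whitespace collapsed
  (the original string is kept for display on the records that carry one);
* protein-protein interaction pairs are stored with the lexicographically
  smaller symbol first, so an unordered pair has a single representation.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field


_WS = re.compile(r"\s+")


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: uppercase, surrounding whitespace removed."""
    return symbol.strip().upper()


def normalize_disease(name: str) -> str:
    """Canonical disease-name form: lowercase, trimmed, whitespace collapsed."""
    return _WS.sub(" ", name.strip()).lower()


class Division(str, enum.Enum):
    """Top-level matrisome division."""

    CORE_MATRISOME = "core_matrisome"
    MATRISOME_ASSOCIATED = "matrisome_associated"


class Category(str, enum.Enum):
    """Matrisome category; each category belongs to exactly one division."""

    COLLAGENS = "collagens"
    GLYCOPROTEINS = "glycoproteins"
    PROTEOGLYCANS = "proteoglycans"
    ECM_AFFILIATED = "ecm_affiliated"
    ECM_REGULATORS = "ecm_regulators"
    SECRETED_FACTORS = "secreted_factors"


#: The division each category belongs to.  Collagens, glycoproteins and
#: proteoglycans are the structural core; the rest are matrisome-associated.
CATEGORY_DIVISION: dict[Category, Division] = {
    Category.COLLAGENS: Division.CORE_MATRISOME,
    Category.GLYCOPROTEINS: Division.CORE_MATRISOME,
    Category.PROTEOGLYCANS: Division.CORE_MATRISOME,
    Category.ECM_AFFILIATED: Division.MATRISOME_ASSOCIATED,
    Category.ECM_REGULATORS: Division.MATRISOME_ASSOCIATED,
    Category.SECRETED_FACTORS: Division.MATRISOME_ASSOCIATED,
}


class AssociationSource(str, enum.Enum):
    """Provenance of a gene-disease association."""

    CLINVAR_LIKE = "clinvar_like"
    MONARCH_LIKE = "monarch_like"
    PHEWAS_LIKE = "phewas_like"
    RARE_DISEASE = "rare_disease"
    CURATED = "curated"


@dataclass(frozen=True, slots=True)
class MatrisomeGene:
    """One gene of the matrisome catalog (the screening universe)."""

    symbol: str
    division: Division
    category: Category

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("matrisome gene symbol must be non-empty")
        if CATEGORY_DIVISION[self.category] is not self.division:
            raise ValueError(
                f"category {self.category.value} is inconsistent with "
                f"division {self.division.value} for {self.symbol}"
            )


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One clinical variant observation."""

    gene_symbol: str
    variant_id: str
    protein_change: str | None
    condition: str
    condition_raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.gene_symbol or not self.condition:
            raise ValueError("gene_symbol and condition must be non-empty")


@dataclass(frozen=True, slots=True)
class PhewasHit:
    """One SNP-phenotype association with its p-value."""

    snp_id: str
    gene_symbol: str
    phenotype: str
    phenotype_category: str
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")


@dataclass(frozen=True, slots=True)
class GeneDiseaseAssociation:
    """A deduplicated (gene, disease) link -- one diseasome edge.

    ``disease`` holds the normalized name (the identity key); ``disease_raw``
    the original spelling for display.
    """

    gene_symbol: str
    disease: str
    source: AssociationSource
    disease_raw: str = field(default="", compare=False)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_symbol, self.disease)


@dataclass(frozen=True, slots=True)
class DrugLink:
    """A drug -> target-gene link, optionally mediated by a specific SNP."""

    drug_name: str
    target_gene: str
    snp_id: str | None = None


@dataclass(frozen=True, slots=True)
class PpiPair:
    """An unordered protein-protein interaction pair in canonical order."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-interaction not allowed: {self.gene_a}")
        if self.gene_a > self.gene_b:
            raise ValueError("PpiPair must be canonical (gene_a <= gene_b); use PpiPair.make")

    @classmethod
    def make(cls, gene_a: str, gene_b: str) -> "PpiPair":
        """Build a canonical pair from symbols in either order."""
        a, b = normalize_symbol(gene_a), normalize_symbol(gene_b)
        return cls(min(a, b), max(a, b))


class MatrisomeCatalog:
    """The matrisome gene catalog: symbol -> :class:`MatrisomeGene`.

    Iteration order is sorted by symbol so downstream outputs are
    deterministic regardless of file row order.
    """

    def __init__(self, genes: "list[MatrisomeGene] | dict[str, MatrisomeGene]"):
        if isinstance(genes, dict):
            self._genes = dict(sorted(genes.items()))
        else:
            self._genes = {g.symbol: g for g in sorted(genes, key=lambda g: g.symbol)}

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._genes

    def __iter__(self):
        return iter(self._genes.values())

    def __getitem__(self, symbol: str) -> MatrisomeGene:
        return self._genes[symbol]

    def get(self, symbol: str) -> "MatrisomeGene | None":
        return self._genes.get(symbol)

    @property
    def symbols(self) -> set[str]:
        return set(self._genes)

    def in_category(self, category: Category) -> set[str]:
        return {s for s, g in self._genes.items() if g.category is category}

    @property
    def collagens(self) -> set[str]:
        return self.in_category(Category.COLLAGENS)


@dataclass(slots=True)
class LoadReport:
    """Bookkeeping for one reader call.

    Satisfies ``rows_in == records_out + dropped + rejected``.  ``extra``
    carries dialect-specific counts, e.g. both row-level and unique-id
    polymorphism counts for variant tables.
    """

    rows_in: int = 0
    records_out: int = 0
    dropped: int = 0
    rejected: int = 0
    messages: list[str] = field(default_factory=list)
    extra: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        if self.rows_in != self.records_out + self.dropped + self.rejected:
            raise AssertionError(
                f"load report violates conservation: {self.rows_in} != "
                f"{self.records_out} + {self.dropped} + {self.rejected}"
            )

    def to_dict(self) -> dict:
        return {
            "rows_in": self.rows_in,
            "records_out": self.records_out,
            "dropped": self.dropped,
            "rejected": self.rejected,
            "messages": list(self.messages),
            "extra": dict(self.extra),
        }
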