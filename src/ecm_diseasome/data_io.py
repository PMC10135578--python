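"""Readers and writers for every record dialect the pipeline touches.

The upstream databases (ClinVar-style variant summaries, a PheWAS catalog
export, Monarch-style causal-gene tables, Orphanet-style rare-disease
extracts, drug-gene tables, PPI pair lists) are consumed through canonical
delimited-text dialects: a header row, tab-separated by default, UTF-8.  A
:class:`Dialect` maps canonical column names onto whatever a real export
calls them, so adapting a download is a configuration change, not a code
change.

Every reader returns ``(records, LoadReport)``; the report satisfies
``rows_in == records_out + dropped + rejected``.  Reading a file written by
:func:`write_association_table` reproduces the association multiset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .records import (
    CATEGORY_DIVISION,
    AssociationSource,
    Category,
    Division,
    DrugLink,
    GeneDiseaseAssociation,
    LoadReport,
    MatrisomeCatalog,
    MatrisomeGene,
    PhewasHit,
    PpiPair,
    VariantRecord,
    normalize_disease,
    normalize_symbol,
)


class FormatError(ValueError):
    """The file does not match the dialect (e.g. a mandatory column is missing)."""


class CatalogConflictError(ValueError):
    """The same gene symbol occurs with conflicting matrisome annotations."""


class ConfigurationError(ValueError):
    """A configuration value (dialect, catalog, term lists) is unusable."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping + delimiter for one input file.

    ``columns`` maps canonical names (``gene``, ``disease``, ...) to the
    actual header names in the file; canonical names absent from the mapping
    are looked up under their own name.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    delimiter: str = "\t"

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


TSV = Dialect()

# Canonical header names per dialect; optional columns in parentheses in docs.
MATRISOME_COLUMNS = ("symbol", "division", "category")
VARIANT_COLUMNS = ("gene", "variant_id", "condition")  # protein_change optional
PHEWAS_COLUMNS = ("snp", "gene", "phenotype", "category", "p")
ASSOCIATION_COLUMNS = ("gene", "disease")  # source optional
DRUG_COLUMNS = ("drug", "gene")  # snp optional
PPI_COLUMNS = ("gene_a", "gene_b")

_CATEGORY_ALIASES = {
    "collagens": Category.COLLAGENS,
    "collagen": Category.COLLAGENS,
    "glycoproteins": Category.GLYCOPROTEINS,
    "ecm glycoproteins": Category.GLYCOPROTEINS,
    "proteoglycans": Category.PROTEOGLYCANS,
    "ecm_affiliated": Category.ECM_AFFILIATED,
    "ecm-affiliated proteins": Category.ECM_AFFILIATED,
    "ecm-affiliated": Category.ECM_AFFILIATED,
    "ecm_regulators": Category.ECM_REGULATORS,
    "ecm regulators": Category.ECM_REGULATORS,
    "secreted_factors": Category.SECRETED_FACTORS,
    "secreted factors": Category.SECRETED_FACTORS,
}

_DIVISION_ALIASES = {
    "core_matrisome": Division.CORE_MATRISOME,
    "core matrisome": Division.CORE_MATRISOME,
    "matrisome_associated": Division.MATRISOME_ASSOCIATED,
    "matrisome-associated": Division.MATRISOME_ASSOCIATED,
    "matrisome associated": Division.MATRISOME_ASSOCIATED,
}


def _read_table(path: str | Path, dialect: Dialect, mandatory: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False,
                        encoding="utf-8")
    missing = [c for c in mandatory if dialect.resolve(c) not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) "
            + ", ".join(f"{c!r} (looked for {dialect.resolve(c)!r})" for c in missing)
        )
    return frame


def _cell(row, dialect: Dialect, canonical: str) -> str:
    return str(row[dialect.resolve(canonical)]).strip()


def _opt_cell(row, frame_columns, dialect: Dialect, canonical: str) -> str | None:
    col = dialect.resolve(canonical)
    if col not in frame_columns:
        return None
    value = str(row[col]).strip()
    return value or None


def read_matrisome_list(path: str | Path, dialect: Dialect = TSV) -> tuple[MatrisomeCatalog, LoadReport]:
    """Load the matrisome gene catalog.

    The division is inferred from the category when the division cell is
    empty.  Exact duplicate rows collapse silently; a symbol appearing with
    two different categories is a conflict error listing the offenders.
    """
    frame = _read_table(path, dialect, ("symbol", "category"))
    report = LoadReport(rows_in=len(frame))
    genes: dict[str, MatrisomeGene] = {}
    conflicts: list[str] = []
    for _, row in frame.iterrows():
        symbol = normalize_symbol(_cell(row, dialect, "symbol"))
        raw_category = _cell(row, dialect, "category").lower()
        if not symbol or not raw_category:
            report.dropped += 1
            continue
        category = _CATEGORY_ALIASES.get(raw_category)
        if category is None:
            report.rejected += 1
            report.messages.append(f"unknown matrisome category {raw_category!r} for {symbol}")
            continue
        division = CATEGORY_DIVISION[category]
        div_col = dialect.resolve("division")
        if div_col in frame.columns:
            raw_division = str(row[div_col]).strip().lower()
            if raw_division and _DIVISION_ALIASES.get(raw_division) is not division:
                report.rejected += 1
                report.messages.append(
                    f"division {raw_division!r} inconsistent with category "
                    f"{category.value} for {symbol}")
                continue
        gene = MatrisomeGene(symbol, division, category)
        previous = genes.get(symbol)
        if previous is None:
            genes[symbol] = gene
        elif previous == gene:
            report.dropped += 1  # exact duplicate row
        else:
            conflicts.append(f"{symbol}: {previous.category.value} vs {category.value}")
            report.rejected += 1
    if conflicts:
        raise CatalogConflictError(
            "conflicting catalog annotations: " + "; ".join(sorted(conflicts)))
    report.records_out = len(genes)
    report.check_conservation()
    return MatrisomeCatalog(genes), report


def read_variant_table(path: str | Path, dialect: Dialect = TSV) -> tuple[list[VariantRecord], LoadReport]:
    """Load clinical variant records.

    Rows with an empty gene or condition are dropped and counted.  Duplicate
    (gene, variant_id, protein_change, condition) rows are deduplicated.  The
    report's ``extra`` exposes both polymorphism counts: usable rows
    (``polymorphism_rows``) and distinct variant ids (``unique_variant_ids``).
    """
    frame = _read_table(path, dialect, ("gene", "variant_id", "condition"))
    report = LoadReport(rows_in=len(frame))
    if frame.empty:
        report.messages.append("empty input: no usable variant rows")
    seen: set[tuple] = set()
    records: list[VariantRecord] = []
    usable_rows = 0
    for _, row in frame.iterrows():
        gene = normalize_symbol(_cell(row, dialect, "gene"))
        raw_condition = _cell(row, dialect, "condition")
        if not gene or not raw_condition:
            report.dropped += 1
            continue
        usable_rows += 1
        variant_id = _cell(row, dialect, "variant_id")
        protein_change = _opt_cell(row, frame.columns, dialect, "protein_change")
        key = (gene, variant_id, protein_change, normalize_disease(raw_condition))
        if key in seen:
            report.dropped += 1
            continue
        seen.add(key)
        records.append(VariantRecord(
            gene_symbol=gene,
            variant_id=variant_id,
            protein_change=protein_change,
            condition=normalize_disease(raw_condition),
            condition_raw=raw_condition,
        ))
    report.records_out = len(records)
    report.extra["polymorphism_rows"] = usable_rows
    report.extra["unique_variant_ids"] = len({r.variant_id for r in records})
    report.check_conservation()
    if not records:
        report.messages.append("no variant records loaded")
    return records, report


def read_phewas_table(path: str | Path, dialect: Dialect = TSV) -> tuple[list[PhewasHit], LoadReport]:
    """Load PheWAS hits; p parsed from decimal or scientific notation.

    Rows whose p-value does not parse or lies outside (0, 1] are rejected and
    counted in the report.
    """
    frame = _read_table(path, dialect, PHEWAS_COLUMNS)
    report = LoadReport(rows_in=len(frame))
    hits: list[PhewasHit] = []
    for _, row in frame.iterrows():
        gene = normalize_symbol(_cell(row, dialect, "gene"))
        snp = _cell(row, dialect, "snp")
        phenotype = _cell(row, dialect, "phenotype")
        if not gene or not snp or not phenotype:
            report.dropped += 1
            continue
        raw_p = _cell(row, dialect, "p")
        try:
            p = float(raw_p)
        except ValueError:
            report.rejected += 1
            report.messages.append(f"unparseable p-value {raw_p!r} for {snp}")
            continue
        if not (0.0 < p <= 1.0):
            report.rejected += 1
            report.messages.append(f"p-value {p} outside (0, 1] for {snp}")
            continue
        hits.append(PhewasHit(
            snp_id=snp, gene_symbol=gene, phenotype=phenotype,
            phenotype_category=_cell(row, dialect, "category"), p_value=p,
        ))
    report.records_out = len(hits)
    report.check_conservation()
    return hits, report


def _read_associations(path, dialect: Dialect, default_source: AssociationSource) -> tuple[list[GeneDiseaseAssociation], LoadReport]:
    frame = _read_table(path, dialect, ASSOCIATION_COLUMNS)
    report = LoadReport(rows_in=len(frame))
    seen: set[tuple[str, str, AssociationSource]] = set()
    records: list[GeneDiseaseAssociation] = []
    for _, row in frame.iterrows():
        gene = normalize_symbol(_cell(row, dialect, "gene"))
        raw_disease = _cell(row, dialect, "disease")
        if not gene or not raw_disease:
            report.dropped += 1
            continue
        source_cell = _opt_cell(row, frame.columns, dialect, "source")
        try:
            source = AssociationSource(source_cell) if source_cell else default_source
        except ValueError:
            report.rejected += 1
            report.messages.append(f"unknown association source {source_cell!r}")
            continue
        disease = normalize_disease(raw_disease)
        key = (gene, disease, source)
        if key in seen:
            report.dropped += 1
            continue
        seen.add(key)
        records.append(GeneDiseaseAssociation(
            gene_symbol=gene, disease=disease, source=source, disease_raw=raw_disease))
    report.records_out = len(records)
    report.check_conservation()
    return records, report


def read_association_table(path: str | Path, dialect: Dialect = TSV,
                           source: AssociationSource = AssociationSource.CURATED) -> tuple[list[GeneDiseaseAssociation], LoadReport]:
    """Load gene-disease associations; (gene, disease) deduped within source."""
    return _read_associations(path, dialect, source)


def read_rare_disease_table(path: str | Path, dialect: Dialect = TSV) -> tuple[list[GeneDiseaseAssociation], LoadReport]:
    """Load rare-disease gene-disease records (Orphanet-style extract)."""
    return _read_associations(path, dialect, AssociationSource.RARE_DISEASE)


def read_drug_table(path: str | Path, dialect: Dialect = TSV) -> tuple[list[DrugLink], LoadReport]:
    """Load drug -> target-gene links; (drug, gene) pairs deduplicated."""
    frame = _read_table(path, dialect, DRUG_COLUMNS)
    report = LoadReport(rows_in=len(frame))
    seen: set[tuple[str, str]] = set()
    links: list[DrugLink] = []
    for _, row in frame.iterrows():
        drug = _cell(row, dialect, "drug")
        gene = normalize_symbol(_cell(row, dialect, "gene"))
        if not drug or not gene:
            report.dropped += 1
            continue
        if (drug, gene) in seen:
            report.dropped += 1
            continue
        seen.add((drug, gene))
        links.append(DrugLink(drug_name=drug, target_gene=gene,
                              snp_id=_opt_cell(row, frame.columns, dialect, "snp")))
    report.records_out = len(links)
    report.check_conservation()
    return links, report


def read_ppi_table(path: str | Path, dialect: Dialect = TSV) -> tuple[list[PpiPair], LoadReport]:
    """Load PPI pairs; (A, B) and (B, A) collapse to one canonical pair."""
    frame = _read_table(path, dialect, PPI_COLUMNS)
    report = LoadReport(rows_in=len(frame))
    seen: set[PpiPair] = set()
    pairs: list[PpiPair] = []
    for _, row in frame.iterrows():
        a = normalize_symbol(_cell(row, dialect, "gene_a"))
        b = normalize_symbol(_cell(row, dialect, "gene_b"))
        if not a or not b:
            report.dropped += 1
            continue
        if a == b:
            report.rejected += 1
            report.messages.append(f"self-interaction {a} rejected")
            continue
        pair = PpiPair.make(a, b)
        if pair in seen:
            report.dropped += 1
            continue
        seen.add(pair)
        pairs.append(pair)
    report.records_out = len(pairs)
    report.check_conservation()
    return pairs, report


def write_association_table(associations: Iterable[GeneDiseaseAssociation],
                            path: str | Path) -> None:
    """Write associations as the canonical TSV, stably sorted by (gene, disease)."""
    rows = sorted(associations, key=lambda a: (a.gene_symbol, a.disease, a.source.value))
    frame = pd.DataFrame(
        [(a.gene_symbol, a.disease, a.source.value) for a in rows],
        columns=["gene", "disease", "source"],
    )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")
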