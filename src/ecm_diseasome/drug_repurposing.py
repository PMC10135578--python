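"""Drug-repurposing triads: drug -> target gene -> associated diseases.

Joining a gene-disease association table with a drug-gene table yields one
repurposing candidate per (drug, gene) whose gene carries at least one
disease association.  By default the join key is the gene symbol; in strict
mode a candidate additionally requires its SNP id (when present on the drug
link) to appear among the gene's variant-bearing records, preserving
SNP-mediated linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .records import DrugLink, GeneDiseaseAssociation


@dataclass(frozen=True, slots=True)
class RepurposingCandidate:
    drug_name: str
    target_gene: str
    snp_id: str | None
    diseases: frozenset[str]

    def __post_init__(self) -> None:
        if not self.diseases:
            raise ValueError("a repurposing candidate requires >= 1 disease")


@dataclass(slots=True)
class JoinReport:
    drugs_in: int = 0
    candidates: int = 0
    drugs_without_gene_match: int = 0
    genes_without_drugs: int = 0
    gene_symbols_without_drugs: list[str] = field(default_factory=list)


def join_candidates(associations: Iterable[GeneDiseaseAssociation],
                    drugs: Iterable[DrugLink],
                    snp_ids_by_gene: dict[str, set[str]] | None = None) -> tuple[list[RepurposingCandidate], JoinReport]:
    """Join drug links onto gene-disease associations.

    One candidate per (drug, gene) with the union of that gene's diseases.
    Drugs targeting genes with no disease association, and associated genes
    no drug targets, are dropped and counted.  When ``snp_ids_by_gene`` is
    given (strict SNP mode), a drug link carrying an SNP id only joins if
    that id is among the gene's known SNPs.
    """
    disease_map: dict[str, set[str]] = {}
    for assoc in associations:
        disease_map.setdefault(assoc.gene_symbol, set()).add(assoc.disease)
    report = JoinReport()
    candidates: list[RepurposingCandidate] = []
    matched_genes: set[str] = set()
    for link in drugs:
        report.drugs_in += 1
        diseases = disease_map.get(link.target_gene)
        if not diseases:
            report.drugs_without_gene_match += 1
            continue
        if (snp_ids_by_gene is not None and link.snp_id is not None
                and link.snp_id not in snp_ids_by_gene.get(link.target_gene, set())):
            report.drugs_without_gene_match += 1
            continue
        matched_genes.add(link.target_gene)
        candidates.append(RepurposingCandidate(
            drug_name=link.drug_name, target_gene=link.target_gene,
            snp_id=link.snp_id, diseases=frozenset(diseases)))
    unmatched = sorted(set(disease_map) - matched_genes)
    report.genes_without_drugs = len(unmatched)
    report.gene_symbols_without_drugs = unmatched
    report.candidates = len(candidates)
    candidates.sort(key=lambda c: (c.target_gene, c.drug_name))
    return candidates, report


@dataclass(slots=True)
class CandidateSummary:
    n_drugs: int
    n_genes: int
    diseases_per_gene: dict[str, int]


def summarize_candidates(candidates: Iterable[RepurposingCandidate]) -> CandidateSummary:
    """Unique drug and gene counts plus the disease-set size per gene."""
    drugs: set[str] = set()
    per_gene: dict[str, set[str]] = {}
    for cand in candidates:
        drugs.add(cand.drug_name)
        per_gene.setdefault(cand.target_gene, set()).update(cand.diseases)
    return CandidateSummary(
        n_drugs=len(drugs),
        n_genes=len(per_gene),
        diseases_per_gene={g: len(d) for g, d in sorted(per_gene.items())},
    )


def candidates_to_frame(candidates: Iterable[RepurposingCandidate]) -> pd.DataFrame:
    rows = [(c.drug_name, c.target_gene, c.snp_id or "",
             len(c.diseases), ";".join(sorted(c.diseases)))
            for c in candidates]
    return pd.DataFrame(rows, columns=["drug", "gene", "snp", "n_diseases", "diseases"])
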