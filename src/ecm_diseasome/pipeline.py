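"""End-to-end orchestration: read -> annotate -> analyze -> report.

Stage order: read every input, annotate gene-bearing records against the
matrisome catalog, then run the per-branch analyses (variants, PheWAS,
associations, rare diseases, PPI screen), categorize diseases, build the
bipartite network, join repurposing candidates, and assemble one
:class:`PipelineReport`.  A failure in any stage aborts with the stage name
attached; the report re-asserts the conservation identities of the upstream
stages.  Identical inputs and config produce byte-identical report JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import data_io, diseasome_network, drug_repurposing, phewas_analysis, variant_analysis
from .disease_categorization import CategoryTerms, categorize_disease, category_counts, default_terms, load_terms
from .matrisome_annotation import annotate_genes, composition_summary, disease_matrisome
from .records import AssociationSource, Category, GeneDiseaseAssociation


class StageError(RuntimeError):
    """An error raised by one pipeline stage, named for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and knobs for one run.  All inputs are canonical-dialect TSVs."""

    matrisome: str | Path
    variants: str | Path | None = None
    phewas: str | Path | None = None
    associations: str | Path | None = None
    rare_diseases: str | Path | None = None
    drugs: str | Path | None = None
    ppi: str | Path | None = None
    terms_path: str | Path | None = None  # JSON with lists A, B, C
    alpha: float = 1e-6  # PheWAS significance threshold
    top_n: int = 1000  # PheWAS top-hit count
    label_threshold: float = 1e-5
    substitutions_collagen_only: bool = True
    cluster_cut: float = 0.5

    def terms(self) -> CategoryTerms:
        return load_terms(self.terms_path) if self.terms_path else default_terms()


@dataclass
class PipelineReport:
    """Everything one run computed, JSON-serializable and deterministic."""

    load_reports: dict = field(default_factory=dict)
    composition: dict = field(default_factory=dict)
    disease_matrisome: dict = field(default_factory=dict)
    variants: dict = field(default_factory=dict)
    phewas: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    ppi: dict = field(default_factory=dict)
    repurposing: dict = field(default_factory=dict)
    rare: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "load_reports": self.load_reports,
            "composition": self.composition,
            "disease_matrisome": self.disease_matrisome,
            "variants": self.variants,
            "phewas": self.phewas,
            "categories": self.categories,
            "network": self.network,
            "ppi": self.ppi,
            "repurposing": self.repurposing,
            "rare": self.rare,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    report = PipelineReport()

    catalog, cat_report = _stage("read_matrisome")(
        data_io.read_matrisome_list, config.matrisome)
    report.load_reports["matrisome"] = cat_report.to_dict()

    variants, phewas_hits, associations, rare = [], [], [], []
    ppi_pairs = []
    if config.variants:
        variants, rep = _stage("read_variants")(data_io.read_variant_table, config.variants)
        report.load_reports["variants"] = rep.to_dict()
    if config.phewas:
        phewas_hits, rep = _stage("read_phewas")(data_io.read_phewas_table, config.phewas)
        report.load_reports["phewas"] = rep.to_dict()
    if config.associations:
        associations, rep = _stage("read_associations")(
            data_io.read_association_table, config.associations)
        report.load_reports["associations"] = rep.to_dict()
    if config.rare_diseases:
        rare, rep = _stage("read_rare")(data_io.read_rare_disease_table, config.rare_diseases)
        report.load_reports["rare_diseases"] = rep.to_dict()
    if config.ppi:
        ppi_pairs, rep = _stage("read_ppi")(data_io.read_ppi_table, config.ppi)
        report.load_reports["ppi"] = rep.to_dict()
    drugs = []
    if config.drugs:
        drugs, rep = _stage("read_drugs")(data_io.read_drug_table, config.drugs)
        report.load_reports["drugs"] = rep.to_dict()

    # --- annotate + variant branch ---------------------------------------
    annotated_variants = _stage("annotate_variants")(annotate_genes, variants, catalog)
    matrisome_variants = [a.record for a in annotated_variants]
    per_disease = _stage("variants_per_disease")(
        variant_analysis.variants_per_disease, matrisome_variants)
    gene_filter = None
    if config.substitutions_collagen_only:
        collagens = catalog.in_category(Category.COLLAGENS)
        gene_filter = collagens.__contains__
    matrix = _stage("substitution_matrix")(
        variant_analysis.substitution_matrix, matrisome_variants, gene_filter)
    report.variants = {
        "matrisome_records": len(matrisome_variants),
        "matrisome_unique_genes": len({r.gene_symbol for r in matrisome_variants}),
        "per_disease_unique_variants": {
            row.disease: int(row.n_variants) for row in per_disease.itertuples()},
        "substitution_total": matrix.total,
        "substitution_ref_ranking": [
            code for code, count in variant_analysis.rank_substituted(matrix) if count],
        "gly_target_ranking": [
            code for code, count in variant_analysis.rank_targets(matrix, "Gly") if count],
    }

    # --- PheWAS branch -----------------------------------------------------
    annotated_hits = _stage("annotate_phewas")(annotate_genes, phewas_hits, catalog)
    matrisome_hits = [a.record for a in annotated_hits]
    top = _stage("phewas_top_hits")(
        phewas_analysis.top_hits, matrisome_hits, config.top_n, config.alpha) \
        if matrisome_hits else []
    report.phewas = {
        "matrisome_rows": len(matrisome_hits),
        "matrisome_unique_snps": len({h.snp_id for h in matrisome_hits}),
        "top_hits": len(top),
        "top_hit_unique_genes": len({h.gene_symbol for h in top}),
    }

    # --- association merge + composition -----------------------------------
    variant_assocs = [
        GeneDiseaseAssociation(gene_symbol=v.gene_symbol, disease=v.condition,
                               source=AssociationSource.CLINVAR_LIKE)
        for v in matrisome_variants]
    merged = _stage("disease_matrisome")(
        disease_matrisome, [associations, rare, variant_assocs], catalog)
    report.disease_matrisome = {
        "n_genes": merged.n_genes,
        "n_diseases": merged.n_diseases,
        "n_pairs": merged.n_pairs,
    }
    tagged = [catalog[s] for s in sorted(merged.genes)]
    report.composition = composition_summary(tagged, len(catalog)).to_dict() \
        if tagged else composition_summary([], len(catalog)).to_dict()

    # --- categorization ------------------------------------------------------
    terms = _stage("load_terms")(config.terms)
    assignments = [categorize_disease(d, terms) for d in sorted(merged.diseases)]
    table, marginals = _stage("category_counts")(category_counts, assignments, "by_disease")
    assert int(table["count"].sum()) == len(assignments), "category partition violated"
    report.categories = {
        "label_counts": {row.label: int(row.count) for row in table.itertuples()},
        "marginals": marginals,
    }

    # --- network -------------------------------------------------------------
    graph, build_report = _stage("build_bipartite")(
        diseasome_network.build_bipartite, merged.associations)
    gpd = diseasome_network.genes_per_disease(graph)
    dpg = diseasome_network.diseases_per_gene(graph)
    assert int(gpd["degree"].sum()) == graph.number_of_edges() == int(dpg["degree"].sum())
    report.network = {
        "n_gene_nodes": len(diseasome_network.gene_nodes(graph)),
        "n_disease_nodes": len(diseasome_network.disease_nodes(graph)),
        "n_edges": graph.number_of_edges(),
        "rejected": build_report.rejected,
        "genes_per_disease": {row.disease: int(row.degree) for row in gpd.itertuples()},
        "diseases_per_gene": {row.gene: int(row.degree) for row in dpg.itertuples()},
    }
    collagen_graph = diseasome_network.collagen_subnetwork(graph, catalog)
    if diseasome_network.gene_nodes(collagen_graph):
        clusters = _stage("shared_disease_clusters")(
            diseasome_network.shared_disease_clusters, collagen_graph, config.cluster_cut)
        report.network["collagen_clusters"] = clusters
        report.network["collagen_n_genes"] = len(diseasome_network.gene_nodes(collagen_graph))

    # --- PPI screen ----------------------------------------------------------
    screen = _stage("matrisome_ppi_pairs")(
        diseasome_network.matrisome_ppi_pairs, ppi_pairs, catalog)
    report.ppi = {"matrisome_pairs": screen.n_pairs, "unique_genes": screen.n_genes}

    # --- repurposing ---------------------------------------------------------
    candidates, join_report = _stage("join_candidates")(
        drug_repurposing.join_candidates, merged.associations, drugs)
    summary = drug_repurposing.summarize_candidates(candidates)
    report.repurposing = {
        "candidates": join_report.candidates,
        "n_drugs": summary.n_drugs,
        "n_genes": summary.n_genes,
        "diseases_per_gene": summary.diseases_per_gene,
        "drugs_without_gene_match": join_report.drugs_without_gene_match,
    }

    # --- rare-disease linkage -------------------------------------------------
    annotated_rare = _stage("annotate_rare")(annotate_genes, rare, catalog)
    rare_records = [a.record for a in annotated_rare]
    report.rare = {
        "matrisome_genes": len({r.gene_symbol for r in rare_records}),
        "unique_rare_diseases": len({r.disease for r in rare_records}),
    }
    return report


def write_report(report: PipelineReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json(), encoding="utf-8")
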