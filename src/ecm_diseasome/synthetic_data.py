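"""Synthetic inputs with planted, machine-readable ground truth.

Real runs of this pipeline consume database exports (clinical variant
summaries, PheWAS catalog rows, causal-gene tables, rare-disease extracts,
drug-gene tables, PPI lists).  Those snapshots are large, versioned, and not
redistributable, so the test bed instead *generates* all seven canonical
dialects from a seeded configuration and records a ground-truth manifest of
every quantity the pipeline computes -- realized counts from the emitted
rows, not expectations, so counting stages can be checked exactly.

What is emulated: the record schemas, gene-symbol overlap structure between
tables, a planted glycine-dominant substitution spectrum, skewed
variant-per-disease allocation, category terms embedded in disease names,
and log-uniform PheWAS p-values.  What is not: linkage disequilibrium,
allele frequencies, phenotype ontologies, or realistic gene nomenclature.
"""

from __future__ import annotations

import dataclasses
import json
import os
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ConfigurationError
from .disease_categorization import DEFAULT_TERMS, default_terms, categorize_disease
from .records import CATEGORY_DIVISION, Category
from .variant_analysis import AA_3TO1, parse_protein_change

#: Category proportions of the published 1027-gene human matrisome
#: (44 collagens, 195 glycoproteins, 35 proteoglycans; 171 ECM-affiliated,
#: 238 ECM regulators, 344 secreted factors).
NABA_CATEGORY_PROPORTIONS: dict[str, float] = {
    "collagens": 44 / 1027,
    "glycoproteins": 195 / 1027,
    "proteoglycans": 35 / 1027,
    "ecm_affiliated": 171 / 1027,
    "ecm_regulators": 238 / 1027,
    "secreted_factors": 344 / 1027,
}

#: Planted substitution spectrum: glycine carries most of the mass and
#: Gly->Arg is the single largest cell, followed by Asp, Ser, Val; proline
#: and arginine rows come next -- the qualitative collagen-helix pattern.
DEFAULT_SUBSTITUTION_DISTRIBUTION: dict[tuple[str, str], float] = {
    ("Gly", "Arg"): 0.25,
    ("Gly", "Asp"): 0.15,
    ("Gly", "Ser"): 0.12,
    ("Gly", "Val"): 0.08,
    ("Pro", "Leu"): 0.08,
    ("Pro", "Ser"): 0.07,
    ("Pro", "Ala"): 0.05,
    ("Arg", "Cys"): 0.07,
    ("Arg", "His"): 0.05,
    ("Ala", "Thr"): 0.05,
    ("Ser", "Phe"): 0.03,
}

PHENOTYPE_CATEGORIES = (
    "circulatory system", "endocrine/metabolic", "musculoskeletal",
    "neurological", "sense organs", "respiratory", "dermatologic",
    "genitourinary", "digestive", "mental disorders",
)


@dataclass
class GeneratorConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    Defaults are the standard study conditions of the test bed: a
    2000-gene universe with a 25% matrisome share (inflated relative to the
    genome so every stage sees hundreds of matrisome records at desk scale),
    category proportions matching the published matrisome composition, 5000
    variant rows, 10000 PheWAS hits, and 800 diseases.
    """

    seed: int
    n_genes: int = 2000
    matrisome_fraction: float = 0.25
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(NABA_CATEGORY_PROPORTIONS))
    # variants
    n_variants: int = 5000
    missense_fraction: float = 0.7
    substitution_distribution: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION_DISTRIBUTION))
    n_duplicate_variants: int = 50
    variant_matrisome_fraction: float = 0.6
    variant_id_reuse_rate: float = 0.1
    # diseases
    n_diseases: int = 800
    term_insertion_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.15, "B": 0.20, "C": 0.30})
    # phewas
    n_phewas: int = 10000
    phewas_matrisome_fraction: float = 0.4
    p_log10_range: tuple[float, float] = (-12.0, 0.0)
    n_invalid_p: int = 25
    # associations
    n_associations: int = 3000
    association_matrisome_fraction: float = 0.5
    # drugs
    n_drug_links: int = 200
    # ppi
    n_ppi: int = 1000
    ppi_matrisome_fraction: float = 0.4
    # rare diseases
    n_rare: int = 500
    n_rare_diseases: int = 300
    rare_matrisome_fraction: float = 0.5

    def validate(self) -> None:
        fractions = {
            "matrisome_fraction": self.matrisome_fraction,
            "missense_fraction": self.missense_fraction,
            "variant_matrisome_fraction": self.variant_matrisome_fraction,
            "variant_id_reuse_rate": self.variant_id_reuse_rate,
            "phewas_matrisome_fraction": self.phewas_matrisome_fraction,
            "association_matrisome_fraction": self.association_matrisome_fraction,
            "ppi_matrisome_fraction": self.ppi_matrisome_fraction,
            "rare_matrisome_fraction": self.rare_matrisome_fraction,
            **{f"term_insertion_probs[{k}]": v for k, v in self.term_insertion_probs.items()},
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        for label, dist in (("category_proportions", self.category_proportions.values()),
                            ("substitution_distribution", self.substitution_distribution.values())):
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ConfigurationError(f"{label} must sum to 1")
        if any(ref == alt for ref, alt in self.substitution_distribution):
            raise ConfigurationError("substitution_distribution may not contain ref == alt")
        unknown = set(self.category_proportions) - {c.value for c in Category}
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")


def _allocate_counts(total: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation so integer counts sum exactly to total."""
    keys = sorted(proportions)
    raw = {k: total * proportions[k] for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    remainder = total - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))[:remainder]:
        counts[k] += 1
    return counts


class SyntheticDataset:
    """Paths of the generated files plus the parsed manifest."""

    def __init__(self, outdir: Path, manifest: dict):
        self.outdir = Path(outdir)
        self.manifest = manifest

    def path(self, name: str) -> Path:
        return self.outdir / name

    @property
    def matrisome(self) -> Path: return self.path("matrisome.tsv")
    @property
    def variants(self) -> Path: return self.path("variants.tsv")
    @property
    def phewas(self) -> Path: return self.path("phewas.tsv")
    @property
    def associations(self) -> Path: return self.path("associations.tsv")
    @property
    def drugs(self) -> Path: return self.path("drugs.tsv")
    @property
    def ppi(self) -> Path: return self.path("ppi.tsv")
    @property
    def rare(self) -> Path: return self.path("rare_diseases.tsv")


def generate(config: GeneratorConfig, outdir: str | Path) -> SyntheticDataset:
    """Emit all seven canonical dialect files plus ``manifest.json``.

    Every stochastic choice is drawn from one seeded stream, so the same
    config and seed reproduce the files byte-identically.  The manifest is
    written last, atomically, and records realized counts obtained by
    re-scanning the emitted rows.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed}

    def pick(pool, fallback):
        chosen = pool if len(pool) else fallback
        return str(rng.choice(chosen))

    # --- gene universe and matrisome catalog -----------------------------
    n_matrisome = int(round(config.n_genes * config.matrisome_fraction))
    matrisome_symbols = [f"MG{i:05d}" for i in range(n_matrisome)]
    other_symbols = [f"NG{i:05d}" for i in range(config.n_genes - n_matrisome)]
    all_symbols = matrisome_symbols + other_symbols
    cat_counts = _allocate_counts(n_matrisome, config.category_proportions)
    categories: dict[str, str] = {}
    cursor = 0
    for cat in sorted(cat_counts):
        for symbol in matrisome_symbols[cursor:cursor + cat_counts[cat]]:
            categories[symbol] = cat
        cursor += cat_counts[cat]
    catalog_rows = [(s, CATEGORY_DIVISION[Category(categories[s])].value, categories[s])
                    for s in matrisome_symbols]
    pd.DataFrame(catalog_rows, columns=["symbol", "division", "category"]).to_csv(
        outdir / "matrisome.tsv", sep="\t", index=False)
    collagen_genes = sorted(s for s, c in categories.items() if c == "collagens")
    manifest["matrisome"] = {
        "n_genes_universe": config.n_genes,
        "n_matrisome": n_matrisome,
        "category_counts": cat_counts,
        "n_collagens": len(collagen_genes),
    }

    # --- disease names with planted category memberships ------------------
    term_lists = {k: list(DEFAULT_TERMS[k]) for k in ("A", "B", "C")}
    diseases: list[str] = []
    memberships: dict[str, str] = {}
    for i in range(config.n_diseases):
        members = [k for k in ("A", "B", "C")
                   if rng.random() < config.term_insertion_probs[k]]
        parts = [str(rng.choice(term_lists[k])) for k in members]
        name = " ".join(parts + [f"synthetic condition {i:04d}"])
        diseases.append(name)
        memberships[name] = "_".join(members) if members else "uncategorized"
        assigned = categorize_disease(name, default_terms())
        assert assigned.label == memberships[name], "planted membership violated"
    manifest["categories"] = {
        "memberships": memberships,
        "marginals_by_disease": {
            k: sum(1 for m in memberships.values() if k in m.split("_"))
            for k in ("A", "B", "C")},
    }
    # Skewed disease weights: low-index diseases absorb most variants.
    weights = 1.0 / (np.arange(config.n_diseases) + 1.0)
    weights /= weights.sum()

    # --- clinical variant table -------------------------------------------
    subs = sorted(config.substitution_distribution.items())
    sub_pairs = [pair for pair, _ in subs]
    sub_probs = np.array([p for _, p in subs])
    sub_probs = sub_probs / sub_probs.sum()
    non_missense_forms = ("p.{r}{p}=", "p.{r}{p}Ter", "p.{r}{p}fs",
                          "p.{r}{p}del", "p.{r}{p}dup", "")
    n_base = config.n_variants - config.n_duplicate_variants
    rows: list[tuple[str, str, str, str]] = []
    for i in range(n_base):
        is_missense = rng.random() < config.missense_fraction
        if is_missense:
            # Missense rows land mostly on collagens so the collagen-filtered
            # matrix carries the planted spectrum.
            u = rng.random()
            if u < 0.5 and collagen_genes:
                gene = pick(collagen_genes, other_symbols)
            elif u < 0.8:
                gene = pick(matrisome_symbols, other_symbols)
            else:
                gene = pick(other_symbols, matrisome_symbols)
            ref, alt = sub_pairs[int(rng.choice(len(sub_pairs), p=sub_probs))]
            position = int(rng.integers(1, 1500))
            style = rng.random()
            if style < 0.7:
                change = f"p.{ref}{position}{alt}"
            elif style < 0.85:
                change = f"{AA_3TO1[ref]}{position}{AA_3TO1[alt]}"
            else:
                change = f"{ref}{position}{alt}"
        else:
            gene = pick(matrisome_symbols, other_symbols) \
                if rng.random() < config.variant_matrisome_fraction \
                else pick(other_symbols, matrisome_symbols)
            form = non_missense_forms[int(rng.integers(len(non_missense_forms)))]
            change = form.format(r="Arg", p=int(rng.integers(1, 1500))) if form else ""
        disease = diseases[int(rng.choice(config.n_diseases, p=weights))]
        if i > 0 and rng.random() < config.variant_id_reuse_rate:
            variant_id = rows[int(rng.integers(len(rows)))][1]
        else:
            variant_id = f"rs{1000000 + i}"
        rows.append((gene, variant_id, change, disease))
    dup_idx = rng.choice(n_base, size=config.n_duplicate_variants, replace=False)
    rows.extend(rows[int(i)] for i in dup_idx)
    order = rng.permutation(len(rows))
    variant_frame = pd.DataFrame([rows[int(i)] for i in order],
                                 columns=["gene", "variant_id", "protein_change", "condition"])
    variant_frame.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    manifest["variants"] = _recount_variants(rows, set(matrisome_symbols),
                                             set(collagen_genes),
                                             config.n_duplicate_variants)

    # --- PheWAS table ------------------------------------------------------
    lo, hi = config.p_log10_range
    phewas_rows: list[tuple[str, str, str, str, str]] = []
    for i in range(config.n_phewas):
        gene = pick(matrisome_symbols, other_symbols) \
            if rng.random() < config.phewas_matrisome_fraction \
            else pick(other_symbols, matrisome_symbols)
        p = 10.0 ** rng.uniform(lo, hi)
        phewas_rows.append((f"rs{2000000 + i}", gene, f"phenotype {int(rng.integers(500)):03d}",
                            PHENOTYPE_CATEGORIES[int(rng.integers(len(PHENOTYPE_CATEGORIES)))],
                            f"{p:.6g}"))
    for i in range(config.n_invalid_p):
        phewas_rows.append((f"rsbad{i}", str(rng.choice(all_symbols)),
                            "invalid phenotype", "none", f"{rng.uniform(1.0001, 10):.4f}"))
    p_order = rng.permutation(len(phewas_rows))
    pd.DataFrame([phewas_rows[int(i)] for i in p_order],
                 columns=["snp", "gene", "phenotype", "category", "p"]).to_csv(
        outdir / "phewas.tsv", sep="\t", index=False)
    valid = [r for r in phewas_rows if float(r[4]) <= 1.0]
    matrisome_hits = [r for r in valid if r[1] in set(matrisome_symbols)]
    manifest["phewas"] = {
        "rows_written": len(phewas_rows),
        "invalid_p_rows": config.n_invalid_p,
        "valid_rows": len(valid),
        "matrisome_rows": len(matrisome_hits),
        "matrisome_unique_snps": len({r[0] for r in matrisome_hits}),
    }

    # --- gene-disease associations ----------------------------------------
    pairs: set[tuple[str, str]] = set()
    assoc_rows: list[tuple[str, str, str]] = []
    attempts = 0
    while len(assoc_rows) < config.n_associations and attempts < 50 * config.n_associations:
        attempts += 1
        gene = pick(matrisome_symbols, other_symbols) \
            if rng.random() < config.association_matrisome_fraction \
            else pick(other_symbols, matrisome_symbols)
        disease = diseases[int(rng.choice(config.n_diseases, p=weights))]
        if (gene, disease.lower()) in pairs:
            continue
        pairs.add((gene, disease.lower()))
        assoc_rows.append((gene, disease, "curated"))
    pd.DataFrame(assoc_rows, columns=["gene", "disease", "source"]).to_csv(
        outdir / "associations.tsv", sep="\t", index=False)
    manifest["associations"] = _recount_associations(assoc_rows, set(matrisome_symbols))

    # --- rare diseases -----------------------------------------------------
    rare_names = [f"rare synthetic disease {i:03d}" for i in range(config.n_rare_diseases)]
    rare_pairs: set[tuple[str, str]] = set()
    rare_rows: list[tuple[str, str]] = []
    attempts = 0
    while len(rare_rows) < config.n_rare and attempts < 50 * config.n_rare:
        attempts += 1
        gene = pick(matrisome_symbols, other_symbols) \
            if rng.random() < config.rare_matrisome_fraction \
            else pick(other_symbols, matrisome_symbols)
        disease = rare_names[int(rng.integers(config.n_rare_diseases))]
        if (gene, disease) in rare_pairs:
            continue
        rare_pairs.add((gene, disease))
        rare_rows.append((gene, disease))
    pd.DataFrame(rare_rows, columns=["gene", "disease"]).to_csv(
        outdir / "rare_diseases.tsv", sep="\t", index=False)
    rare_mat = [r for r in rare_rows if r[0] in set(matrisome_symbols)]
    manifest["rare"] = {
        "pairs": len(rare_rows),
        "matrisome_pairs": len(rare_mat),
        "matrisome_genes": len({g for g, _ in rare_mat}),
        "matrisome_diseases": len({d for _, d in rare_mat}),
    }

    # --- drug-gene links ---------------------------------------------------
    assoc_genes = sorted({g for g, _, _ in assoc_rows})
    drug_rows: list[tuple[str, str, str]] = []
    seen_links: set[tuple[str, str]] = set()
    attempts = 0
    while len(drug_rows) < config.n_drug_links and attempts < 50 * config.n_drug_links:
        attempts += 1
        drug = f"drug-{int(rng.integers(150)):03d}"
        gene = pick(assoc_genes, all_symbols) if rng.random() < 0.5 \
            else str(rng.choice(all_symbols))
        if (drug, gene) in seen_links:
            continue
        seen_links.add((drug, gene))
        snp = f"rs{3000000 + len(drug_rows)}" if rng.random() < 0.5 else ""
        drug_rows.append((drug, gene, snp))
    pd.DataFrame(drug_rows, columns=["drug", "gene", "snp"]).to_csv(
        outdir / "drugs.tsv", sep="\t", index=False)
    # Triads against the merged matrisome associations: curated + rare +
    # variant-derived (every matrisome variant row links its gene to its
    # condition), matching the pipeline's merge order.
    matrisome_assoc_genes = ({g for g, _, _ in assoc_rows if g in set(matrisome_symbols)}
                             | {g for g, _ in rare_mat}
                             | {g for g, _, _, _ in rows if g in set(matrisome_symbols)})
    triads = [(d, g) for d, g, _ in drug_rows if g in matrisome_assoc_genes]
    manifest["drugs"] = {
        "links": len(drug_rows),
        "matrisome_candidates": len(triads),
        "matrisome_candidate_genes": len({g for _, g in triads}),
        "matrisome_candidate_drugs": len({d for d, _ in triads}),
    }

    # --- PPI pairs ----------------------------------------------------------
    ppi_pairs: set[tuple[str, str]] = set()
    attempts = 0
    while len(ppi_pairs) < config.n_ppi and attempts < 50 * config.n_ppi:
        attempts += 1
        if rng.random() < config.ppi_matrisome_fraction and len(matrisome_symbols) >= 2:
            a, b = rng.choice(matrisome_symbols, size=2, replace=False)
        else:
            a = str(rng.choice(all_symbols))
            b = pick(other_symbols, matrisome_symbols)  # at least one non-matrisome
            if a == b:
                continue
        pair = (min(str(a), str(b)), max(str(a), str(b)))
        ppi_pairs.add(pair)
    ppi_list = sorted(ppi_pairs)
    pd.DataFrame(ppi_list, columns=["gene_a", "gene_b"]).to_csv(
        outdir / "ppi.tsv", sep="\t", index=False)
    survivors = [p for p in ppi_list
                 if p[0] in set(matrisome_symbols) and p[1] in set(matrisome_symbols)]
    manifest["ppi"] = {
        "pairs_written": len(ppi_list),
        "matrisome_pairs": len(survivors),
        "matrisome_unique_genes": len({g for p in survivors for g in p}),
    }

    # --- merged diseasome (curated + rare + variant-derived), matrisome only --
    merged_pairs = ({(g, d.lower()) for g, d, _ in assoc_rows if g in set(matrisome_symbols)}
                    | {(g, d) for g, d in rare_mat}
                    | {(g, d.lower()) for g, _, _, d in rows if g in set(matrisome_symbols)})
    per_gene: dict[str, int] = defaultdict(int)
    per_disease_deg: dict[str, int] = defaultdict(int)
    for g, d in merged_pairs:
        per_gene[g] += 1
        per_disease_deg[d] += 1
    # Planted category marginals over the diseases actually in the merged
    # diseasome (rare-disease names carry no category terms by construction).
    merged_marginals = {
        k: sum(1 for d in per_disease_deg
               if k in memberships.get(d, "uncategorized").split("_"))
        for k in ("A", "B", "C")}
    manifest["diseasome"] = {
        "pairs": len(merged_pairs),
        "genes": len(per_gene),
        "diseases": len(per_disease_deg),
        "per_gene_degree": dict(sorted(per_gene.items())),
        "per_disease_degree": dict(sorted(per_disease_deg.items())),
        "category_marginals": merged_marginals,
        "category_label_counts": _label_counts(per_disease_deg, memberships),
    }

    manifest["config"] = _config_to_jsonable(config)
    _write_manifest(manifest, outdir / "manifest.json")
    return SyntheticDataset(outdir, manifest)


def _label_counts(diseases, memberships: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for d in diseases:
        counts[memberships.get(d, "uncategorized")] += 1
    return dict(sorted(counts.items()))


def _recount_variants(rows, matrisome: set[str], collagens: set[str],
                      n_duplicates: int) -> dict:
    """Re-scan the emitted variant rows for the manifest (emission-log recount)."""
    unique_keys = {(g, v, c or None, d.lower()) for g, v, c, d in rows}
    mat_rows = [(g, v, c, d) for g, v, c, d in unique_keys if g in matrisome]
    per_disease: dict[str, set[str]] = defaultdict(set)
    for g, v, c, d in mat_rows:
        per_disease[d].add(v)
    sub_all: dict[str, int] = defaultdict(int)
    sub_collagen: dict[str, int] = defaultdict(int)
    for g, v, c, d in unique_keys:
        result = parse_protein_change(c)
        if not result.is_missense:
            continue
        key = f"{result.missense.ref.code3}>{result.missense.alt.code3}"
        sub_all[key] += 1
        if g in collagens:
            sub_collagen[key] += 1
    ref_totals: dict[str, int] = defaultdict(int)
    for key, count in sub_collagen.items():
        ref_totals[key.split(">")[0]] += count
    gly_targets = {key.split(">")[1]: count for key, count in sub_collagen.items()
                   if key.startswith("Gly>")}
    return {
        "rows_written": len(rows),
        "planted_duplicates": n_duplicates,
        "unique_records": len(unique_keys),
        "matrisome_records": len(mat_rows),
        "matrisome_unique_genes": len({g for g, *_ in mat_rows}),
        "per_disease_unique_variants": {d: len(v) for d, v in sorted(per_disease.items())},
        "substitution_counts": dict(sorted(sub_all.items())),
        "substitution_counts_collagen": dict(sorted(sub_collagen.items())),
        "collagen_ref_ranking": [k for k, _ in sorted(ref_totals.items(),
                                                      key=lambda kv: (-kv[1], kv[0]))],
        "collagen_gly_target_ranking": [k for k, _ in sorted(gly_targets.items(),
                                                             key=lambda kv: (-kv[1], kv[0]))],
    }


def _recount_associations(assoc_rows, matrisome: set[str]) -> dict:
    unique = {(g, d.lower()) for g, d, _ in assoc_rows}
    mat = [(g, d) for g, d in unique if g in matrisome]
    per_gene: dict[str, int] = defaultdict(int)
    per_disease: dict[str, int] = defaultdict(int)
    for g, d in mat:
        per_gene[g] += 1
        per_disease[d] += 1
    return {
        "unique_pairs_all": len(unique),
        "matrisome_pairs": len(mat),
        "matrisome_genes": len(per_gene),
        "matrisome_diseases": len(per_disease),
        "per_gene_degree": dict(sorted(per_gene.items())),
        "per_disease_degree": dict(sorted(per_disease.items())),
    }


def _config_to_jsonable(config: GeneratorConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["substitution_distribution"] = {
        f"{r}>{a}": p for (r, a), p in config.substitution_distribution.items()}
    return raw


def _write_manifest(manifest: dict, path: Path) -> None:
    tmp = path.with_suffix(".json.tmp")
    with open(tmp, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    os.replace(tmp, path)


# --- fixtures from lists printed in the literature --------------------------

STICKLER_COLLAGENS = ("COL2A1", "COL9A1", "COL9A2", "COL9A3", "COL11A1", "COL11A2")
ULLRICH_COLLAGENS = ("COL6A1", "COL6A2", "COL6A3", "COL12A1")
PLG_DRUGS = ("alteplase", "aminocaproic acid", "anistreplase", "aprotinin",
             "reteplase", "streptokinase", "tenecteplase", "tranexamic acid",
             "urokinase")
REPURPOSING_GENES = ("COL1A2", "NOV", "LPA", "MMP24", "PLG")
PLG_SNP = "rs783147"

#: Matrisome annotation for the fixture genes, following the published
#: catalog's category scheme (collagen chains -> collagens; CCN3/NOV a core
#: glycoprotein; LPA ECM-affiliated; MMP24 and PLG ECM regulators).
_FIXTURE_CATEGORIES: dict[str, str] = {
    **{g: "collagens" for g in STICKLER_COLLAGENS + ULLRICH_COLLAGENS},
    "COL1A2": "collagens", "NOV": "glycoproteins", "LPA": "ecm_affiliated",
    "MMP24": "ecm_regulators", "PLG": "ecm_regulators",
}


def paper_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Materialize the in-literature worked-example fixtures.

    Writes, in the canonical dialects: the Stickler-syndrome collagen
    associations (six genes), the Ullrich congenital muscular dystrophy
    associations (four genes), the nine plasminogen-targeting drugs, a
    five-gene repurposing association table, and a small catalog covering
    every fixture gene.  Disease names for the repurposing genes are
    synthetic placeholders (the source lists print genes and drugs, not
    indications).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["catalog"] = outdir / "fixture_catalog.tsv"
    pd.DataFrame(
        [(g, CATEGORY_DIVISION[Category(c)].value, c)
         for g, c in sorted(_FIXTURE_CATEGORIES.items())],
        columns=["symbol", "division", "category"]).to_csv(
        paths["catalog"], sep="\t", index=False)

    paths["stickler"] = outdir / "stickler_associations.tsv"
    pd.DataFrame([(g, "Stickler syndrome", "curated") for g in STICKLER_COLLAGENS],
                 columns=["gene", "disease", "source"]).to_csv(
        paths["stickler"], sep="\t", index=False)

    paths["ullrich"] = outdir / "ullrich_associations.tsv"
    pd.DataFrame([(g, "Ullrich congenital muscular dystrophy", "curated")
                  for g in ULLRICH_COLLAGENS],
                 columns=["gene", "disease", "source"]).to_csv(
        paths["ullrich"], sep="\t", index=False)

    paths["plg_drugs"] = outdir / "plg_drugs.tsv"
    pd.DataFrame([(d, "PLG", PLG_SNP) for d in PLG_DRUGS],
                 columns=["drug", "gene", "snp"]).to_csv(
        paths["plg_drugs"], sep="\t", index=False)

    paths["repurposing"] = outdir / "repurposing_associations.tsv"
    pd.DataFrame([(g, f"synthetic indication for {g}", "curated")
                  for g in REPURPOSING_GENES],
                 columns=["gene", "disease", "source"]).to_csv(
        paths["repurposing"], sep="\t", index=False)
    return paths
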