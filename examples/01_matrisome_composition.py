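"""How much of the matrisome catalog does a disease gene set cover?

Builds a 1027-gene catalog-sized comparison: 333 disease-associated genes
against the full catalog, printing the one-decimal percentage used in
two-ring composition diagrams.
"""

from ecm_diseasome.matrisome_annotation import composition_summary
from ecm_diseasome.records import CATEGORY_DIVISION, Category, MatrisomeGene

disease_genes = [
    MatrisomeGene(f"G{i:04d}", CATEGORY_DIVISION[Category.COLLAGENS], Category.COLLAGENS)
    if i < 40 else
    MatrisomeGene(f"G{i:04d}", CATEGORY_DIVISION[Category.GLYCOPROTEINS], Category.GLYCOPROTEINS)
    for i in range(333)
]

summary = composition_summary(disease_genes, catalog_size=1027)
print(f"disease-matrisome genes: {summary.total_genes} / {summary.catalog_size}")
print(f"fraction of catalog:     {summary.fraction_of_catalog}%")
print(f"by division:             {summary.by_division}")
# The fraction is the share of the screening universe with at least one
# disease link; ~32% indicates broad disease involvement of the matrisome.
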