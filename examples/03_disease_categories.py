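"""Sort diseases into the connective-tissue / common / age-related lattice.

Uses the shipped default term lists; a disease matching terms from several
lists receives a combination label such as A_C.
"""

from ecm_diseasome.disease_categorization import (
    categorize_disease,
    category_counts,
    default_terms,
)

names = [
    "Marfan syndrome",                      # A: classic connective-tissue disease
    "Osteogenesis imperfecta type III",     # A
    "childhood asthma",                     # B: common disease
    "autism spectrum disorder",             # B
    "pulmonary fibrosis",                   # C: age-related
    "Alport-related renal fibrosis",        # A + C overlap
    "completely novel disorder",            # no term matches
]

terms = default_terms()
assignments = [categorize_disease(n, terms) for n in names]
for name, a in zip(names, assignments):
    print(f"{name!r:42s} -> {a.label}")

table, marginals = category_counts(assignments, weight="by_disease")
print("\nlabel counts (partition of the input):")
print(table.to_string(index=False))
print("marginals (overlaps counted in every member):", marginals)
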