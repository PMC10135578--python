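"""Which collagen residue is most often substituted, and into what?

Parses HGVS-style protein changes from a handful of clinical variant
records and prints the ranked substitution spectrum.
"""

from ecm_diseasome.records import VariantRecord
from ecm_diseasome.variant_analysis import (
    rank_substituted,
    rank_targets,
    substitution_matrix,
)

records = [
    VariantRecord("COL3A1", "rs1", "p.Gly661Arg", "vascular EDS"),
    VariantRecord("COL4A5", "rs2", "p.Gly852Arg", "Alport syndrome"),
    VariantRecord("COL4A5", "rs3", "p.Gly325Arg", "Alport syndrome"),
    VariantRecord("COL1A1", "rs4", "p.Gly352Ser", "osteogenesis imperfecta"),
    VariantRecord("COL2A1", "rs5", "p.Pro86Leu", "Stickler syndrome"),
    VariantRecord("COL7A1", "rs6", "G2034R", "epidermolysis bullosa"),  # one-letter dialect
    VariantRecord("COL1A2", "rs7", "p.Arg134Cys", "EDS"),
    VariantRecord("COL1A1", "rs8", "p.Gly232=", "no effect"),  # synonymous, not counted
]

matrix = substitution_matrix(records)
print(f"missense events counted: {matrix.total}")
print("most substituted residues:",
      [(code, n) for code, n in rank_substituted(matrix) if n])
print("glycine goes to:",
      [(code, n) for code, n in rank_targets(matrix, "Gly") if n])
# Glycine dominates because every third helix residue must be glycine;
# any substitution there disrupts the collagen triple helix.
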