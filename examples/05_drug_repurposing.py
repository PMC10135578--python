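"""Join drug-gene links onto gene-disease associations: repurposing triads.

The nine plasminogen (PLG)-targeting drugs each become a candidate for
every disease PLG is associated with.
"""

import tempfile

from ecm_diseasome.data_io import read_drug_table
from ecm_diseasome.drug_repurposing import join_candidates, summarize_candidates
from ecm_diseasome.records import AssociationSource, GeneDiseaseAssociation
from ecm_diseasome.synthetic_data import paper_fixtures

with tempfile.TemporaryDirectory() as tmp:
    drugs, _ = read_drug_table(paper_fixtures(tmp)["plg_drugs"])

plg_associations = [
    GeneDiseaseAssociation("PLG", disease, AssociationSource.CURATED)
    for disease in ("thrombosis", "myocardial infarction", "stroke",
                    "pulmonary embolism")]

candidates, report = join_candidates(plg_associations, drugs)
summary = summarize_candidates(candidates)
print(f"{report.candidates} candidates "
      f"({summary.n_drugs} drugs x {summary.n_genes} gene)")
for c in candidates:
    print(f"  {c.drug_name:20s} -> {c.target_gene} ({len(c.diseases)} diseases)")
# Each drug already modulates the target, so every associated disease is a
# candidate indication; clinical plausibility still needs expert review.
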