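"""Build the bipartite gene-disease network from the printed collagen lists.

Stickler syndrome links six collagens; Ullrich congenital muscular
dystrophy links four.  The degree table recovers both counts, and the
shared-disease clustering separates the two collagen groups.
"""

import tempfile

from ecm_diseasome.data_io import read_association_table
from ecm_diseasome.diseasome_network import (
    build_bipartite,
    genes_per_disease,
    shared_disease_clusters,
)
from ecm_diseasome.synthetic_data import paper_fixtures

with tempfile.TemporaryDirectory() as tmp:
    fixtures = paper_fixtures(tmp)
    stickler, _ = read_association_table(fixtures["stickler"])
    ullrich, _ = read_association_table(fixtures["ullrich"])

graph, report = build_bipartite(stickler + ullrich)
print(f"network: {graph.number_of_nodes()} nodes, {report.edges} edges")
print(genes_per_disease(graph).to_string(index=False))

clusters = shared_disease_clusters(graph, cut=0.5)
print("gene clusters (genes sharing a disease co-cluster):", clusters)
# Expect degree 6 for Stickler, 4 for Ullrich, and two clean clusters: the
# two syndromes share no collagen in these lists.
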