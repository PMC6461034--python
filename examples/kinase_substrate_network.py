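"""Build and export the kinase-substrate network for the top-ranked kinases.

Nodes are proteins: observed kinases (hexagon style), inferred kinases that
lack their own phosphopeptides (pentagon style), and non-kinase substrates
(circles).  Edges run kinase -> substrate, weighted by the summed class-I
substrate-site phosphosignal, colored by relation source (curated coral,
predicted cornflowerblue, both forestgreen).
"""

from pathlib import Path

from inka import build_network, edge_table, layout_fr, synthetic, write_graphml
from inka.scoring import kinase_peptide_evidence, score_sample, substrate_site_evidence

experiment = synthetic.generate(seed=1)
kb = experiment.knowledgebase()
merged = experiment.merged_table()

scores = score_sample(merged, kb, "sample1")
graph = build_network(
    scores,
    substrate_site_evidence(merged, kb, "sample1"),
    kinase_peptide_evidence(merged, kb, "sample1"),
    top_n=20,
)
layout_fr(graph, seed=0)

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
write_graphml(graph, out / "network.graphml")
print(f"{graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")
print("\nheaviest edges (kinase -> substrate, summed site phosphosignal):")
print(edge_table(graph).nlargest(5, "weight").to_string(index=False))
# The driver kinase appears as a hub: high node score, many outgoing edges.
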