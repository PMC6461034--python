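"""Per-sample kinase-substrate relation networks.

Nodes are proteins: hexagon-style *observed kinases* (identified through one
or more phosphopeptides), pentagon-style *inferred kinases* (substrate-linked
but lacking direct observation), and circle-style non-kinase *substrates*.
Directed edges run kinase -> substrate, weighted by the summed phosphosignal
of the linked class-I substrate sites, and tagged with the relation source
(curated, predicted, or both).  Figure styling (the coral / cornflowerblue /
forestgreen edge palette and the white-to-red node gradient) is retained as
attributes rather than hard-coded drawing.

Layout is force-directed (Fruchterman-Reingold family) with the parameters
set from the node count N: niter = 100N, area = N^1.8, repulse.rad = N^1.5,
ncell = N^3.  The networkx backend honors niter and area (through the
optimal-distance and scale parameters); the grid-variant radius and cell
parameters are recorded as metadata and approximated, with the deviation
logged.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OBSERVED_KINASE = "observed_kinase"
INFERRED_KINASE = "inferred_kinase"
SUBSTRATE = "substrate"

EDGE_COLORS = {"PSP": "coral", "NWK": "cornflowerblue", "both": "forestgreen"}


def _edge_source(sources: set[str]) -> str:
    return "both" if len(sources) > 1 else next(iter(sources))


def build_network(
    scores: pd.DataFrame,
    substrate_evidence: pd.DataFrame,
    kinase_peptides: pd.DataFrame | None = None,
    top_n: int = 20,
    include_inferred: bool = True,
) -> nx.DiGraph:
    """Build the kinase-substrate network for the top-n ranked kinases.

    ``scores`` is a per-kinase score table (from :func:`inka.scoring
    .score_sample`); ``substrate_evidence`` the per-(kinase, site, source)
    evidence frame; ``kinase_peptides`` the kinase-centric evidence frame used
    to mark observed kinases and activation-loop phosphorylation.  With
    ``include_inferred``, unobserved kinases whose targets overlap the
    network's substrate nodes are added as inferred-kinase nodes.
    """
    graph = nx.DiGraph()
    if scores.empty:
        logger.warning("empty score table: returning an empty network")
        return graph

    ranked = scores[scores["inka"] > 0].copy()
    ranked["_sym"] = ranked.index
    ranked = ranked.sort_values(["inka", "_sym"], ascending=[False, True], kind="mergesort")
    top = list(ranked.index[:top_n])

    observed_genes: set[str] = set()
    actloop_genes: set[str] = set()
    if kinase_peptides is not None and len(kinase_peptides):
        obs = kinase_peptides[kinase_peptides["quant"] > 0]
        observed_genes = set(obs["gene_symbol"])
        actloop_genes = set(obs[obs["is_activation_loop"]]["gene_symbol"])
    else:
        observed_genes = set(scores.index[scores["c_kin"] > 0])

    edges = substrate_evidence[substrate_evidence["kinase_symbol"].isin(top)]
    edges = edges[edges["phosphosignal"] > 0]

    def _add_kinase(symbol: str, kind: str) -> None:
        inka = float(scores.loc[symbol, "inka"]) if symbol in scores.index else 0.0
        graph.add_node(
            symbol,
            kind=kind,
            inka_score=inka,
            has_activation_loop_site=symbol in actloop_genes,
        )

    for kin in top:
        _add_kinase(kin, OBSERVED_KINASE if kin in observed_genes else INFERRED_KINASE)

    def _add_edges(frame: pd.DataFrame) -> None:
        grouped = frame.groupby(["kinase_symbol", "substrate_symbol"])
        for (kin, sub), block in grouped:
            if sub not in graph:
                if sub in observed_genes:
                    _add_kinase(sub, OBSERVED_KINASE)
                elif sub in set(scores.index):
                    _add_kinase(sub, INFERRED_KINASE)
                else:
                    graph.add_node(sub, kind=SUBSTRATE)
            # per-site phosphosignals summed over the sites linking this pair
            per_site = block.drop_duplicates(["site_key"])
            source = _edge_source(set(block["source"]))
            graph.add_edge(
                kin,
                sub,
                weight=float(per_site["phosphosignal"].sum()),
                n_sites=int(per_site["site_key"].nunique()),
                source=source,
                color=EDGE_COLORS[source],
            )

    _add_edges(edges)

    if include_inferred:
        present = set(graph.nodes)
        extra = substrate_evidence[
            ~substrate_evidence["kinase_symbol"].isin(observed_genes)
            & ~substrate_evidence["kinase_symbol"].isin(top)
            & substrate_evidence["substrate_symbol"].isin(present)
            & (substrate_evidence["phosphosignal"] > 0)
        ]
        for kin in sorted(set(extra["kinase_symbol"])):
            _add_kinase(kin, INFERRED_KINASE)
        _add_edges(extra)

    return graph


def layout_fr(graph: nx.DiGraph, seed: int | None = None) -> dict:
    """Force-directed node coordinates with size-scaled parameters.

    For N nodes the layout uses niter = 100N iterations on an area of N^1.8
    (optimal pair distance sqrt(area/N)).  The grid-variant repulsion radius
    N^1.5 and cell count N^3 are stored on the graph for provenance but are
    not parameters of this backend.  Deterministic under a fixed seed;
    coordinates are also written to the nodes as ``x``/``y`` attributes.
    """
    n = graph.number_of_nodes()
    if n == 0:
        return {}
    niter = 100 * n
    area = float(n) ** 1.8
    graph.graph.update(
        fr_niter=niter,
        fr_area=area,
        fr_repulse_rad=float(n) ** 1.5,
        fr_ncell=float(n) ** 3,
        fr_backend="networkx.spring_layout",
    )
    if n == 1:
        pos = {next(iter(graph.nodes)): np.zeros(2)}
    else:
        logger.info(
            "force-directed layout: niter=%d area=%.3g (repulse.rad/ncell recorded, "
            "approximated by the backend)",
            niter,
            area,
        )
        pos = nx.spring_layout(
            graph,
            k=np.sqrt(area / n),
            iterations=niter,
            seed=seed,
            scale=np.sqrt(area) / 2.0,
        )
    for node, (x, y) in pos.items():
        graph.nodes[node]["x"] = float(x)
        graph.nodes[node]["y"] = float(y)
    return {node: (float(p[0]), float(p[1])) for node, p in pos.items()}


def write_graphml(graph: nx.DiGraph, path) -> None:
    """Serialize the network with all attributes as GraphML."""
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.DiGraph:
    """Read a network written by :func:`write_graphml`."""
    return nx.read_graphml(path)


def edge_table(graph: nx.DiGraph) -> pd.DataFrame:
    """Tidy edge list: kinase, substrate, weight, n_sites, source, color."""
    rows = [
        {"kinase": u, "substrate": v, **attrs} for u, v, attrs in graph.edges(data=True)
    ]
    cols = ["kinase", "substrate", "weight", "n_sites", "source", "color"]
    return pd.DataFrame(rows, columns=cols)


def node_table(graph: nx.DiGraph) -> pd.DataFrame:
    """Tidy node-attribute table."""
    rows = [{"node": node, **attrs} for node, attrs in graph.nodes(data=True)]
    frame = pd.DataFrame(rows)
    lead = [c for c in ("node", "kind", "inka_score", "has_activation_loop_site") if c in frame]
    rest = [c for c in frame.columns if c not in lead]
    return frame[lead + rest]


def write_tables(graph: nx.DiGraph, edge_path, node_path) -> None:
    """Write the tidy edge-list and node-attribute tables as TSV."""
    edge_table(graph).to_csv(edge_path, sep="\t", index=False, lineterminator="\n")
    node_table(graph).to_csv(node_path, sep="\t", index=False, lineterminator="\n")
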