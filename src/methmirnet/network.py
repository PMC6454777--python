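"""Assembly of the meth-miRNA-mRNA networks.

Two bipartite, directed miRNA->gene networks are built: the
tumor-suppressor network (up-regulated OG miRNAs targeting down-regulated
TS genes) and the oncogenic network (down-regulated TS miRNAs targeting
up-regulated OG genes). Gene nodes carry a methylation flag when the
candidate is also differentially methylated in the silencing-consistent
direction (TS + hypermethylated, OG + hypomethylated). Visual styling is
left to the viewer; only attributes are exported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import AnalysisError, ParameterError

logger = logging.getLogger(__name__)

NETWORK_ROLES = ("tumor_suppressor", "oncogenic")


def integrate_methylation(ts_genes, og_genes, hyper, hypo) -> tuple[set, set]:
    """Methylation-consistent candidates: hypermethylated TS genes and
    hypomethylated OG genes (plain set intersections)."""
    flagged_ts = set(ts_genes) & set(hyper)
    flagged_og = set(og_genes) & set(hypo)
    logger.info(
        "integrate_methylation: %d hyper TS, %d hypo OG", len(flagged_ts), len(flagged_og)
    )
    return flagged_ts, flagged_og


@dataclass
class MethMirnaMrnaNetwork:
    """Typed miRNA->gene network with expression direction and methylation
    flags on the nodes and confidence on the edges.

    ``nodes``: list of (id, node_type {gene|mirna}, direction {up|down},
    meth_flag {hyper|hypo|none}); ``edges``: list of
    (mirna_id, gene_id, confidence). Within one network the gene direction
    is opposite to the miRNA direction.
    """

    network_role: str
    nodes: list[tuple[str, str, str, str]] = field(default_factory=list)
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.network_role not in NETWORK_ROLES:
            raise ParameterError(
                f"network_role must be one of {NETWORK_ROLES}, got {self.network_role!r}"
            )
        ids = [n[0] for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise AnalysisError("duplicate node id in network")
        known = set(ids)
        for m, g, _c in self.edges:
            if m not in known or g not in known:
                missing = m if m not in known else g
                raise AnalysisError(f"edge references unknown node {missing!r}")
        gene_dir = "down" if self.network_role == "tumor_suppressor" else "up"
        mirna_dir = "up" if gene_dir == "down" else "down"
        for nid, ntype, direction, meth_flag in self.nodes:
            if ntype not in ("gene", "mirna"):
                raise AnalysisError(f"node {nid!r}: unknown node_type {ntype!r}")
            expected = gene_dir if ntype == "gene" else mirna_dir
            if direction != expected:
                raise AnalysisError(
                    f"node {nid!r}: direction {direction!r} inconsistent with "
                    f"{self.network_role} network ({ntype} nodes must be {expected})"
                )
            if meth_flag not in ("hyper", "hypo", "none"):
                raise AnalysisError(f"node {nid!r}: unknown meth_flag {meth_flag!r}")
        self.nodes = sorted(self.nodes)
        self.edges = sorted(self.edges)

    @classmethod
    def from_parts(cls, nodes, edges, network_role) -> "MethMirnaMrnaNetwork":
        return cls(network_role=network_role, nodes=list(nodes), edges=list(edges))

    # -- views ---------------------------------------------------------------
    def gene_nodes(self) -> list[str]:
        return [n[0] for n in self.nodes if n[1] == "gene"]

    def mirna_nodes(self) -> list[str]:
        return [n[0] for n in self.nodes if n[1] == "mirna"]

    def gene_degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.gene_nodes()}
        for _m, g, _c in self.edges:
            deg[g] += 1
        return deg

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph(network_role=self.network_role)
        for nid, ntype, direction, meth_flag in self.nodes:
            g.add_node(nid, node_type=ntype, direction=direction, meth_flag=meth_flag)
        for m, t, c in self.edges:
            g.add_edge(m, t, confidence=float(c))
        return g

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.nodes, columns=["id", "node_type", "direction", "meth_flag"]
        )

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["mirna_id", "gene_id", "confidence"])


def build_network(
    selected_mirnas,
    pruned_edges,
    gene_candidates,
    flagged_genes,
    network_role: str,
    include_isolated_genes: bool = False,
) -> MethMirnaMrnaNetwork:
    """Assemble one network from the selected hub miRNAs and pruned edges.

    Gene nodes default to only the targeted candidates (isolated candidates
    stay in the exported tables); ``include_isolated_genes=True`` adds the
    untargeted candidates as isolated nodes. ``flagged_genes`` get the
    role-appropriate methylation flag.
    """
    if network_role not in NETWORK_ROLES:
        raise ParameterError(f"unknown network_role {network_role!r}")
    gene_candidates = set(gene_candidates)
    flagged_genes = set(flagged_genes)
    gene_dir = "down" if network_role == "tumor_suppressor" else "up"
    mirna_dir = "up" if gene_dir == "down" else "down"
    meth_flag = "hyper" if network_role == "tumor_suppressor" else "hypo"

    for m, g, _c in pruned_edges:
        if m not in set(selected_mirnas):
            raise AnalysisError(f"edge references unselected miRNA {m!r}")
        if g not in gene_candidates:
            raise AnalysisError(f"edge references non-candidate gene {g!r}")

    targeted = {g for _m, g, _c in pruned_edges}
    gene_ids = gene_candidates if include_isolated_genes else targeted
    nodes = [(m, "mirna", mirna_dir, "none") for m in sorted(set(selected_mirnas))]
    nodes += [
        (g, "gene", gene_dir, meth_flag if g in flagged_genes else "none")
        for g in sorted(gene_ids)
    ]
    return MethMirnaMrnaNetwork(
        network_role=network_role, nodes=nodes, edges=sorted(pruned_edges)
    )
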