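"""Layered gene regulatory network assembly, hubs, and SIF export.

The master network is assembled from three signed co-expression edge
sets: layer 1 holds PrLP–PrLP edges, layer 2 adds edges touching rice
transcription factors, layer 3 adds edges touching stress- or
memory-related genes.  Duplicate pairs collapse to the lowest layer.
Edges are stored undirected (co-expression is symmetric); node roles
are kept as attributes and exported as a sidecar table because the SIF
edge-list format carries none.
"""

from __future__ import annotations

import csv
import logging
import math
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx

logger = logging.getLogger(__name__)

ROLES = ("PrLP", "TF", "Ts/RTR", "stress", "memory")

SignedEdge = Tuple[str, str, int]


def assemble_layers(
    prlp_edges: Iterable[SignedEdge],
    tf_edges: Iterable[SignedEdge],
    stress_memory_edges: Iterable[SignedEdge],
    role_tables: Mapping[str, Set[str]],
) -> nx.Graph:
    """Union of the three layers with lowest-layer collapse.

    Each edge is ``(gene_a, gene_b, sign)`` with sign in {-1, +1}; the
    layers are processed in order, so a pair recurring in a later layer
    keeps its first (lowest) layer and sign.  Nodes absent from every
    role table are created with an empty role set and logged.
    """
    graph = nx.Graph()
    for layer, edges in enumerate(
        (prlp_edges, tf_edges, stress_memory_edges), start=1
    ):
        for a, b, sign in edges:
            if sign not in (-1, 1):
                raise ValueError(f"edge ({a}, {b}) has invalid sign {sign!r}")
            for node in (a, b):
                if node not in graph:
                    roles = frozenset(
                        r for r, members in role_tables.items() if node in members
                    )
                    if not roles:
                        logger.warning("gene %s has no role assignment", node)
                    graph.add_node(node, roles=roles)
            if not graph.has_edge(a, b):
                graph.add_edge(a, b, sign=int(sign), layer=layer,
                               evidence_filtered=False)
    return graph


def validate_network(graph: nx.Graph) -> List[str]:
    """Layer/role consistency problems, empty when the network is valid."""
    problems = []
    for u, v, data in graph.edges(data=True):
        ur = graph.nodes[u].get("roles", frozenset())
        vr = graph.nodes[v].get("roles", frozenset())
        layer = data.get("layer")
        if layer == 1 and not ("PrLP" in ur and "PrLP" in vr):
            problems.append(f"layer-1 edge {u}-{v} does not join two PrLPs")
        elif layer == 2 and not ("TF" in ur or "TF" in vr):
            problems.append(f"layer-2 edge {u}-{v} touches no TF")
        elif layer == 3 and not (
            {"stress", "memory"} & ur or {"stress", "memory"} & vr
        ):
            problems.append(f"layer-3 edge {u}-{v} touches no stress/memory gene")
    return problems


def split_layers(
    edges: Iterable[SignedEdge],
    role_tables: Mapping[str, Set[str]],
) -> Tuple[List[SignedEdge], List[SignedEdge], List[SignedEdge]]:
    """Partition signed edges into the three prionome-anchored layers.

    Layer 1: PrLP–PrLP pairs.  Layer 2: remaining pairs joining a PrLP
    with a TF.  Layer 3: remaining pairs joining a stress/memory gene
    with a PrLP, or with a TF/Ts-RTR already connected to the prionome
    through layers 1–2.  Pairs matching no layer are dropped, so the
    network always grows outward from the prionome: an empty PrLP set
    yields three empty layers.
    """
    prlp = role_tables.get("PrLP", set())
    tf = role_tables.get("TF", set())
    tsrtr = role_tables.get("Ts/RTR", set())
    sm = role_tables.get("stress", set()) | role_tables.get("memory", set())
    l1: List[SignedEdge] = []
    l2: List[SignedEdge] = []
    rest: List[SignedEdge] = []
    for a, b, sign in edges:
        if a in prlp and b in prlp:
            l1.append((a, b, sign))
        elif (a in tf and b in prlp) or (b in tf and a in prlp):
            l2.append((a, b, sign))
        else:
            rest.append((a, b, sign))
    anchored = set(prlp)
    for a, b, _ in l1 + l2:
        for node in (a, b):
            if node in tf or node in tsrtr:
                anchored.add(node)
    l3 = [
        (a, b, sign) for a, b, sign in rest
        if (a in sm and b in anchored) or (b in sm and a in anchored)
    ]
    return l1, l2, l3


def find_hubs(graph: nx.Graph, top_fraction: float = 0.05) -> List[str]:
    """Nodes in the top ``top_fraction`` by degree, boundary ties included."""
    if graph.number_of_nodes() == 0:
        return []
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    ranked = sorted(graph.degree, key=lambda kv: (-kv[1], kv[0]))
    k = max(1, math.ceil(top_fraction * len(ranked)))
    cutoff = ranked[k - 1][1]
    return [node for node, degree in ranked if degree >= cutoff]


def export_sif(graph: nx.Graph, path) -> None:
    """One ``source<TAB>relation<TAB>target`` line per edge (pos/neg)."""
    lines = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((u, v))
        relation = "pos" if data.get("sign", 1) > 0 else "neg"
        lines.append(f"{a}\t{relation}\t{b}")
    with open(path, "w") as fh:
        for line in sorted(lines):
            fh.write(line + "\n")


def import_sif(path) -> nx.Graph:
    """Inverse of :func:`export_sif` (roles are not part of SIF)."""
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 or fields[1] not in {"pos", "neg"}:
                raise ValueError(f"malformed SIF line {lineno}: {line!r}")
            a, relation, b = fields
            for node in (a, b):
                if node not in graph:
                    graph.add_node(node, roles=frozenset())
            graph.add_edge(a, b, sign=1 if relation == "pos" else -1)
    return graph


def export_node_table(graph: nx.Graph, path) -> None:
    """Sidecar node-attribute TSV: gene_id, roles, degree."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "roles", "degree"])
        for node in sorted(graph.nodes):
            roles = ",".join(sorted(graph.nodes[node].get("roles", ())))
            writer.writerow([node, roles, graph.degree[node]])


def read_role_tables(paths: Mapping[str, str]) -> Dict[str, Set[str]]:
    """Read one-gene-per-line role files keyed by role name."""
    tables: Dict[str, Set[str]] = {}
    for role, path in paths.items():
        with open(path) as fh:
            tables[role] = {
                line.strip() for line in fh
                if line.strip() and not line.startswith("#")
            }
    return tables
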