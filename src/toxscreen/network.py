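"""Thresholded Tanimoto similarity network and degree-based reference selection.

The toxic-training library is turned into an undirected graph whose edges are
the compound pairs with Tanimoto >= tau (0.5 in the published protocol).
Degree centrality — the number of compounds a molecule resembles at or above
the threshold — identifies the structural core of the library: nodes with
degree at or above half the maximum degree form the toxic reference set used
as the screening template.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .fingerprints import Fingerprint, tanimoto

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityEdge",
    "SimilarityNetwork",
    "ReferenceSet",
    "build_network",
    "degree_table",
    "half_max_cutoff",
    "select_reference",
    "export_network",
    "read_network",
]


@dataclass(frozen=True)
class SimilarityEdge:
    u: str
    v: str
    score: float


@dataclass
class SimilarityNetwork:
    """Undirected threshold graph: nodes are compound ids, edges carry the
    exact Tanimoto score (kept so thresholds can be swept without refingerprinting)."""

    nodes: list[str]
    edges: list[SimilarityEdge]
    tau: float
    backend: str = "unknown"

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((e.u, e.v, e.score) for e in self.edges)
        return g


@dataclass
class ReferenceSet:
    """Degree-selected toxic reference subset with full provenance."""

    members: list[tuple[str, int, Fingerprint]]
    tau: float
    max_degree: int
    degree_cutoff: int
    provenance: dict = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return [m[0] for m in self.members]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def backend(self) -> str:
        return self.provenance.get("backend", "unknown")


def build_network(
    fingerprints: Sequence[tuple[str, Fingerprint]], tau: float = 0.5
) -> SimilarityNetwork:
    """All-pairs Tanimoto scan; edge set is exactly the unordered pairs with
    similarity >= tau. Isolated nodes stay in the graph."""
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    if len(fingerprints) < 2:
        raise ValueError("need at least 2 fingerprints to build a network")
    ids = [cid for cid, _ in fingerprints]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids: {dupes[:5]}")
    backends = {fp.backend for _, fp in fingerprints}
    if len(backends) > 1:
        raise ValueError(f"mixed fingerprint backends in one library: {sorted(backends)}")

    # vectorised popcount/intersection scan over the 166-key matrix
    import numpy as np

    mat = np.stack([fp.as_array() for _, fp in fingerprints]).astype(np.int16)
    pop = mat.sum(axis=1)
    inter = mat @ mat.T
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)

    edges = []
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = sim[iu, ju] >= tau
    for i, j in zip(iu[keep], ju[keep]):
        edges.append(SimilarityEdge(ids[i], ids[j], float(sim[i, j])))
    edges.sort(key=lambda e: (e.u, e.v))
    logger.info("network: %d nodes, %d edges at tau=%.3g", len(ids), len(edges), tau)
    return SimilarityNetwork(nodes=list(ids), edges=edges, tau=tau, backend=backends.pop())


def degree_table(network: SimilarityNetwork) -> dict[str, int]:
    """Edge count incident to each node (the CytoNCA-style Degree value)."""
    deg = {n: 0 for n in network.nodes}
    for e in network.edges:
        deg[e.u] += 1
        deg[e.v] += 1
    return deg


def half_max_cutoff(max_degree: int) -> int:
    """Half of the maximum degree, rounded up for odd maxima."""
    return math.ceil(max_degree / 2)


def select_reference(
    network: SimilarityNetwork,
    degrees: Mapping[str, int] | None = None,
    fingerprints: Mapping[str, Fingerprint] | None = None,
    strict_greater: bool = False,
) -> ReferenceSet:
    """Select nodes with degree >= ceil(max_degree / 2) as the toxic
    reference set (``strict_greater=True`` uses > instead of >=).

    A network with no edges yields an empty reference set with a warning,
    not an error.
    """
    if degrees is None:
        degrees = degree_table(network)
    if not degrees:
        raise ValueError("empty network")
    max_degree = max(degrees.values())
    cutoff = half_max_cutoff(max_degree)
    if max_degree == 0:
        logger.warning("all degrees are 0; reference set is empty")
        member_ids: list[str] = []
    elif strict_greater:
        member_ids = sorted(n for n, d in degrees.items() if d > cutoff)
    else:
        member_ids = sorted(n for n, d in degrees.items() if d >= cutoff)
    fingerprints = fingerprints or {}
    members = [
        (n, degrees[n], fingerprints.get(n, Fingerprint.from_on_keys([], backend=network.backend)))
        for n in member_ids
    ]
    prov = {
        "backend": network.backend,
        "tau": network.tau,
        "max_degree": max_degree,
        "degree_cutoff": cutoff,
        "rule": "degree > cutoff" if strict_greater else "degree >= cutoff",
        "library_size": len(network.nodes),
        "n_edges": network.n_edges,
    }
    logger.info(
        "reference set: max degree %d, cutoff %d, %d members", max_degree, cutoff, len(members)
    )
    return ReferenceSet(
        members=members, tau=network.tau, max_degree=max_degree, degree_cutoff=cutoff, provenance=prov
    )


def export_network(network: SimilarityNetwork, path: str | Path, format: str = "sif") -> None:
    """Write the network as Cytoscape SIF ('u sim v', isolated nodes as bare
    lines) or CSV (u,v,score)."""
    path = Path(path)
    if format == "sif":
        touched = {e.u for e in network.edges} | {e.v for e in network.edges}
        lines = [f"{e.u}\tsim\t{e.v}" for e in network.edges]
        lines += [n for n in network.nodes if n not in touched]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["u", "v", "score"])
            for e in network.edges:
                w.writerow([e.u, e.v, f"{e.score:.6f}"])
    else:
        raise ValueError(f"unknown export format {format!r}")
    sidecar = path.with_suffix(path.suffix + ".prov.json")
    sidecar.write_text(
        json.dumps({"tau": network.tau, "backend": network.backend, "n_nodes": len(network.nodes), "n_edges": network.n_edges}, indent=1)
    )


def read_network(path: str | Path, tau: float, format: str = "csv", backend: str = "unknown") -> SimilarityNetwork:
    """Read back a CSV edge list written by export_network (round-trip)."""
    path = Path(path)
    if format != "csv":
        raise ValueError("only CSV round-trip reading is supported")
    edges = []
    nodes: set[str] = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            edges.append(SimilarityEdge(row["u"], row["v"], float(row["score"])))
            nodes.update((row["u"], row["v"]))
    edges.sort(key=lambda e: (e.u, e.v))
    return SimilarityNetwork(nodes=sorted(nodes), edges=edges, tau=tau, backend=backend)
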