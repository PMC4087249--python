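"""Network construction and centrality features.

Disease-associated variants are enriched in proteins that sit centrally
in interactome graphs, so per-node centrality becomes a per-variant
feature. Four measures are computed on undirected simple graphs at three
scales: protein (PPI), domain (domain-domain interaction and domain
bigram) and residue (spatial contact graphs from coordinates).

Definitions follow the interactome-analysis conventions:

- degree: number of adjacent edges;
- betweenness: fraction of shortest paths between other node pairs that
  pass through the node, normalised by (n-1)(n-2)/2;
- closeness: 1 / (sum of shortest-path distances to reachable nodes),
  computed within the node's connected component;
- coreness: largest k for which the node survives iterative removal of
  all nodes of degree < k (the k-core).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .core import SAV, logger
from .errors import ParseError, ValidationError

CENTRALITY_MEASURES = ("degree", "betweenness", "closeness", "coreness")


class NetworkKind(str, Enum):
    PPI = "ppi"
    DOMAIN_INTERACTION = "domain_interaction"
    DOMAIN_BIGRAM = "domain_bigram"
    RESIDUE = "residue"


@dataclass
class Network:
    """An undirected simple graph (no self-loops, no parallel edges)."""

    graph: nx.Graph
    kind: NetworkKind = NetworkKind.PPI

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loops not allowed: {loops[:3]}")

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple], kind: NetworkKind = NetworkKind.PPI,
        nodes: Iterable | None = None,
    ) -> "Network":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                logger.warning("dropping self-loop %r", a)
                continue
            g.add_edge(a, b)
        return cls(g, kind)


def read_edge_list(path: str | Path, kind: NetworkKind = NetworkKind.PPI) -> Network:
    """Read an undirected edge list TSV (``idA<TAB>idB`` per row).

    Duplicate and reversed-duplicate rows collapse; self-loop rows are
    dropped with a warning.
    """
    g = nx.Graph()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(row)}"
                )
            a, b = row[0].strip(), row[1].strip()
            if a == b:
                logger.warning("%s:%d: self-loop %r dropped", path, lineno, a)
                continue
            g.add_edge(a, b)
    return Network(g, kind)


def kcore_decomposition(net: Network) -> dict:
    """Coreness of every node; isolated nodes have coreness 0."""
    if net.graph.number_of_nodes() == 0:
        return {}
    return dict(nx.core_number(net.graph))


def _closeness_inverse_sum(g: nx.Graph) -> dict:
    # 1/sum(d) over the node's component; isolated nodes get 0
    out = {}
    for v in g.nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(dist.values())  # d(v,v)=0 contributes nothing
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def centrality(
    net: Network,
    measure: str,
    normalized_betweenness: bool = True,
    harmonic_closeness: bool = False,
) -> dict:
    """One of the four centrality measures for every node.

    ``normalized_betweenness=False`` returns raw shortest-path counts;
    ``harmonic_closeness=True`` switches to the sum-of-inverse-distances
    variant, which is comparable across components.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("centrality of an empty network")
    if measure == "degree":
        return {v: float(d) for v, d in g.degree()}
    if measure == "betweenness":
        return dict(nx.betweenness_centrality(g, normalized=normalized_betweenness))
    if measure == "closeness":
        if harmonic_closeness:
            return dict(nx.harmonic_centrality(g))
        return _closeness_inverse_sum(g)
    if measure == "coreness":
        return {v: float(c) for v, c in kcore_decomposition(net).items()}
    raise ValidationError(f"unknown centrality measure {measure!r}")


@dataclass
class ResidueCoordinates:
    """Heavy-atom coordinates of one residue."""

    residue_index: int
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] == 0:
            raise ValidationError(f"residue {self.residue_index} has no atoms")
        if not np.isfinite(self.coords).all():
            raise ValidationError(f"residue {self.residue_index}: non-finite coordinates")


def read_pdb_residues(
    path: str | Path, chain: str | None = None, cbeta_only: bool = False
) -> list[ResidueCoordinates]:
    """Heavy-atom coordinates per residue from a PDB file.

    Only ATOM records of the first model are read; if the file has
    several chains, ``chain`` selects one (default: the first seen).
    ``cbeta_only`` keeps just the C-beta atom (C-alpha for glycine).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise ValidationError(f"{path}: chain {chain!r} not found")
    elif len(chains) > 1:
        logger.warning("%s: %d chains, using chain %r", path, len(chains), chains[0].id)
    residues = []
    for res in chains[0].get_residues():
        if res.id[0] != " ":  # skip HETATM/water
            continue
        atoms = [
            a for a in res.get_atoms() if (a.element or "").strip().upper() != "H"
        ]
        if cbeta_only:
            keep = [a for a in atoms if a.get_name() == "CB"] or [
                a for a in atoms if a.get_name() == "CA"
            ]
            atoms = keep or atoms
        if atoms:
            residues.append(
                ResidueCoordinates(res.id[1], np.array([a.coord for a in atoms]))
            )
    return residues


def build_residue_network(
    residues: Sequence[ResidueCoordinates], threshold: float = 5.0
) -> Network:
    """Residue contact graph: an edge joins residues whose minimum
    heavy-atom distance is below ``threshold`` (angstroms, default 5)."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    g = nx.Graph()
    g.add_nodes_from(r.residue_index for r in residues)
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            d = cdist(residues[i].coords, residues[j].coords).min()
            if d < threshold:
                g.add_edge(residues[i].residue_index, residues[j].residue_index)
    return Network(g, NetworkKind.RESIDUE)


def annotate_sav_centrality(
    savs: Sequence[SAV],
    net: Network,
    mapping: Callable[[SAV], object] | Mapping | None = None,
    prefix: str | None = None,
) -> dict[str, list[float]]:
    """Per-SAV feature columns for all four centrality measures.

    ``mapping`` takes an SAV to its node in the network (default: the
    protein id, the natural choice for a PPI graph). SAVs whose node is
    absent from the graph get NaN in every column.
    """
    if mapping is None:
        node_of = lambda s: s.protein_id
    elif callable(mapping):
        node_of = mapping
    else:
        node_of = lambda s: mapping.get(s, mapping.get(s.protein_id))
    prefix = prefix if prefix is not None else net.kind.value
    tables = {m: centrality(net, m) for m in CENTRALITY_MEASURES}
    columns: dict[str, list[float]] = {
        f"{prefix}_{m}": [] for m in CENTRALITY_MEASURES
    }
    for s in savs:
        node = node_of(s)
        for m in CENTRALITY_MEASURES:
            val = tables[m].get(node, math.nan)
            if node not in tables[m]:
                logger.debug("SAV %s: node %r absent from %s network", s, node, prefix)
            columns[f"{prefix}_{m}"].append(val)
    return columns
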