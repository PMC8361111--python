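"""MS/MS molecular networking: spectral similarity, graph build and export.

Nodes are MS/MS spectra; an edge connects two spectra whose similarity is
at or above a cutoff, grouping structurally related metabolites (shared
fragments and neutral losses).  Similarity is the standard molecular-
networking kernel: cosine of intensity-weighted peak vectors under greedy
one-to-one peak matching within a small m/z tolerance, optionally
precursor-shift-aware (modified cosine).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .spectra_io import Spectrum

__all__ = [
    "NetworkConfig",
    "NetworkGraph",
    "spectral_similarity",
    "build_network",
    "export_graph",
    "import_graph",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    """Networking parameters.

    ``intensity_weighting`` is the exponent applied to intensities before
    the cosine; 0.5 (square root) damps the dominance of base peaks.
    ``modified_cosine`` additionally allows peak pairs offset by the
    precursor mass difference, linking spectra related by one modification.
    """

    similarity_cutoff: float = 0.70
    fragment_floor: float = 3000.0
    bin_tolerance: float = 0.01
    intensity_weighting: float = 0.5
    modified_cosine: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.similarity_cutoff <= 1:
            raise ValueError("similarity_cutoff must lie in [0, 1]")
        if self.bin_tolerance <= 0:
            raise ValueError("bin_tolerance must be positive")


@dataclass
class NetworkGraph:
    """An undirected similarity graph plus the spectra that stayed isolated."""

    graph: nx.Graph
    isolated: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _weighted_peaks(s: Spectrum, exponent: float) -> list[tuple[float, float]]:
    return [(f.mz, f.intensity**exponent) for f in s.fragments]


def spectral_similarity(
    a: Spectrum, b: Spectrum, cfg: NetworkConfig = NetworkConfig()
) -> float:
    """Cosine similarity of two spectra under greedy one-to-one peak matching.

    Peaks are intensity-weighted (``intensity**intensity_weighting``);
    candidate pairs within ``bin_tolerance`` (plus precursor-shifted pairs
    when ``modified_cosine``) are accepted greedily by descending weight
    product, each peak used at most once.  Symmetric, bounded in [0, 1],
    and 1.0 on identical spectra.  A spectrum with no fragments scores 0.
    """
    pa = _weighted_peaks(a, cfg.intensity_weighting)
    pb = _weighted_peaks(b, cfg.intensity_weighting)
    if not pa or not pb:
        return 0.0
    norm_a = math.sqrt(sum(w * w for _, w in pa))
    norm_b = math.sqrt(sum(w * w for _, w in pb))
    shifts = [0.0]
    if cfg.modified_cosine:
        shifts.append(a.precursor_mz - b.precursor_mz)
    pairs: list[tuple[float, int, int]] = []
    for shift in shifts:
        for i, (mza, wa) in enumerate(pa):
            for j, (mzb, wb) in enumerate(pb):
                if abs(mza - (mzb + shift)) <= cfg.bin_tolerance:
                    pairs.append((wa * wb, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    for product, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += product
    return min(score / (norm_a * norm_b), 1.0)


def build_network(
    spectra: Sequence[Spectrum],
    cfg: NetworkConfig = NetworkConfig(),
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> NetworkGraph:
    """All-pairs similarity graph thresholded at ``similarity_cutoff``.

    Only spectra participating in at least one edge become nodes; the rest
    are reported in ``isolated``.  ``node_attrs`` (id -> attribute mapping,
    e.g. prediction source or heatmap region) are attached to surviving
    nodes; the spectrum's charge is always recorded so downstream viewers
    can flag doubly charged nodes.
    """
    ids = [s.id for s in spectra]
    if len(ids) != len(set(ids)):
        raise ValueError("spectrum ids must be unique for networking")
    g = nx.Graph()
    order = sorted(range(len(spectra)), key=lambda i: spectra[i].id)
    for ii, i in enumerate(order):
        for j in order[ii + 1 :]:
            sim = spectral_similarity(spectra[i], spectra[j], cfg)
            if sim >= cfg.similarity_cutoff:
                g.add_edge(spectra[i].id, spectra[j].id, similarity=round(sim, 6))
    connected = set(g.nodes)
    isolated = sorted(set(ids) - connected)
    for s in spectra:
        if s.id in connected:
            g.nodes[s.id]["charge"] = s.charge
            if node_attrs and s.id in node_attrs:
                g.nodes[s.id].update(node_attrs[s.id])
    logger.info(
        "network: %d/%d spectra passed the %.0f%% cutoff (%d edges, %d isolated)",
        len(connected),
        len(ids),
        cfg.similarity_cutoff * 100,
        g.number_of_edges(),
        len(isolated),
    )
    return NetworkGraph(graph=g, isolated=isolated)


def export_graph(
    network: NetworkGraph, node_path: str | Path, edge_path: str | Path
) -> None:
    """Write node and edge TSVs with deterministic row order.

    The node file has one row per node with its attributes; the edge file
    has columns (source, target, similarity) with source < target.
    """
    g = network.graph
    node_rows = [{"id": n, **g.nodes[n]} for n in sorted(g.nodes)]
    node_cols = ["id"] + sorted({k for r in node_rows for k in r} - {"id"})
    pd.DataFrame(node_rows, columns=node_cols).to_csv(node_path, sep="\t", index=False)
    edge_rows = [
        {"source": min(u, v), "target": max(u, v), "similarity": d["similarity"]}
        for u, v, d in g.edges(data=True)
    ]
    edge_rows.sort(key=lambda r: (r["source"], r["target"]))
    pd.DataFrame(edge_rows, columns=["source", "target", "similarity"]).to_csv(
        edge_path, sep="\t", index=False
    )


def import_graph(node_path: str | Path, edge_path: str | Path) -> NetworkGraph:
    """Rebuild a :class:`NetworkGraph` from exported node/edge TSVs."""
    nodes = pd.read_csv(node_path, sep="\t", dtype={"id": str})
    edges = pd.read_csv(edge_path, sep="\t", dtype={"source": str, "target": str})
    g = nx.Graph()
    for _, row in nodes.iterrows():
        attrs = {k: v for k, v in row.items() if k != "id" and pd.notna(v)}
        g.add_node(row["id"], **attrs)
    for _, row in edges.iterrows():
        g.add_edge(row["source"], row["target"], similarity=float(row["similarity"]))
    return NetworkGraph(graph=g, isolated=[])
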