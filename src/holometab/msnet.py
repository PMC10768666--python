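"""Feature-based molecular networking.

Nodes are aligned LC-MS/MS features; edges encode modified-cosine spectral
similarity. The modified cosine pairs fragment peaks either directly (same
m/z within tolerance) or shifted by the precursor-mass difference, which
lets structural analogs connect. Edges are thresholded on score and matched
peak count, pruned to mutual top-K neighborhoods, and connected components
("molecular families") are capped to a maximum size by removing their lowest
scoring edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import Spectrum


@dataclass
class NetworkParams:
    """Networking thresholds.

    min_cosine / min_matched_peaks gate edges ("above 0.7", "more than six
    matched peaks"); with strict_matched_peaks the literal reading >= 7 is
    used, the compatibility flag False gives the common >= 6 convention.
    """

    min_cosine: float = 0.7
    min_matched_peaks: int = 6
    strict_matched_peaks: bool = True
    top_k: int = 10
    max_family_size: int = 100
    fragment_tol_da: float = 0.02
    library_min_score: float = 0.7
    library_min_peaks: int = 6

    def __post_init__(self):
        if not 0.0 <= self.min_cosine <= 1.0:
            raise ValueError("min_cosine must be in [0, 1]")
        if self.min_matched_peaks < 0 or self.top_k < 0 or self.max_family_size < 1:
            raise ValueError("counts must be positive")

    @property
    def required_matched_peaks(self) -> int:
        return self.min_matched_peaks + (1 if self.strict_matched_peaks else 0)


@dataclass(frozen=True)
class SpectralMatch:
    score: float
    n_matched_peaks: int
    pairs: tuple[tuple[int, int, bool], ...]  # (index in a, index in b, shifted)


def _norm_weights(spec: Spectrum) -> np.ndarray:
    w = np.sqrt(np.asarray(spec.intensities, dtype=float))
    n = np.linalg.norm(w)
    return w / n if n > 0 else w


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    tol_da: float = 0.02,
    allow_shift: bool = True,
) -> SpectralMatch:
    """GNPS-convention modified cosine between two MS/MS spectra.

    Intensities are sqrt-scaled and L2-normalized; peaks are pairable when
    their m/z agree within tol_da either directly or after shifting spectrum
    a's peaks by the precursor-mass difference. The score is the value of an
    exact maximum-weight one-to-one matching over all pairable peak pairs
    (solved as a linear assignment problem), so identical spectra score 1.
    """
    na, nb = a.n_peaks, b.n_peaks
    if na == 0 or nb == 0:
        return SpectralMatch(0.0, 0, ())
    wa, wb = _norm_weights(a), _norm_weights(b)
    shift = b.precursor_mz - a.precursor_mz
    dm = np.abs(a.mz[:, None] - b.mz[None, :])
    direct = dm <= tol_da
    allowed = direct.copy()
    shifted_only = np.zeros_like(direct)
    if allow_shift and abs(shift) > 1e-12:
        sm = np.abs(a.mz[:, None] + shift - b.mz[None, :]) <= tol_da
        shifted_only = sm & ~direct
        allowed |= sm
    if not allowed.any():
        return SpectralMatch(0.0, 0, ())
    weights = np.where(allowed, wa[:, None] * wb[None, :], 0.0)
    ri, ci = linear_sum_assignment(weights, maximize=True)
    pairs = []
    score = 0.0
    for i, j in zip(ri, ci):
        if allowed[i, j] and weights[i, j] > 0:
            pairs.append((int(i), int(j), bool(shifted_only[i, j])))
            score += float(weights[i, j])
    if score > 1.0 - 1e-12:  # guard accumulated float error; self-match is 1
        score = 1.0
    return SpectralMatch(score, len(pairs), tuple(pairs))


def cosine_direct(a: Spectrum, b: Spectrum, tol_da: float = 0.02) -> SpectralMatch:
    """Plain (non-shifted) dot-product cosine, used for identity matching."""
    return modified_cosine(a, b, tol_da=tol_da, allow_shift=False)


# --------------------------------------------------------------------------
# Edge construction and pruning
# --------------------------------------------------------------------------

EDGE_COLUMNS = ["u", "v", "score", "n_matched"]


def pairwise_similarity(
    spectra: Mapping[str, Spectrum],
    params: Optional[NetworkParams] = None,
) -> pd.DataFrame:
    """Score every unordered pair of features; returns a DataFrame with
    columns u, v, score, n_matched (u < v lexicographically)."""
    params = params or NetworkParams()
    ids = sorted(spectra)
    rows = []
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            m = modified_cosine(spectra[u], spectra[v], tol_da=params.fragment_tol_da)
            rows.append((u, v, m.score, m.n_matched_peaks))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def threshold_edges(edges: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    keep = (edges["score"] > params.min_cosine) & \
           (edges["n_matched"] >= params.required_matched_peaks)
    return edges.loc[keep].reset_index(drop=True)


def apply_mutual_topk(edges: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    """Keep edge (u,v) iff v is among u's top_k most similar neighbors AND u
    among v's. Ties at rank K are all kept."""
    if params.top_k == 0 or edges.empty:
        return edges.iloc[0:0].reset_index(drop=True)
    nbrs: dict[str, list[tuple[float, str]]] = {}
    for u, v, s in zip(edges["u"], edges["v"], edges["score"]):
        nbrs.setdefault(u, []).append((s, v))
        nbrs.setdefault(v, []).append((s, u))
    allowed: dict[str, set[str]] = {}
    for node, lst in nbrs.items():
        lst.sort(key=lambda t: (-t[0], t[1]))
        if len(lst) <= params.top_k:
            allowed[node] = {v for _, v in lst}
        else:
            cutoff = lst[params.top_k - 1][0]
            allowed[node] = {v for s, v in lst if s >= cutoff}
    keep = [v in allowed.get(u, set()) and u in allowed.get(v, set())
            for u, v in zip(edges["u"], edges["v"])]
    return edges.loc[keep].reset_index(drop=True)


def cap_family_size(edges: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    """Iteratively remove the globally lowest-scoring edge inside any
    over-sized connected component until every component has at most
    max_family_size nodes. Score ties break on lexicographic node ids."""
    g = nx.Graph()
    for u, v, s, n in edges.itertuples(index=False):
        g.add_edge(u, v, score=s, n_matched=n)
    removed = set()
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > params.max_family_size]
        if not oversized:
            break
        cand = []
        for comp in oversized:
            for u, v, d in g.subgraph(comp).edges(data=True):
                a, b = sorted((u, v))
                cand.append((d["score"], a, b))
        score, a, b = min(cand)
        g.remove_edge(a, b)
        removed.add(frozenset((a, b)))
    keep = [frozenset((u, v)) not in removed for u, v in zip(edges["u"], edges["v"])]
    return edges.loc[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# Network assembly
# --------------------------------------------------------------------------

@dataclass
class MolecularNetwork:
    """The molecular network: graph + family (connected component) labels."""

    graph: nx.Graph
    families: dict[str, int]
    edges: pd.DataFrame
    params: NetworkParams

    def family_members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, fam in self.families.items():
            out.setdefault(fam, set()).add(node)
        return out

    @property
    def n_families(self) -> int:
        return len(set(self.families.values()))


def build_network(table, params: Optional[NetworkParams] = None) -> MolecularNetwork:
    """Build the molecular network of a FeatureTable.

    Every feature becomes a node (singletons stay as size-1 families). Node
    attributes carry consensus m/z, RT and the per-sample intensity shares
    (the "pie chart" of each node). Edges survive the score / matched-peak
    thresholds, mutual top-K pruning and the family-size cap, in that order.
    """
    params = params or NetworkParams()
    spectra = {rid: s for rid, s in table.spectra.items()}
    missing = set(table.features.index) - set(spectra)
    if missing:
        raise ValueError(f"features without spectra: {sorted(missing)[:5]} ...")
    edges = pairwise_similarity(spectra, params)
    edges = threshold_edges(edges, params)
    edges = apply_mutual_topk(edges, params)
    edges = cap_family_size(edges, params)

    g = nx.Graph()
    inten = table.intensities
    for rid in table.features.index:
        shares = inten.loc[rid]
        if isinstance(shares.index, pd.MultiIndex):
            shares = shares.groupby(level=0).mean()
        g.add_node(rid, mz=float(table.features.loc[rid, "mz"]),
                   rt=float(table.features.loc[rid, "rt"]),
                   shares={k: float(v) for k, v in shares.items() if v > 0})
    for u, v, s, n in edges.itertuples(index=False):
        g.add_edge(u, v, score=float(s), n_matched=int(n))

    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    families = {}
    for fam_id, comp in enumerate(comps):
        for node in comp:
            families[node] = fam_id
    nx.set_node_attributes(g, families, "family")
    return MolecularNetwork(graph=g, families=families, edges=edges, params=params)


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

def export_graphml(network: MolecularNetwork, path) -> Path:
    """Write GraphML with scalar attributes; dict-valued attributes (the
    per-sample shares, annotations) are JSON-encoded strings."""
    g = nx.Graph()
    for node, data in network.graph.nodes(data=True):
        attrs = {}
        for k, v in data.items():
            attrs[k] = json.dumps(v, sort_keys=True) if isinstance(v, (dict, list)) else v
        g.add_node(node, **attrs)
    for u, v, data in network.graph.edges(data=True):
        g.add_edge(u, v, **data)
    path = Path(path)
    nx.write_graphml(g, path)
    return path


def import_graphml(path) -> nx.Graph:
    """Read back an exported network, decoding JSON-encoded attributes."""
    g = nx.read_graphml(str(path))
    for _, data in g.nodes(data=True):
        for k, v in list(data.items()):
            if isinstance(v, str) and v[:1] in "[{":
                try:
                    data[k] = json.loads(v)
                except json.JSONDecodeError:
                    pass
    return g


def export_edgelist_tsv(network: MolecularNetwork, path) -> Path:
    """GNPS-style edge list (CLUSTERID1, CLUSTERID2, Cosine, MatchedPeaks)."""
    df = network.edges.rename(columns={
        "u": "CLUSTERID1", "v": "CLUSTERID2",
        "score": "Cosine", "n_matched": "MatchedPeaks"})
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
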