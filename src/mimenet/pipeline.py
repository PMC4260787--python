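"""Network layer on top of windowed causality matrices.

Implements the constructions used downstream of the causality estimates:
time-averaged single-subject ("intra") networks via a fraction-of-maximum
threshold, signed contrast networks between two conditions via the
radius rule (R = (max - min)/2, significance beyond +-R/2), in/out degree
profiles and their contrasts, electrode-averaged cross-subject weight
series with dominance-based directed links, and threshold-perturbation
stability reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .mime_core import CausalityMatrix
from .signal_io import WindowSpec

__all__ = [
    "DirectedNetwork",
    "DegreeProfile",
    "CrossBrainWeightSeries",
    "average_matrices",
    "intra_network",
    "contrast_matrix",
    "contrast_network",
    "binarize_and_transpose",
    "network_from_adjacency",
    "degree_profiles",
    "average_profiles",
    "degree_contrast",
    "cross_brain_weights",
    "cross_brain_link",
    "threshold_sweep",
]

A_STRONGER = "A_stronger"  # "red": value significantly larger in condition A
B_STRONGER = "B_stronger"  # "green": larger in condition B


@dataclasses.dataclass
class DirectedNetwork:
    """Node-labelled directed graph with weighted edges.

    edges: list of (source, target, weight); ``signs`` optionally maps an
    edge (source, target) to A_STRONGER / B_STRONGER for contrast networks.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    signs: dict[tuple[str, str], str] | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for s, t, w in self.edges:
            if s == t:
                raise ValueError(f"self-loop on {s}")
            if s not in node_set or t not in node_set:
                raise ValueError(f"edge ({s}, {t}) references unknown node")
            if self.signs is None and w < 0:
                raise ValueError("unsigned network has a negative weight")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t, _ in self.edges}

    def edges_with_sign(self, sign: str) -> set[tuple[str, str]]:
        if self.signs is None:
            return set()
        return {e for e, s in self.signs.items() if s == sign}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, w in self.edges:
            attrs = {"weight": w}
            if self.signs:
                attrs["sign"] = self.signs[(s, t)]
            g.add_edge(s, t, **attrs)
        return g

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"source": s, "target": t, "weight": w,
             "sign": self.signs[(s, t)] if self.signs else ""}
            for s, t, w in self.edges
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]
                     ).to_csv(path, index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


@dataclasses.dataclass
class DegreeProfile:
    """Per-node in/out degrees (integer for one network, real after
    averaging over windows), plus the across-node mean as a summary row."""

    nodes: list[str]
    in_degree: np.ndarray
    out_degree: np.ndarray

    def __post_init__(self) -> None:
        self.in_degree = np.asarray(self.in_degree, dtype=np.float64)
        self.out_degree = np.asarray(self.out_degree, dtype=np.float64)
        if len(self.nodes) != self.in_degree.size != self.out_degree.size:
            raise ValueError("degree arrays must match the node list")
        if np.any(self.in_degree < 0) or np.any(self.out_degree < 0):
            raise ValueError("degrees must be nonnegative")

    @property
    def mean_in(self) -> float:
        return float(self.in_degree.mean())

    @property
    def mean_out(self) -> float:
        return float(self.out_degree.mean())

    def as_frame(self) -> pd.DataFrame:
        """Table with the overall mean appended as a pseudo-node row."""
        return pd.DataFrame({
            "node": self.nodes + ["MEAN"],
            "in_degree": np.append(self.in_degree, self.mean_in),
            "out_degree": np.append(self.out_degree, self.mean_out),
        })


@dataclasses.dataclass
class CrossBrainWeightSeries:
    """Per-window electrode-averaged cross-subject weights, one scalar per
    window for each ordered subject pair."""

    pairs: list[tuple[str, str]]
    weights: dict[tuple[str, str], np.ndarray]
    window_indices: list[int]

    def __post_init__(self) -> None:
        for p in self.pairs:
            w = np.asarray(self.weights[p], dtype=np.float64)
            if np.any(w < 0):
                raise ValueError(f"negative weight in series {p}")
            if w.size != len(self.window_indices):
                raise ValueError(f"series {p} does not cover every window")
            self.weights[p] = w

    def series(self, source: str, target: str) -> np.ndarray:
        return self.weights[(source, target)]

    def to_frame(self) -> pd.DataFrame:
        data = {"window": self.window_indices}
        data.update({f"{a}->{b}": self.weights[(a, b)]
                     for a, b in self.pairs})
        return pd.DataFrame(data)


def _check_compatible(a: CausalityMatrix, b: CausalityMatrix) -> None:
    if a.channel_labels != b.channel_labels:
        raise ValueError("channel labels differ between matrices")
    if a.values.shape != b.values.shape:
        raise ValueError("matrix shapes differ")


def average_matrices(mats: list[CausalityMatrix]) -> CausalityMatrix:
    """Entrywise mean over windows; window metadata replaced by the span."""
    if not mats:
        raise ValueError("no matrices to average")
    for m in mats[1:]:
        _check_compatible(mats[0], m)
    mean = np.mean([m.values for m in mats], axis=0)
    specs = [m.window for m in mats if m.window is not None]
    window = None
    if specs:
        window = WindowSpec(
            length_s=sum(s.length_s for s in specs),
            index=min(s.index for s in specs),
            start_s=min(s.start_s for s in specs),
            end_s=max(s.end_s for s in specs),
        )
    return CausalityMatrix(mean, list(mats[0].channel_labels), window=window,
                           block_boundaries=mats[0].block_boundaries,
                           params=mats[0].params)


def _intra_threshold(avg: CausalityMatrix, frac: float) -> float:
    return frac * float(avg.off_diagonal().max()) if avg.n_channels > 1 else 0.0


def intra_network(avg: CausalityMatrix, frac: float) -> DirectedNetwork:
    """Directed network from a time-averaged single-subject matrix.

    An edge i -> j is kept iff avg(i, j) >= frac * max(off-diagonal) and
    avg(i, j) > 0. The comparison is inclusive so that a uniform matrix
    yields the complete network rather than an empty one.
    """
    if not 0 < frac < 1:
        raise ValueError(f"threshold fraction must be in (0,1), got {frac}")
    thr = _intra_threshold(avg, frac)
    labels = avg.channel_labels
    edges = [
        (labels[i], labels[j], float(avg.values[i, j]))
        for i in range(avg.n_channels)
        for j in range(avg.n_channels)
        if i != j and avg.values[i, j] > 0 and avg.values[i, j] >= thr
    ]
    return DirectedNetwork(nodes=list(labels), edges=edges)


def contrast_matrix(avgA: CausalityMatrix,
                    avgB: CausalityMatrix) -> np.ndarray:
    """Signed entrywise difference avgA - avgB (condition A minus B)."""
    _check_compatible(avgA, avgB)
    return avgA.values - avgB.values


def contrast_radius(contrast: np.ndarray) -> float:
    """Half the spread of the off-diagonal contrast values."""
    contrast = np.asarray(contrast, dtype=np.float64)
    mask = ~np.eye(contrast.shape[0], dtype=bool)
    off = contrast[mask]
    return float(off.max() - off.min()) / 2.0


def contrast_network(contrast: np.ndarray, labels: list[str] | None = None,
                     radius_divisor: float = 2.0,
                     threshold: float | None = None) -> DirectedNetwork:
    """Signed network from a contrast matrix.

    The significance threshold defaults to R / radius_divisor with
    R = (global max - global min) / 2 over off-diagonal entries; entries
    strictly outside [-thr, +thr] are significant. Positive entries become
    A_stronger ("red") edges, negative ones B_stronger ("green"). A
    zero-range matrix yields an empty network.
    """
    contrast = np.asarray(contrast, dtype=np.float64)
    k = contrast.shape[0]
    if contrast.shape != (k, k):
        raise ValueError("contrast matrix must be square")
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    if threshold is None:
        threshold = contrast_radius(contrast) / radius_divisor
    edges, signs = [], {}
    if threshold > 0:
        for i in range(k):
            for j in range(k):
                v = contrast[i, j]
                if i != j and abs(v) > threshold:
                    edges.append((labels[i], labels[j], float(v)))
                    signs[(labels[i], labels[j])] = (
                        A_STRONGER if v > 0 else B_STRONGER)
    return DirectedNetwork(nodes=labels, edges=edges, signs=signs)


def binarize_and_transpose(mat: CausalityMatrix, frac: float) -> np.ndarray:
    """Binary matrix of suprathreshold entries (intra_network rule),
    transposed: adjacency[i, j] = 1 records an edge j -> i. The directed
    graph it encodes (see :func:`network_from_adjacency`) is identical to
    intra_network's edge set."""
    if not 0 < frac < 1:
        raise ValueError(f"threshold fraction must be in (0,1), got {frac}")
    thr = _intra_threshold(mat, frac)
    binary = ((mat.values > 0) & (mat.values >= thr)
              & ~np.eye(mat.n_channels, dtype=bool))
    return binary.T.astype(np.int8)


def network_from_adjacency(adj: np.ndarray,
                           labels: list[str]) -> DirectedNetwork:
    """Rebuild the directed graph from a transposed binary adjacency:
    adj[i, j] = 1 encodes the edge j -> i."""
    adj = np.asarray(adj)
    edges = [
        (labels[j], labels[i], 1.0)
        for i in range(adj.shape[0])
        for j in range(adj.shape[1])
        if adj[i, j]
    ]
    return DirectedNetwork(nodes=list(labels), edges=edges)


def degree_profiles(net: DirectedNetwork) -> DegreeProfile:
    """In/out degree counts per node."""
    idx = {n: i for i, n in enumerate(net.nodes)}
    indeg = np.zeros(len(net.nodes))
    outdeg = np.zeros(len(net.nodes))
    for s, t, _ in net.edges:
        outdeg[idx[s]] += 1
        indeg[idx[t]] += 1
    return DegreeProfile(list(net.nodes), indeg, outdeg)


def average_profiles(profiles: list[DegreeProfile]) -> DegreeProfile:
    """Real-valued mean of degree profiles over windows/conditions."""
    if not profiles:
        raise ValueError("no profiles to average")
    nodes = profiles[0].nodes
    for p in profiles[1:]:
        if p.nodes != nodes:
            raise ValueError("profiles cover different node sets")
    return DegreeProfile(
        list(nodes),
        np.mean([p.in_degree for p in profiles], axis=0),
        np.mean([p.out_degree for p in profiles], axis=0),
    )


def degree_contrast(profilesA: DegreeProfile,
                    profilesB: DegreeProfile) -> pd.DataFrame:
    """Per-node signed degree contrasts (A - B) with the overall-mean
    contrast appended as a pseudo-node row."""
    if profilesA.nodes != profilesB.nodes:
        raise ValueError("profiles cover different node sets")
    return pd.DataFrame({
        "node": profilesA.nodes + ["MEAN"],
        "in_contrast": np.append(profilesA.in_degree - profilesB.in_degree,
                                 profilesA.mean_in - profilesB.mean_in),
        "out_contrast": np.append(profilesA.out_degree - profilesB.out_degree,
                                  profilesA.mean_out - profilesB.mean_out),
    })


def cross_brain_weights(mats: list[CausalityMatrix]
                        ) -> CrossBrainWeightSeries:
    """Electrode-averaged off-diagonal block weight per window for every
    ordered subject pair of augmented matrices."""
    if not mats:
        raise ValueError("no matrices supplied")
    if not mats[0].block_boundaries:
        raise ValueError("matrices carry no block boundaries")
    subjects = list(mats[0].block_boundaries)
    pairs = [(a, b) for a in subjects for b in subjects if a != b]
    weights = {p: [] for p in pairs}
    indices = []
    for w, m in enumerate(mats, start=1):
        if m.block_boundaries != mats[0].block_boundaries:
            raise ValueError("block boundaries differ across windows")
        indices.append(m.window.index if m.window else w)
        for a, b in pairs:
            weights[(a, b)].append(float(m.block(a, b).mean()))
    return CrossBrainWeightSeries(
        pairs=pairs,
        weights={p: np.asarray(v) for p, v in weights.items()},
        window_indices=indices,
    )


def cross_brain_link(wAB: np.ndarray, wBA: np.ndarray,
                     delta: float = 0.10) -> str | None:
    """Dominance decision for one ordered subject pair.

    A direction dominates a window when its weight exceeds (1 + delta)
    times the mean of the two directions' weights in that window. A link
    is drawn in direction d when d dominates a strict majority of windows
    and its time-averaged weight exceeds the reverse direction's; when
    neither direction satisfies this the flows cancel and no link is drawn.

    Returns "AB", "BA" or None.
    """
    wAB = np.asarray(wAB, dtype=np.float64)
    wBA = np.asarray(wBA, dtype=np.float64)
    if wAB.shape != wBA.shape:
        raise ValueError("weight series lengths differ")
    if wAB.size == 0:
        return None
    bar = (1.0 + delta) * (wAB + wBA) / 2.0
    dom_ab = int(np.sum(wAB > bar))
    dom_ba = int(np.sum(wBA > bar))
    half = wAB.size / 2.0
    if dom_ab > half and wAB.mean() > wBA.mean():
        return "AB"
    if dom_ba > half and wBA.mean() > wAB.mean():
        return "BA"
    return None


def _edge_key(edge: tuple[str, str]) -> str:
    return f"{edge[0]}->{edge[1]}"


def threshold_sweep(mat, base_threshold: float,
                    perturbations: tuple[float, ...] = (-0.1, 0.1),
                    kind: str = "intra",
                    labels: list[str] | None = None) -> dict:
    """Edge-set stability under threshold perturbation.

    kind="intra": ``mat`` is a CausalityMatrix and ``base_threshold`` the
    fraction of the off-diagonal maximum. kind="contrast": ``mat`` is a
    signed contrast array and ``base_threshold`` the absolute significance
    threshold (pass contrast_radius(mat)/2 for the default rule). For each
    perturbation p the threshold becomes base*(1+p). The report lists the
    base edges, per-perturbation gained/lost edges, and the "dominant"
    edges present at every perturbation.
    """
    for p in perturbations:
        if p <= -1:
            raise ValueError("perturbation must be > -1")

    def edges_at(thr):
        if kind == "intra":
            # inline rule rather than intra_network so that perturbed
            # fractions >= 1 (e.g. +100% sweeps) stay well-defined
            t = thr * float(mat.off_diagonal().max())
            lab = mat.channel_labels
            return {
                (lab[i], lab[j])
                for i in range(mat.n_channels)
                for j in range(mat.n_channels)
                if i != j and mat.values[i, j] > 0 and mat.values[i, j] >= t
            }
        if kind == "contrast":
            return contrast_network(mat, labels, threshold=thr).edge_set()
        raise ValueError(f"unknown kind {kind!r}")

    base_edges = edges_at(base_threshold)
    report = {
        "kind": kind,
        "base_threshold": base_threshold,
        "base_edges": sorted(map(_edge_key, base_edges)),
        "perturbations": {},
    }
    dominant = set(base_edges)
    for p in perturbations:
        edges = edges_at(base_threshold * (1.0 + p))
        dominant &= edges
        report["perturbations"][f"{p:+g}"] = {
            "threshold": base_threshold * (1.0 + p),
            "edges": sorted(map(_edge_key, edges)),
            "gained": sorted(map(_edge_key, edges - base_edges)),
            "lost": sorted(map(_edge_key, base_edges - edges)),
        }
    report["dominant_edges"] = sorted(map(_edge_key, dominant))
    report["stable"] = all(
        not v["gained"] and not v["lost"]
        for v in report["perturbations"].values()
    )
    return report


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
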