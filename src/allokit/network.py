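"""Weighted residue-interaction networks and allosteric communication paths.

Edges connect residue pairs whose generalized correlation coefficient
R_MI = sqrt(1 - exp(-2 I / d)) exceeds 0.5 in at least one independent
ensemble, with edge length w_ij = -log R_MI, so strongly correlated pairs
are communication shortcuts.  The mutual information I between two
residues' fluctuation vectors is estimated with the closed-form Gaussian
estimator by default (d = 3 dimensions per residue).  When a per-residue
proximity coevolution score (pMI) is supplied, a fourth coordinate is
appended to every residue's fluctuation description: a unit-variance
Gaussian channel whose inter-residue correlation is the product of the
residues' max-normalized pMI values, so strongly coevolving pairs gain
mutual information on top of their dynamic coupling (d = 4).

Shortest paths between all residue pairs are computed with the
Floyd–Warshall algorithm; edge betweenness (fraction of shortest paths
through an edge) and ranked effector-to-sensor pathways expose the
network's communication backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import floyd_warshall

from .dynamics import TrajectoryEnsemble, superpose_frames
from .structure import ContactMap

RMI_EDGE_THRESHOLD = 0.5
RMI_CAP = 1.0 - 1e-12


@dataclass
class GeneralizedCorrelationMatrix:
    """Stack of N x N generalized correlation matrices, one per ensemble."""

    stack: np.ndarray            # (S, N, N), values in [0, 1], diagonal 1
    estimator: str = "gaussian"
    with_coevolution: bool = False

    @property
    def n_residues(self) -> int:
        return self.stack.shape[1]

    def max_over_simulations(self) -> np.ndarray:
        return np.nanmax(self.stack, axis=0)


@dataclass
class ShortestPathMatrix:
    distances: np.ndarray        # (N, N)
    predecessors: np.ndarray     # (N, N) int, -9999 where undefined
    node_list: list

    def path(self, source: int, target: int) -> Optional[list]:
        """Reconstruct one shortest path from the predecessor matrix."""
        si = self.node_list.index(source)
        ti = self.node_list.index(target)
        if not np.isfinite(self.distances[si, ti]):
            return None
        out = [ti]
        while out[-1] != si:
            prev = self.predecessors[si, out[-1]]
            if prev < 0:
                return None
            out.append(int(prev))
        return [self.node_list[i] for i in reversed(out)]


@dataclass
class CommunicationPath:
    source: int
    target: int
    nodes: list
    total_weight: float


@dataclass
class CommunicationPathSet:
    paths: list                  # CommunicationPath, ranked by total weight
    unreachable: list            # (source, target) pairs with no route
    node_traversal_counts: dict  # node -> number of top paths through it

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"source": p.source, "target": p.target,
             "total_weight": p.total_weight,
             "nodes": "-".join(str(n) for n in p.nodes)}
            for p in self.paths])


def gaussian_mutual_information(cov_ii: np.ndarray, cov_jj: np.ndarray,
                                cov_ij: np.ndarray) -> float:
    """Closed-form MI of two jointly Gaussian vectors from their
    marginal and cross covariance blocks:
    I = 0.5 ln[det(C_ii) det(C_jj) / det(C_joint)]."""
    d = cov_ii.shape[0]
    joint = np.block([[cov_ii, cov_ij], [cov_ij.T, cov_jj]])
    sign_m, ld_i = np.linalg.slogdet(cov_ii)
    sign_n, ld_j = np.linalg.slogdet(cov_jj)
    sign_q, ld_joint = np.linalg.slogdet(joint)
    if sign_m <= 0 or sign_n <= 0:
        raise np.linalg.LinAlgError("singular marginal covariance")
    if sign_q <= 0:
        return np.inf
    return max(0.5 * (ld_i + ld_j - ld_joint), 0.0)


def rmi_from_mi(mi: float, d: int) -> float:
    """Map mutual information to the [0, 1] generalized correlation
    coefficient, R_MI = sqrt(1 - exp(-2 I / d))."""
    if np.isinf(mi):
        return 1.0
    return float(np.sqrt(max(1.0 - np.exp(-2.0 * mi / d), 0.0)))


def generalized_correlation(trajectories: Sequence[TrajectoryEnsemble],
                            pmi: Optional[np.ndarray] = None,
                            superpose: bool = True,
                            singular_tol: float = 1e-10
                            ) -> GeneralizedCorrelationMatrix:
    """Per-ensemble generalized correlation matrices from residue
    fluctuation vectors (Gaussian MI estimator).

    With ``pmi``, each residue's 3-D fluctuation vector gains a static
    coevolution channel: unit variance, cross-correlation
    p_i * p_j with p the pMI profile scaled to [0, 1) by its maximum
    (NaNs contribute 0), adding -0.5 ln(1 - (p_i p_j)^2) of mutual
    information per pair at d = 4.  Pairs with near-singular marginal
    covariance are masked (NaN) with a warning.
    """
    if len(trajectories) == 0:
        raise ValueError("need at least one ensemble")
    n = trajectories[0].n_residues
    if any(t.n_residues != n for t in trajectories):
        raise ValueError("ensembles disagree on residue count")

    coevo_rho = None
    d_dims = 3
    if pmi is not None:
        p = np.nan_to_num(np.asarray(pmi, float), nan=0.0)
        top = p.max()
        scaled = p / (top * (1.0 + 1e-9)) if top > 0 else np.zeros_like(p)
        coevo_rho = np.outer(scaled, scaled)
        d_dims = 4

    mats = []
    for traj in trajectories:
        frames = superpose_frames(traj.frames) if superpose else traj.frames
        F = frames.shape[0]
        flat = frames.reshape(F, -1)
        dR = flat - flat.mean(axis=0)
        C = dR.T @ dR / F
        blocks = C.reshape(n, 3, n, 3)
        rmi = np.eye(n)
        for i in range(n):
            cii = blocks[i, :, i, :]
            if np.linalg.det(cii) < singular_tol:
                import logging
                logging.getLogger(__name__).warning(
                    "near-singular fluctuation covariance at residue %d; "
                    "its pairs are masked", i)
                rmi[i, :] = np.nan
                rmi[:, i] = np.nan
                rmi[i, i] = 1.0
                continue
            for j in range(i + 1, n):
                cjj = blocks[j, :, j, :]
                if np.linalg.det(cjj) < singular_tol:
                    continue
                try:
                    mi = gaussian_mutual_information(cii, cjj,
                                                    blocks[i, :, j, :])
                except np.linalg.LinAlgError:
                    rmi[i, j] = rmi[j, i] = np.nan
                    continue
                if coevo_rho is not None:
                    rho = min(coevo_rho[i, j], RMI_CAP)
                    mi += -0.5 * np.log1p(-rho * rho)
                rmi[i, j] = rmi[j, i] = rmi_from_mi(mi, d_dims)
        mats.append(rmi)
    return GeneralizedCorrelationMatrix(
        stack=np.stack(mats), estimator="gaussian",
        with_coevolution=pmi is not None)


def build_network(rmi: GeneralizedCorrelationMatrix,
                  contacts: Optional[ContactMap] = None,
                  threshold: float = RMI_EDGE_THRESHOLD) -> nx.Graph:
    """Weighted residue graph: keep an edge when the max-over-ensembles
    R_MI strictly exceeds ``threshold`` (and, when a contact map is given,
    the pair is a structural contact); weight = -log of that max R_MI,
    capped just below 1 so weights stay finite and non-negative."""
    best = rmi.max_over_simulations()
    n = rmi.n_residues
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            v = best[i, j]
            if not np.isfinite(v) or v <= threshold:
                continue
            if contacts is not None and not contacts.contacts[i, j]:
                continue
            capped = min(v, RMI_CAP)
            g.add_edge(i, j, rmi=float(v), weight=float(-np.log(capped)))
    return g


def all_shortest_paths(g: nx.Graph) -> ShortestPathMatrix:
    """Exact all-pairs shortest distances and predecessors
    (Floyd–Warshall on the dense weight matrix)."""
    nodes = sorted(g.nodes())
    n = len(nodes)
    pos = {u: k for k, u in enumerate(nodes)}
    W = np.full((n, n), np.inf)
    np.fill_diagonal(W, 0.0)
    for u, v, data in g.edges(data=True):
        w = data["weight"]
        if w < 0:
            raise ValueError("negative edge weight")
        W[pos[u], pos[v]] = W[pos[v], pos[u]] = w
    dist, pred = floyd_warshall(W, directed=False, return_predecessors=True)
    return ShortestPathMatrix(distances=dist, predecessors=pred,
                              node_list=nodes)


def edge_betweenness(g: nx.Graph) -> dict:
    """Fraction of all shortest paths traversing each edge, with equal
    splitting among ties; values lie in [0, 1]."""
    return nx.edge_betweenness_centrality(g, weight="weight",
                                          normalized=True)


def communication_pathways(g: nx.Graph, effectors: Sequence[int],
                           sensors: Sequence[int],
                           k_paths: int = 3) -> CommunicationPathSet:
    """Ranked effector-to-sensor routes: for every (effector, sensor) pair
    the shortest path plus up to k-1 next-shortest loopless alternatives
    (Yen's algorithm); per-node traversal counts expose gate-keeper
    residues."""
    if not effectors or not sensors:
        raise ValueError("effector and sensor sets must be non-empty")
    missing = [u for u in list(effectors) + list(sensors) if u not in g]
    if missing:
        raise ValueError(f"nodes absent from the graph: {missing}")
    paths: list[CommunicationPath] = []
    unreachable: list[tuple] = []
    for e in effectors:
        for s in sensors:
            if e == s:
                continue
            try:
                gen = nx.shortest_simple_paths(g, e, s, weight="weight")
                for _ in range(k_paths):
                    nodes = next(gen, None)
                    if nodes is None:
                        break
                    total = sum(g[u][v]["weight"]
                                for u, v in zip(nodes, nodes[1:]))
                    paths.append(CommunicationPath(
                        source=e, target=s, nodes=list(nodes),
                        total_weight=total))
            except nx.NetworkXNoPath:
                unreachable.append((e, s))
    paths.sort(key=lambda p: p.total_weight)
    counts: dict[int, int] = {}
    for p in paths:
        for u in p.nodes:
            counts[u] = counts.get(u, 0) + 1
    return CommunicationPathSet(paths=paths, unreachable=unreachable,
                                node_traversal_counts=counts)


def export_edge_list(g: nx.Graph) -> pd.DataFrame:
    rows = [{"i": u, "j": v, "rmi": d["rmi"], "weight": d["weight"]}
            for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["i", "j", "rmi", "weight"])
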