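"""Viral cohorts: MCL clustering of the significant-LS network.

The significant local-similarity edges among vOTUs (and, by default, the
host genomovar series themselves) form a weighted undirected graph;
Markov clustering partitions it into "viral cohorts" — sets of viruses
with coherent abundance trajectories.  A cohort containing exactly one
host node is assigned to that genomovar; with several hosts the one with
the highest mean |LS| to the cohort's vOTUs wins.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import AbundanceMatrix
from .lsa import LSEdge

__all__ = ["ViralCohort", "build_graph", "mcl", "assign_cohorts", "cohort_abundance"]


@dataclass
class ViralCohort:
    cohort_id: str
    members: list[str]                 # vOTU ids
    assigned_genomovar: str | None
    mean_abs_ls: float                 # to the assigned genomovar; NaN if none


def build_graph(edges: Iterable[LSEdge], include_hosts: bool = True, host_ids: Sequence[str] = ()) -> nx.Graph:
    """Weighted graph of significant edges (weight = |ls|, sign kept as
    attribute).  Host series can be excluded; series with no significant
    edge do not appear.  Duplicate unordered pairs are an error."""
    hosts = set(host_ids)
    g = nx.Graph()
    seen = set()
    for e in edges:
        if not e.significant:
            continue
        key = frozenset((e.series_a, e.series_b))
        if key in seen:
            raise ValueError(f"duplicate edge for pair {sorted(key)}")
        seen.add(key)
        if not include_hosts and (e.series_a in hosts or e.series_b in hosts):
            continue
        g.add_edge(e.series_a, e.series_b, weight=abs(e.ls), ls=e.ls, delay=e.delay)
    return g


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    self_loops: bool = True,
    prune: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[list[str]]:
    """Markov Clustering of a weighted graph.

    The column-stochastic transition matrix (self-loops added) is
    alternately expanded (matrix power) and inflated (elementwise power,
    renormalized, small entries pruned) until the change falls below
    ``tol``.  Each node joins the cluster of its heaviest attractor row;
    ties break lexicographically, making the partition deterministic.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    n = len(nodes)
    W = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    if self_loops:
        np.fill_diagonal(W, W.diagonal() + 1.0)
    M = W / W.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        M2 = np.linalg.matrix_power(M, expansion)
        np.power(M2, inflation, out=M2)
        M2[M2 < prune] = 0.0
        M2 /= M2.sum(axis=0, keepdims=True)
        delta = np.abs(M2 - M).max()
        M = M2
        if delta < tol:
            break
    else:
        raise RuntimeError(f"MCL did not converge in {max_iter} iterations (residual {delta:.2e})")
    clusters: dict[int, list[str]] = {}
    for j in range(n):
        rows = np.flatnonzero(M[:, j] > prune)
        if rows.size == 0:
            rows = np.array([j])
        # heaviest attractor; lexicographic node id breaks exact ties
        best = min(
            ((-M[i, j], nodes[i]) for i in rows),
        )[1]
        clusters.setdefault(nodes.index(best), []).append(nodes[j])
    return sorted((sorted(m) for m in clusters.values()), key=lambda m: (-len(m), m[0]))


def assign_cohorts(
    partition: Sequence[Sequence[str]],
    host_ids: Sequence[str],
    graph: nx.Graph | None = None,
) -> list[ViralCohort]:
    """Turn an MCL partition into viral cohorts with genomovar assignments.

    Cohorts are numbered VC1, VC2, ... by descending vOTU count.  A
    cluster with one host is that genomovar's cohort; several hosts are
    disambiguated by mean |LS| between each host and the cluster's vOTUs
    (requires the graph); a host-free cluster stays unassigned.
    """
    hosts = set(host_ids)
    prelim = []
    for cluster in partition:
        members = sorted(m for m in cluster if m not in hosts)
        in_hosts = sorted(m for m in cluster if m in hosts)
        if not members:
            continue
        if len(in_hosts) == 1:
            assigned = in_hosts[0]
        elif len(in_hosts) > 1:
            if graph is None:
                raise ValueError("graph needed to disambiguate a multi-host cluster")
            def mean_ls(h: str) -> float:
                w = [graph[h][v]["weight"] for v in members if graph.has_edge(h, v)]
                return float(np.mean(w)) if w else 0.0
            assigned = max(in_hosts, key=lambda h: (mean_ls(h), h))
        else:
            assigned = None
        if assigned is not None and graph is not None:
            w = [graph[assigned][v]["weight"] for v in members if graph.has_edge(assigned, v)]
            mls = float(np.mean(w)) if w else float("nan")
        else:
            mls = float("nan")
        prelim.append((members, assigned, mls))
    prelim.sort(key=lambda t: (-len(t[0]), t[0][0]))
    return [
        ViralCohort(cohort_id=f"VC{i}", members=m, assigned_genomovar=a, mean_abs_ls=l)
        for i, (m, a, l) in enumerate(prelim, start=1)
    ]


def cohort_abundance(cohorts: Sequence[ViralCohort], votu_matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Per-sample summed abundance of each cohort's member vOTUs."""
    rows = {}
    flags = {}
    for c in cohorts:
        missing = [m for m in c.members if m not in votu_matrix.values.index]
        if missing:
            raise ValueError(f"cohort {c.cohort_id}: members missing from matrix: {missing}")
        rows[c.cohort_id] = votu_matrix.values.loc[c.members].sum(axis=0)
        flags[c.cohort_id] = votu_matrix.flags.loc[c.members].all(axis=0)
    return AbundanceMatrix(values=pd.DataFrame(rows).T, flags=pd.DataFrame(flags).T)
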