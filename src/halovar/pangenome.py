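"""Pangenome structure: orthology groups, occurrence classes, openness.

Genes are clustered greedily into orthology groups (OGs) CD-HIT style:
longest first, each gene joining the cluster whose representative aligns
best at >=90% identity over >=70% of the shorter sequence, otherwise
founding its own.  OG occurrence p = n/N over genomes classifies genes as
core (p >= 90%), common (20% <= p < 90%), rare (1/N < p < 20%) or
genome-specific (p = 1/N).  Pangenome openness is the Heaps' law exponent
gamma of the rarefaction curve (distinct OGs vs genomes sampled); gamma
near 0 means a closed pangenome, larger gamma an open one.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .align import best_local
from .io import GenomeRecord

__all__ = [
    "OrthologyGroup",
    "greedy_cluster_genes",
    "occurrence_class",
    "og_presence_matrix",
    "heaps_gamma",
]

OccClass = Literal["core", "common", "rare", "specific"]


@dataclass
class OrthologyGroup:
    og_id: str
    representative: str
    members: list[str]            # gene ids
    genomes: list[str]            # source genome per member (parallel list)

    @property
    def occurrence(self) -> int:
        return len(set(self.genomes))


def _source_genome(gene_id: str) -> str:
    # gene ids follow "<genome>|<gene>"; a bare id is its own genome
    return gene_id.split("|", 1)[0]


def greedy_cluster_genes(
    genes: Sequence[GenomeRecord],
    identity: float = 90.0,
    coverage_short: float = 70.0,
) -> list[OrthologyGroup]:
    """Greedy incremental clustering of gene sequences into OGs.

    Genes are processed longest-first (ties by id); each joins the best
    existing cluster (highest representative identity meeting both
    thresholds) — the best-cluster rule, not first-fit — else founds a new
    cluster.  The representative is the founding (largest) gene.
    """
    order = sorted(genes, key=lambda g: (-len(g.sequence), g.id))
    reps: list[GenomeRecord] = []
    members: list[list[str]] = []
    max_frac = 1 - identity / 100.0
    for gene in order:
        best_i = -1
        best_ident = -1.0
        for i, rep in enumerate(reps):
            hit = best_local(gene.sequence, rep.sequence, max_distance=int(len(gene.sequence) * max_frac) + 1)
            if hit is None:
                continue
            if hit.identity >= identity and hit.coverage >= coverage_short and hit.identity > best_ident:
                best_ident = hit.identity
                best_i = i
        if best_i >= 0:
            members[best_i].append(gene.id)
        else:
            reps.append(gene)
            members.append([gene.id])
    out = []
    for i, (rep, mem) in enumerate(zip(reps, members), start=1):
        out.append(
            OrthologyGroup(
                og_id=f"OG{i:05d}",
                representative=rep.id,
                members=mem,
                genomes=[_source_genome(m) for m in mem],
            )
        )
    return out


def occurrence_class(n: int, N: int) -> OccClass:
    """Occurrence class from p = n/N (n genomes carrying the OG out of N)."""
    if not 1 <= n <= N:
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    if N == 1:
        return "core"
    if n == 1:
        return "specific"
    p = 100.0 * n / N
    if p >= 90.0:
        return "core"
    if p >= 20.0:
        return "common"
    return "rare"


def og_presence_matrix(ogs: Sequence[OrthologyGroup], genome_ids: Sequence[str]) -> pd.DataFrame:
    """Genome x OG boolean presence matrix."""
    mat = pd.DataFrame(False, index=list(genome_ids), columns=[o.og_id for o in ogs])
    for og in ogs:
        for g in set(og.genomes):
            mat.loc[g, og.og_id] = True
    return mat


def heaps_gamma(
    presence: pd.DataFrame,
    n_permutations: int = 20,
    seed: int = 0,
) -> float:
    """Heaps' law exponent of the pangenome rarefaction curve.

    For each of ``n_permutations`` random genome orders the cumulative
    number of distinct OGs is accumulated; gamma is the log-log least
    squares slope of the permutation-median curve.  A constant curve
    (closed pangenome) yields gamma 0.
    """
    M = presence.to_numpy(dtype=bool)
    n = M.shape[0]
    if n < 5:
        raise ValueError("need at least 5 genomes for a rarefaction fit")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_permutations, n), dtype=float)
    for p in range(n_permutations):
        idx = rng.permutation(n)
        seen = np.zeros(M.shape[1], dtype=bool)
        for k, g in enumerate(idx):
            seen |= M[g]
            curves[p, k] = seen.sum()
    med = np.median(curves, axis=0)
    if med[0] <= 0:
        raise ValueError("empty gene sets: rarefaction curve starts at 0")
    k = np.arange(1, n + 1)
    slope, _ = np.polyfit(np.log(k), np.log(med), 1)
    return float(slope)
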