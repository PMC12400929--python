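"""Quality gating of MAGs and ANI-based genomovar delineation.

A genomovar is a group of genomes sharing >99.5% ANI (and typically
>99% of their genes).  Clustering is average-linkage agglomeration on
distance 100 - ANI with the tree cut at 0.5, so members of one cluster
sit above the 99.5% ANI threshold on average while between-cluster ANI
stays at or below it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import GenomeRecord

__all__ = [
    "GenomovarCluster",
    "quality_gate",
    "quality_score",
    "cluster_genomovars",
    "shared_gene_fraction",
]


@dataclass
class GenomovarCluster:
    genomovar_id: str
    members: list[str]
    representative: str
    mean_within_ani: float
    min_within_ani: float


def quality_gate(
    genomes: Sequence[GenomeRecord],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> list[GenomeRecord]:
    """Keep MAGs with completeness >= 50% and contamination strictly < 10%."""
    return [
        g
        for g in genomes
        if g.completeness >= min_completeness and g.contamination < max_contamination
    ]


def quality_score(completeness: float, contamination: float) -> float:
    """MAG quality score: completeness - 5 x contamination."""
    if not (0 <= completeness <= 100 and 0 <= contamination <= 100):
        raise ValueError("completeness/contamination outside [0,100]")
    return completeness - 5.0 * contamination


def cluster_genomovars(
    ani: pd.DataFrame,
    ani_cut: float = 99.5,
    quality: dict[str, float] | None = None,
) -> list[GenomovarCluster]:
    """Average-linkage clustering of an ANI matrix cut at 100 - ani_cut.

    Clusters are labelled Gv1, Gv2, ... in descending size (ties broken by
    lexicographically smallest member), which makes output invariant to
    input permutation.  The representative is the member with the highest
    quality score (all-equal scores fall back to the smallest id).
    Undefined (NaN) ANI entries are refused with the offending pairs named.
    """
    ids = list(ani.index)
    if list(ani.columns) != ids:
        raise ValueError("ANI matrix must have identical row/column labels")
    bad = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if math.isnan(ani.iat[i, j])
    ]
    if bad:
        raise ValueError(f"undefined ANI for pairs: {bad}")
    order = np.argsort(ids)
    ids_sorted = [ids[i] for i in order]
    mat = ani.loc[ids_sorted, ids_sorted].to_numpy(dtype=float)
    dist = 100.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry for squareform
    if len(ids_sorted) == 1:
        labels = np.array([1])
    else:
        Z = linkage(squareform(dist, checks=False), method="average")
        # strict cut: genomes merge only when their linkage distance is
        # below 100 - ani_cut, i.e. within-ANI strictly above the cut
        labels = fcluster(Z, t=(100.0 - ani_cut) * (1 - 1e-12), criterion="distance")
    groups: dict[int, list[str]] = {}
    for gid, lab in zip(ids_sorted, labels):
        groups.setdefault(int(lab), []).append(gid)
    ordered = sorted(groups.values(), key=lambda m: (-len(m), min(m)))
    out = []
    for i, members in enumerate(ordered, start=1):
        members = sorted(members)
        if len(members) > 1:
            sub = ani.loc[members, members].to_numpy(dtype=float)
            tri = sub[np.triu_indices(len(members), k=1)]
            mean_w, min_w = float(tri.mean()), float(tri.min())
        else:
            mean_w = min_w = 100.0
        if quality:
            rep = max(members, key=lambda m: (quality.get(m, -math.inf), m))
        else:
            rep = members[0]
        out.append(
            GenomovarCluster(
                genomovar_id=f"Gv{i}",
                members=members,
                representative=rep,
                mean_within_ani=mean_w,
                min_within_ani=min_w,
            )
        )
    return out


def shared_gene_fraction(og_presence_a: set, og_presence_b: set) -> float:
    """Percent of shared orthology groups, relative to the smaller set.

    The min-denominator convention avoids punishing MAG incompleteness.
    NaN (flagged) on an empty set."""
    if not og_presence_a or not og_presence_b:
        return math.nan
    inter = len(og_presence_a & og_presence_b)
    return 100.0 * inter / min(len(og_presence_a), len(og_presence_b))
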