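"""Viral OTU dereplication and per-sample vOTU abundance.

Viral contigs >= 5000 bp are dereplicated at >=95% identity over >=85%
of the shorter sequence into vOTUs; the longest member represents each
vOTU.  Abundances are TAD80 of reads recruited to representatives at
>=95% identity, effort-normalized.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import best_local
from .io import AbundanceMatrix, GenomeRecord, ReadAlignment
from .recruitment import abundance_from_alignments, min_depth_filter

__all__ = ["VOtu", "length_gate", "cluster_votus", "votu_abundance"]


@dataclass
class VOtu:
    votu_id: str
    representative: str
    members: list[str]
    length: int                # of the representative


def length_gate(contigs: Sequence[GenomeRecord], min_len: int = 5000) -> list[GenomeRecord]:
    """Keep contigs with length >= min_len (5000 bp default)."""
    return [c for c in contigs if len(c) >= min_len]


def cluster_votus(
    contigs: Sequence[GenomeRecord],
    identity: float = 95.0,
    coverage_short: float = 85.0,
) -> list[VOtu]:
    """Greedy longest-first dereplication into vOTUs.

    Each contig joins the first existing cluster (clusters are founded in
    descending representative length) whose representative it matches at
    >=identity% over >=coverage_short% of the shorter sequence; the
    founding (longest) contig represents the vOTU.  Deterministic: ties in
    length break by contig id.
    """
    order = sorted(contigs, key=lambda c: (-len(c), c.id))
    reps: list[GenomeRecord] = []
    members: list[list[str]] = []
    max_frac = 1 - identity / 100.0
    for contig in order:
        placed = False
        for i, rep in enumerate(reps):
            hit = best_local(
                contig.sequence, rep.sequence, max_distance=int(len(contig) * max_frac) + 1
            )
            if hit is not None and hit.identity >= identity and hit.coverage >= coverage_short:
                members[i].append(contig.id)
                placed = True
                break
        if not placed:
            reps.append(contig)
            members.append([contig.id])
    return [
        VOtu(votu_id=f"vOTU{i:05d}", representative=rep.id, members=mem, length=len(rep))
        for i, (rep, mem) in enumerate(zip(reps, members), start=1)
    ]


def votu_abundance(
    votus: Sequence[VOtu],
    per_sample_alignments: dict[str, Iterable[ReadAlignment]],
    rep_lengths: dict[str, int],
    total_reads: dict[str, int],
    min_id: float = 95.0,
    effort: float = 1e8,
    min_depth: float = 10.0,
    seed: int = 0,
) -> AbundanceMatrix:
    """Effort-normalized TAD80 of each vOTU representative per sample."""
    missing = [v.representative for v in votus if v.representative not in rep_lengths]
    if missing:
        raise ValueError(f"no length for representatives: {missing}")
    norm_cols = {}
    raw_cols = {}
    for sample, alns in per_sample_alignments.items():
        norm, raw = abundance_from_alignments(
            alns,
            {v.representative: rep_lengths[v.representative] for v in votus},
            total_reads=total_reads[sample],
            min_identity=min_id,
            effort=effort,
            seed=seed,
        )
        norm_cols[sample] = norm
        raw_cols[sample] = raw
    values = pd.DataFrame(norm_cols)
    raw = pd.DataFrame(raw_cols)
    values.index.name = "votu_representative"
    matrix = AbundanceMatrix(values=values)
    return min_depth_filter(matrix, raw, min_depth=min_depth)
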