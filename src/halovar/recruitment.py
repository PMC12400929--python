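"""Competitive read recruitment, depth profiles and TAD80 abundance.

Reads mapped against a panel of near-identical references (one
representative per genomovar) are filtered by identity (>=95% for
species-level, >=99.3% for genomovar-level counting), assigned
competitively to their best reference, turned into per-position depth
profiles, and summarised as TAD80: the mean depth of the middle 80% of
positions after discarding the top and bottom 10% of positions ranked by
depth.  TAD80 / total reads x 1e8 puts samples of different sequencing
effort on one scale, and entities whose raw TAD80 is below 10X are
flagged out of downstream statistics.
"""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, ReadAlignment

log = logging.getLogger("halovar")

__all__ = [
    "filter_identity",
    "group_by_read",
    "competitive_assign",
    "depth_profile",
    "tad",
    "effort_normalize",
    "min_depth_filter",
    "gene_copy_number",
    "abundance_from_alignments",
]

TiePolicy = Literal["random", "drop"]


def filter_identity(alignments: Iterable[ReadAlignment], threshold: float) -> list[ReadAlignment]:
    """Keep alignments with identity >= threshold (percent)."""
    return [a for a in alignments if a.identity >= threshold]


def group_by_read(alignments: Iterable[ReadAlignment]) -> dict[str, list[ReadAlignment]]:
    groups: dict[str, list[ReadAlignment]] = defaultdict(list)
    for a in alignments:
        groups[a.read_id].append(a)
    return dict(groups)


def competitive_assign(
    alignments: Iterable[ReadAlignment],
    seed: int = 0,
    tie_policy: TiePolicy = "random",
) -> list[ReadAlignment]:
    """One winning alignment per read: highest identity, then longest
    alignment.  Residual ties across *different* references are either
    split uniformly at random (seeded) or dropped.

    Random splitting is unbiased per read but flattens abundance shares
    when references share long identical stretches; ``tie_policy="drop"``
    keeps only unambiguous reads and preserves proportionality, and is
    what the abundance path uses.
    """
    rng = np.random.default_rng(seed)
    winners: list[ReadAlignment] = []
    groups = group_by_read(alignments)
    for read_id in sorted(groups):
        group = groups[read_id]
        best_key = max((a.identity, a.aln_len) for a in group)
        top = [a for a in group if (a.identity, a.aln_len) == best_key]
        top_refs = sorted({a.ref_id for a in top})
        if len(top_refs) == 1:
            winners.append(min(top, key=lambda a: (a.ref_start, a.is_secondary)))
        elif tie_policy == "random":
            ref = top_refs[rng.integers(len(top_refs))]
            winners.append(min((a for a in top if a.ref_id == ref), key=lambda a: a.ref_start))
        # tie_policy == "drop": ambiguous read contributes to no reference
    return winners


def depth_profile(alignments: Iterable[ReadAlignment], ref_len: int) -> np.ndarray:
    """Per-position coverage counts over one reference (half-open spans)."""
    depth = np.zeros(ref_len + 1, dtype=np.int64)
    for a in alignments:
        if a.ref_end > ref_len:
            raise ValueError(
                f"alignment of {a.read_id!r} ends at {a.ref_end} > reference length {ref_len}"
            )
        depth[a.ref_start] += 1
        depth[a.ref_end] -= 1
    return np.cumsum(depth[:-1])


def tad(profile: np.ndarray, trim: float = 0.10) -> float:
    """Truncated average depth: drop floor(trim*L) positions from each tail
    of the depth-sorted positions and average the remainder (TAD80 at the
    default trim of 0.10)."""
    if trim >= 0.5 or trim < 0:
        raise ValueError(f"trim={trim} outside [0, 0.5)")
    profile = np.asarray(profile)
    L = profile.size
    if L < 10:
        raise ValueError("reference too short for a trimmed average (need >= 10 positions)")
    k = math.floor(trim * L)
    ordered = np.sort(profile)
    kept = ordered[k : L - k]
    return float(kept.mean())


def effort_normalize(tad_value: float, total_reads: int, effort: float = 1e8) -> float:
    """Scale a TAD value by sequencing effort: tad / total_reads * effort."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    return tad_value / total_reads * effort


def min_depth_filter(matrix: AbundanceMatrix, raw_tad: pd.DataFrame, min_depth: float = 10.0) -> AbundanceMatrix:
    """Flag entries whose raw (un-normalized) TAD is below ``min_depth``."""
    if not raw_tad.index.equals(matrix.values.index) or not raw_tad.columns.equals(matrix.values.columns):
        raise ValueError("raw_tad must share the matrix's labels")
    flags = matrix.flags | (raw_tad < min_depth)
    return AbundanceMatrix(values=matrix.values, flags=flags)


def gene_copy_number(gene_tad: float, species_tad: float) -> float:
    """Gene depth over whole-species depth = copies per genome.

    NaN (flagged) when the species depth is unusable."""
    if species_tad is None or math.isnan(species_tad) or species_tad <= 0:
        return math.nan
    return gene_tad / species_tad


def abundance_from_alignments(
    alignments: Iterable[ReadAlignment],
    ref_lengths: dict[str, int],
    total_reads: int,
    min_identity: float = 99.3,
    trim: float = 0.10,
    effort: float = 1e8,
    min_depth: float = 10.0,
    seed: int = 0,
    tie_policy: TiePolicy = "drop",
) -> tuple[pd.Series, pd.Series]:
    """Identity filter -> competitive assignment -> TAD -> normalization,
    for one sample.  Returns (normalized abundance, raw TAD) per reference;
    raw TAD below ``min_depth`` is reported as-is (the matrix-level filter
    applies the flag)."""
    kept = filter_identity(alignments, min_identity)
    winners = competitive_assign(kept, seed=seed, tie_policy=tie_policy)
    by_ref: dict[str, list[ReadAlignment]] = defaultdict(list)
    for a in winners:
        by_ref[a.ref_id].append(a)
    raw = {}
    norm = {}
    for ref_id, length in ref_lengths.items():
        profile = depth_profile(by_ref.get(ref_id, []), length)
        t = tad(profile, trim)
        raw[ref_id] = t
        norm[ref_id] = effort_normalize(t, total_reads, effort)
    return pd.Series(norm), pd.Series(raw)
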