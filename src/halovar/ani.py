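"""Average nucleotide identity (ANI) between genomes and read-based ANIr.

ANI is fragment-based: the query genome is cut into non-overlapping
1000 bp windows, each aligned end-free to its best location in the
subject; fragments passing identity/coverage floors contribute their
identity, and the final value is the mean of the two directional means,
which keeps the statistic symmetric.  ANIr is the mean identity of reads
recruited to one reference within an identity window (default [95,100]),
a microdiversity proxy: higher ANIr = more clonal population.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import best_local
from .io import GenomeRecord, ReadAlignment

__all__ = ["AniResult", "fragment_ani", "ani_matrix", "anir"]


@dataclass
class AniResult:
    genome_a: str
    genome_b: str
    ani: float              # percent; NaN when undefined
    aligned_fraction: float  # percent of fragments that passed the filters
    n_fragments: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ani)


def _directional(a: str, b: str, frag_len: int, min_id: float, min_aln: float) -> tuple[float, int, int]:
    identities = []
    n_total = 0
    # banded in two stages: a narrow band catches intra-species fragments
    # cheaply, the full band (down to the identity floor) only runs when
    # the narrow one misses
    narrow = max(10, int(frag_len * 0.06))
    max_dist = int(frag_len * (1 - min_id / 100.0) * 2) + 10
    for start in range(0, len(a) - frag_len + 1, frag_len):
        n_total += 1
        frag = a[start : start + frag_len]
        hit = best_local(frag, b, max_distance=narrow)
        if hit is None and max_dist > narrow:
            hit = best_local(frag, b, max_distance=max_dist)
        if hit is None:
            continue
        if hit.identity >= min_id and hit.coverage >= min_aln:
            identities.append(hit.identity)
    mean = float(np.mean(identities)) if identities else math.nan
    return mean, len(identities), n_total


def fragment_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    frag_len: int = 1000,
    min_frag_identity: float = 70.0,
    min_frag_aln: float = 70.0,
) -> AniResult:
    """Reciprocal fragment-based ANI between two genomes.

    Returns an AniResult with ``ani`` NaN (flagged, never 0) when no
    fragment passes the filters in either direction.
    """
    if len(a) < frag_len or len(b) < frag_len:
        raise ValueError(f"both sequences must be >= frag_len={frag_len}")
    ab, n_ab, tot_ab = _directional(a.sequence, b.sequence, frag_len, min_frag_identity, min_frag_aln)
    ba, n_ba, tot_ba = _directional(b.sequence, a.sequence, frag_len, min_frag_identity, min_frag_aln)
    used = [x for x in (ab, ba) if not math.isnan(x)]
    ani = float(np.mean(used)) if len(used) == 2 else math.nan
    frac = 100.0 * (n_ab + n_ba) / max(1, tot_ab + tot_ba)
    return AniResult(a.id, b.id, ani=ani, aligned_fraction=frac, n_fragments=n_ab + n_ba)


def ani_matrix(
    genomes: Sequence[GenomeRecord],
    frag_len: int = 1000,
    min_frag_identity: float = 70.0,
    min_frag_aln: float = 70.0,
) -> pd.DataFrame:
    """Symmetric ANI matrix over all unordered pairs, diagonal 100.

    Undefined pairs are NaN; downstream clustering refuses them."""
    if len(genomes) < 1:
        raise ValueError("need at least one genome")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for ga, gb in itertools.combinations(genomes, 2):
        res = fragment_ani(ga, gb, frag_len, min_frag_identity, min_frag_aln)
        mat.loc[ga.id, gb.id] = mat.loc[gb.id, ga.id] = res.ani
    return mat


def anir(
    alignments: Iterable[ReadAlignment],
    identity_window: tuple[float, float] = (95.0, 100.0),
) -> float:
    """Mean identity of recruited reads within the identity window.

    Each read counts once (its best alignment).  Returns NaN when no
    alignment falls inside the window."""
    lo, hi = identity_window
    best: dict[str, ReadAlignment] = {}
    for aln in alignments:
        cur = best.get(aln.read_id)
        if cur is None or aln.identity > cur.identity:
            best[aln.read_id] = aln
    ids = [a.identity for a in best.values() if lo <= a.identity <= hi]
    return float(np.mean(ids)) if ids else math.nan
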