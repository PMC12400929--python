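"""Shared alignment kernel.

Two tools live here: an end-free local aligner for fragments / genes /
contigs (edlib under the hood) and a naive seeded read mapper used by the
test and simulation paths.  Production-scale read mapping stays with an
external mapper emitting SAM; the built-in mapper exists so the whole
pipeline runs on synthetic data without one.
"""
from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .io import GenomeRecord, ReadAlignment

_BASE_TO_U8 = np.zeros(128, dtype=np.uint8)
for i, b in enumerate("ACGTN"):
    _BASE_TO_U8[ord(b)] = i


def seq_to_u8(seq: str) -> np.ndarray:
    return _BASE_TO_U8[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class LocalHit:
    """Best end-free placement of a query inside a target."""

    identity: float          # percent over query columns
    coverage: float          # percent of the query spanned on the target
    t_start: int
    t_end: int               # half-open
    edit_distance: int


def best_local(query: str, target: str, max_distance: int | None = None) -> LocalHit | None:
    """Align ``query`` against the best location in ``target`` (ends free on
    the target).  Identity is computed over query length, the NM-style
    convention in which indel columns count as differences."""
    k = -1 if max_distance is None else int(max_distance)
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    end += 1
    dist = res["editDistance"]
    qlen = len(query)
    identity = 100.0 * max(0.0, 1.0 - dist / qlen)
    coverage = 100.0 * min(1.0, (end - start) / qlen)
    return LocalHit(identity=identity, coverage=coverage, t_start=start, t_end=end, edit_distance=dist)


class KmerIndex:
    """Exact k-mer index of one reference, for ungapped read placement.

    Synthetic reads carry substitutions only, so a read maps ungapped at
    the offset implied by any error-free seed.  A few seed offsets are
    probed per read; candidates are scored by Hamming distance.
    """

    def __init__(self, ref: GenomeRecord, k: int = 21):
        self.ref_id = ref.id
        self.k = k
        self.arr = seq_to_u8(ref.sequence)
        self.length = len(ref.sequence)
        index: dict[bytes, list[int]] = {}
        data = ref.sequence.encode()
        for i in range(0, self.length - k + 1):
            index.setdefault(data[i : i + k], []).append(i)
        self._index = index

    def map_read(self, read_seq: str, max_candidates: int = 50) -> tuple[int, int] | None:
        """Return (mismatches, ref_start) of the best ungapped placement, or
        None when no seed matches."""
        L = len(read_seq)
        if L > self.length:
            return None
        data = read_seq.encode()
        arr = seq_to_u8(read_seq)
        offsets = sorted({0, L // 2, max(0, L - self.k)})
        candidates: set[int] = set()
        for off in offsets:
            for pos in self._index.get(data[off : off + self.k], ()):
                start = pos - off
                if 0 <= start <= self.length - L:
                    candidates.add(start)
                if len(candidates) >= max_candidates:
                    break
        if not candidates:
            return None
        best: tuple[int, int] | None = None
        for start in sorted(candidates):
            nm = int(np.count_nonzero(self.arr[start : start + L] != arr))
            if best is None or nm < best[0]:
                best = (nm, start)
        return best


def map_reads(
    reads: list[tuple[str, str]],
    refs: list[GenomeRecord],
    k: int = 21,
) -> list[ReadAlignment]:
    """Map every read against every reference, keeping the best placement
    per (read, reference).  Output order: read-major, then reference."""
    indexes = [KmerIndex(r, k=k) for r in refs]
    out: list[ReadAlignment] = []
    for read_id, seq in reads:
        for idx in indexes:
            hit = idx.map_read(seq)
            if hit is None:
                continue
            nm, start = hit
            out.append(
                ReadAlignment(
                    read_id=read_id,
                    ref_id=idx.ref_id,
                    ref_start=start,
                    aln_len=len(seq),
                    mismatches_plus_indels=nm,
                )
            )
    return out
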