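"""Readers and writers for the formats the pipeline touches.

FASTA (genomes, viral contigs), SAM (read alignments), TSV (labelled
matrices) and a YAML run configuration.  All coordinates are 0-based
half-open internally; SAM's 1-based positions are converted at the
boundary by pysam.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

log = logging.getLogger("halovar")

__all__ = [
    "GenomeRecord",
    "ReadAlignment",
    "SamStats",
    "AbundanceMatrix",
    "RunConfig",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_sam",
    "write_sam",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeRecord:
    """A genome, MAG or contig with its quality metadata.

    completeness / contamination are CheckM2-style percent estimates and
    gate which MAGs enter the analysis (completeness >= 50, contamination
    < 10).
    """

    id: str
    sequence: str
    completeness: float = 100.0
    contamination: float = 0.0
    source_sample: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"genome {self.id!r}: empty sequence")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"genome {self.id!r}: completeness {self.completeness} outside [0,100]")
        if not 0.0 <= self.contamination <= 100.0:
            raise ValueError(f"genome {self.id!r}: contamination {self.contamination} outside [0,100]")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadAlignment:
    """A read placed on a reference.

    ``aln_len`` counts alignment columns (matches + mismatches + indel
    columns); ``mismatches_plus_indels`` is the NM-style difference count,
    so ``identity = 100 * (aln_len - NM) / aln_len``.  ``ref_start`` is
    0-based; the covered reference span is ``[ref_start, ref_end)``.
    """

    read_id: str
    ref_id: str
    ref_start: int
    aln_len: int
    mismatches_plus_indels: int
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise ValueError(f"read {self.read_id!r}: negative ref_start")
        if not 0 <= self.mismatches_plus_indels <= self.aln_len:
            raise ValueError(
                f"read {self.read_id!r}: mismatch count {self.mismatches_plus_indels} "
                f"outside [0, {self.aln_len}]"
            )

    @property
    def identity(self) -> float:
        return 100.0 * (self.aln_len - self.mismatches_plus_indels) / self.aln_len

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.aln_len


@dataclass
class SamStats:
    """Summary of one SAM parse: what was kept and what was skipped."""

    n_records: int = 0
    n_unmapped: int = 0
    n_missing_nm: int = 0
    n_kept: int = 0


@dataclass
class AbundanceMatrix:
    """Entities (species / genomovars / vOTUs / genes) x samples.

    ``values`` holds TAD80-derived abundances (raw or effort-normalized);
    ``flags`` marks entries excluded from downstream statistics, e.g.
    because their raw sequencing depth fell below the 10X floor.
    """

    values: pd.DataFrame
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if (self.values.fillna(0.0) < 0).any().any():
            raise ValueError("abundance values must be >= 0")

    def unflagged(self) -> pd.DataFrame:
        """Values with flagged entries replaced by NaN."""
        return self.values.mask(self.flags)

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.unflagged(), path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceMatrix":
        df = read_table(path)
        return cls(values=df.fillna(0.0), flags=df.isna())


#: Default thresholds of the workflow.  Identity filters, the TAD trim, the
#: 10X depth floor, the vOTU dereplication rule, the LS / P / Q cuts and the
#: 1e8-read sequencing-effort unit follow the study design this package
#: re-implements; all are overridable per run.
_DEFAULTS = dict(
    species_identity=95.0,
    genomovar_identity=99.3,
    genomovar_ani=99.5,
    votu_identity=95.0,
    votu_coverage=85.0,
    ls_cut=0.6,
    p_cut=0.05,
    q_cut=0.01,
    max_delay=3,
    tad_trim=0.10,
    min_depth=10.0,
    min_viral_len=5000,
    effort=1e8,
)


@dataclass
class RunConfig:
    """Thresholds, paths and the global seed for one pipeline run."""

    species_identity: float = _DEFAULTS["species_identity"]
    genomovar_identity: float = _DEFAULTS["genomovar_identity"]
    genomovar_ani: float = _DEFAULTS["genomovar_ani"]
    votu_identity: float = _DEFAULTS["votu_identity"]
    votu_coverage: float = _DEFAULTS["votu_coverage"]
    ls_cut: float = _DEFAULTS["ls_cut"]
    p_cut: float = _DEFAULTS["p_cut"]
    q_cut: float = _DEFAULTS["q_cut"]
    max_delay: int = _DEFAULTS["max_delay"]
    tad_trim: float = _DEFAULTS["tad_trim"]
    min_depth: float = _DEFAULTS["min_depth"]
    min_viral_len: int = _DEFAULTS["min_viral_len"]
    effort: float = _DEFAULTS["effort"]
    regime: str = "D20"
    rng_seed: int = 1
    outdir: str = "halovar_out"

    def __post_init__(self) -> None:
        for name in ("species_identity", "genomovar_identity", "genomovar_ani", "votu_identity", "votu_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0,100]")
        if not 0 <= self.tad_trim < 0.5:
            raise ValueError(f"tad_trim={self.tad_trim} outside [0, 0.5)")
        if self.effort <= 0:
            raise ValueError("effort must be > 0")
        if not 0 <= self.ls_cut <= 1 or not 0 <= self.p_cut <= 1 or not 0 <= self.q_cut <= 1:
            raise ValueError("ls/p/q cuts outside their ranges")
        if self.regime not in ("D13", "D20"):
            raise ValueError(f"regime must be 'D13' or 'D20', got {self.regime!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords (sequences uppercased, N allowed)."""
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1 is not a FASTA header: {first.strip()[:40]!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM

def read_sam(
    path: str | Path,
    ref_lengths: dict[str, int] | None = None,
) -> tuple[list[ReadAlignment], SamStats]:
    """Parse a SAM file into ReadAlignments.

    Unmapped records are skipped; secondary alignments are kept and
    flagged (competitive recruitment needs every candidate placement).
    Records without an NM tag (and no MD tag to derive it) are skipped
    with a warning and counted in the returned stats.
    """
    stats = SamStats()
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            stats.n_records += 1
            if rec.is_unmapped:
                stats.n_unmapped += 1
                continue
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif rec.has_tag("MD"):
                # mismatches from MD + indel bases from CIGAR
                md_mismatch = sum(1 for c in str(rec.get_tag("MD")) if c in "ACGTN")
                indel = sum(l for op, l in rec.cigartuples if op in (1, 2))
                nm = md_mismatch + indel
            else:
                stats.n_missing_nm += 1
                log.warning("read %s: no NM/MD tag, skipped", rec.query_name)
                continue
            aln_len = sum(l for op, l in rec.cigartuples if op in (0, 1, 2, 7, 8))
            ref_len = None if ref_lengths is None else ref_lengths.get(rec.reference_name)
            if ref_len is not None:
                span = sum(l for op, l in rec.cigartuples if op in (0, 2, 7, 8))
                if rec.reference_start + span > ref_len:
                    raise FormatError(
                        f"read {rec.query_name!r} extends past the end of {rec.reference_name!r}"
                    )
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    ref_start=rec.reference_start,
                    aln_len=aln_len,
                    mismatches_plus_indels=nm,
                    is_secondary=rec.is_secondary,
                )
            )
            stats.n_kept += 1
    return out, stats


def write_sam(
    alignments: Sequence[ReadAlignment],
    path: str | Path,
    ref_lengths: dict[str, int],
) -> None:
    """Write substitution-only alignments as plain SAM with NM tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": int(l)} for name, l in ref_lengths.items()],
    }
    ref_index = {name: i for i, name in enumerate(ref_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for aln in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = aln.read_id
            rec.reference_id = ref_index[aln.ref_id]
            rec.reference_start = aln.ref_start
            rec.cigarstring = f"{aln.aln_len}M"
            rec.flag = 256 if aln.is_secondary else 0
            rec.mapping_quality = 255
            rec.set_tag("NM", aln.mismatches_plus_indels)
            sam.write(rec)


# ---------------------------------------------------------------------------
# TSV tables

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled matrix as TSV (NaN as empty cell)."""
    if df.index.duplicated().any():
        raise ValueError(f"duplicate row labels: {df.index[df.index.duplicated()].tolist()}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate column labels: {df.columns[df.columns.duplicated()].tolist()}")
    df.to_csv(path, sep="\t", index_label="id", na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate labels")
    return df
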