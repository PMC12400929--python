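"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study system: one extremely halophilic
archaeal species whose population consists of a few genomovars at
~98.7-99.3% pairwise ANI sharing ~70-90% of their genes, sampled by
short-read metagenomes, and a brine mesocosm time series in which
recurrent dilution-evaporation disturbances (down to 13% or 20% salts,
back up to 36%) plus seasonal temperature drive genomovar succession,
with each genomovar tracked by its own cohort of lytic virus populations.

Genomes: an ancestor of whole-gene blocks diverges along a star tree
with per-branch substitution rates fitted (least squares) to the target
ANI matrix, so expected pairwise identity equals the targets; gene
content changes as whole-gene presence/absence hitting a shared-gene
fraction target exactly (core + disjoint genomovar-specific sets).
Reads: uniform starts, substitution-only errors.  Ecology: daily Euler
updates of a forced Lotka-Volterra system; vOTU abundances are fixed
random proportions of their cohort plus lognormal noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import gammaln

from .io import GenomeRecord

__all__ = [
    "GenomovarTruth",
    "EcologyParams",
    "EcologyTruth",
    "PAPER_ANI_TARGETS",
    "simulate_genomovar_genomes",
    "simulate_reads",
    "write_fastq",
    "simulate_ecology",
    "simulate_viral_contigs",
    "heaps_presence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Reported mean inter-genomovar ANI of the four Hqr. walsbyi genomovars
#: (Hqrw1..Hqrw4); used as the default divergence targets.
PAPER_ANI_TARGETS = pd.DataFrame(
    [
        [100.0, 99.3, 99.1, 98.7],
        [99.3, 100.0, 99.2, 98.9],
        [99.1, 99.2, 100.0, 98.9],
        [98.7, 98.9, 98.9, 100.0],
    ],
    index=["Hqrw1", "Hqrw2", "Hqrw3", "Hqrw4"],
    columns=["Hqrw1", "Hqrw2", "Hqrw3", "Hqrw4"],
)


def _u8_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def star_rates_from_ani(ani_targets: np.ndarray, embed_tol: float = 0.15) -> np.ndarray:
    """Per-genomovar branch divergences (percent) of the star tree whose
    leaf-to-leaf distances best reproduce ``100 - ani_targets``.

    Raises when the matrix is not star-embeddable within ``embed_tol``
    percent, naming the worst-fitting genomovar triple."""
    A = np.asarray(ani_targets, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or not np.allclose(A, A.T, atol=1e-9):
        raise ValueError("ani_targets must be a symmetric square matrix")
    D = 100.0 - A
    if n == 1:
        return np.zeros(1)
    if n == 2:
        return np.array([D[0, 1] / 2, D[0, 1] / 2])
    # least-squares star fit has the closed form
    # d_i = (S_i - sum(S)/(2(n-1))) / (n-2) with S_i the row sums of D
    S = D.sum(axis=1)
    d = (S - S.sum() / (2 * (n - 1))) / (n - 2)
    if np.any(d < -1e-9):
        j = int(np.argmin(d))
        others = [x for x in range(n) if x != j][:2]
        raise ValueError(
            f"ANI targets are not star-tree additive: triple ({others[0]}, {j}, "
            f"{others[1]}) implies a negative branch length for taxon {j} ({d[j]:.3f})"
        )
    d = np.maximum(d, 0.0)
    fitted = d[:, None] + d[None, :]
    np.fill_diagonal(fitted, 0.0)
    resid = np.abs(fitted - D)
    if resid.max() > embed_tol:
        i, j = np.unravel_index(np.argmax(resid), resid.shape)
        k = next(x for x in range(n) if x not in (i, j))
        raise ValueError(
            f"ANI targets are not star-tree additive within {embed_tol}: "
            f"triple ({i}, {j}, {k}) misfits pair ({i},{j}) by {resid[i, j]:.3f} ANI points"
        )
    return d


@dataclass
class GenomovarTruth:
    """Everything planted by the genome simulator."""

    genomovar_of: dict[str, str]                 # genome id -> genomovar id
    ani_targets: pd.DataFrame                    # genomovar x genomovar, percent
    gene_inventory: dict[str, set]               # genome id -> gene ids kept
    gene_len: int
    n_genes: int
    _full_arrays: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def realized_identity(self, a: str, b: str) -> float:
        """Percent Hamming identity over genes present in both genomes
        (the planted orthologous alignment)."""
        shared = sorted(self.gene_inventory[a] & self.gene_inventory[b])
        if not shared:
            return math.nan
        idx = np.concatenate(
            [np.arange(g * self.gene_len, (g + 1) * self.gene_len) for g in shared]
        )
        xa = self._full_arrays[a][idx]
        xb = self._full_arrays[b][idx]
        return 100.0 * float(np.mean(xa == xb))

    def shared_fraction(self, a: str, b: str) -> float:
        sa, sb = self.gene_inventory[a], self.gene_inventory[b]
        return 100.0 * len(sa & sb) / min(len(sa), len(sb))

    def genes_of(self, genome_id: str) -> list[GenomeRecord]:
        """Per-gene sequences of one genome (for pangenome clustering)."""
        arr = self._full_arrays[genome_id]
        out = []
        for g in sorted(self.gene_inventory[genome_id]):
            seq = _u8_to_seq(arr[g * self.gene_len : (g + 1) * self.gene_len])
            out.append(GenomeRecord(id=f"{genome_id}|gene_{g:04d}", sequence=seq))
        return out


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    if rate <= 0:
        return out
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        shift = rng.integers(1, 4, hits.size)
        idx = (np.searchsorted(_BASES, out[hits]) + shift) % 4
        out[hits] = _BASES[idx]
    return out


def simulate_genomovar_genomes(
    ancestor_len: int = 200_000,
    n_genomovars: int = 4,
    strains_per_genomovar: int = 3,
    ani_targets: pd.DataFrame | np.ndarray | None = None,
    gene_len: int = 1000,
    shared_fraction_target: float = 85.0,
    strain_divergence: float = 0.3,
    strain_gene_loss: float = 0.005,
    seed: int = 0,
) -> tuple[list[GenomeRecord], GenomovarTruth]:
    """Simulate genomovar genomes by star-tree divergence from one ancestor.

    ``ani_targets`` (percent, genomovar level) defaults to the four
    reported Hqrw genomovar means; ``strain_divergence`` (percent) is the
    expected pairwise divergence between strains of one genomovar, so
    within-genomovar ANI is about 100 - strain_divergence.  The
    shared-gene fraction target (scalar, percent) is hit exactly via a
    core gene set plus disjoint genomovar-specific sets.
    """
    if ancestor_len < 50 * gene_len:
        raise ValueError("ancestor_len must be >= 50 * gene_len")
    if ani_targets is None:
        ani_targets = PAPER_ANI_TARGETS.iloc[:n_genomovars, :n_genomovars]
    targets = np.asarray(ani_targets, dtype=float)
    if targets.shape[0] != n_genomovars:
        raise ValueError("ani_targets size does not match n_genomovars")
    gv_names = (
        list(ani_targets.index)
        if isinstance(ani_targets, pd.DataFrame)
        else [f"Hqrw{i+1}" for i in range(n_genomovars)]
    )
    # strain branches (half the within-genomovar divergence) are carved out
    # of the genomovar branches so realized between-genomovar divergence
    # still equals the target
    branch = star_rates_from_ani(targets)  # percent
    strain_branch = strain_divergence / 2.0
    if np.any(branch - strain_branch < -1e-9) and n_genomovars > 1:
        raise ValueError(
            "strain_divergence/2 exceeds a genomovar branch length; "
            "between-genomovar targets would be missed"
        )
    gv_rate = np.maximum(branch - strain_branch, 0.0) / 100.0
    strain_rate = strain_branch / 100.0

    rng = np.random.default_rng(seed)
    n_genes = ancestor_len // gene_len
    ancestor = _BASES[rng.integers(0, 4, n_genes * gene_len)]

    # gene content: exact core + disjoint specific sets
    f = shared_fraction_target / 100.0
    if not 0 < f <= 1:
        raise ValueError("shared_fraction_target must be in (0, 100]")
    if n_genomovars == 1 or f == 1.0:
        kept = n_genes
        core = list(range(n_genes))
        specific = [[] for _ in range(n_genomovars)]
    else:
        kept = min(n_genes, int(n_genes / (n_genomovars - (n_genomovars - 1) * f)))
        n_core = round(f * kept)
        n_spec = kept - n_core
        pool = rng.permutation(n_genes)
        core = sorted(pool[:n_core].tolist())
        specific = [
            sorted(pool[n_core + g * n_spec : n_core + (g + 1) * n_spec].tolist())
            for g in range(n_genomovars)
        ]

    records: list[GenomeRecord] = []
    truth = GenomovarTruth(
        genomovar_of={},
        ani_targets=pd.DataFrame(targets, index=gv_names, columns=gv_names),
        gene_inventory={},
        gene_len=gene_len,
        n_genes=n_genes,
    )
    # strain branches shortened so realized between-genomovar divergence
    # (gv_a + strain + gv_b + strain) equals the target
    for g, gv in enumerate(gv_names):
        gv_arr = _mutate(ancestor, gv_rate[g], rng)
        gv_genes = set(core) | set(specific[g])
        for s in range(strains_per_genomovar):
            gid = f"{gv}_s{s+1}"
            arr = _mutate(gv_arr, strain_rate, rng)
            genes = set(gv_genes)
            if strain_gene_loss > 0 and len(genes) > 1:
                n_lose = int(round(strain_gene_loss * len(genes)))
                if n_lose:
                    lose = rng.choice(sorted(genes), size=n_lose, replace=False)
                    genes -= set(int(x) for x in lose)
            seq_parts = [
                arr[k * gene_len : (k + 1) * gene_len] for k in sorted(genes)
            ]
            seq = _u8_to_seq(np.concatenate(seq_parts))
            records.append(GenomeRecord(id=gid, sequence=seq, source_sample="synthetic"))
            truth.genomovar_of[gid] = gv
            truth.gene_inventory[gid] = genes
            truth._full_arrays[gid] = arr
    return records, truth


def simulate_reads(
    genomes: list[GenomeRecord],
    weights: np.ndarray | list[float],
    read_len: int = 150,
    err_rate: float = 0.0,
    n_reads: int = 10_000,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Substitution-only shotgun reads drawn proportional to weight x length.

    Returns (reads, truth) where truth records source genome, start and
    planted error count per read."""
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    w = np.asarray(weights, dtype=float)
    if w.size != len(genomes) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be >= 0 with a positive sum and match the genomes")
    if any(len(g) < read_len for g in genomes):
        raise ValueError("read_len exceeds the shortest genome")
    rng = np.random.default_rng(seed)
    p = w * np.array([len(g) for g in genomes], dtype=float)
    p /= p.sum()
    counts = rng.multinomial(n_reads, p)
    arrs = [np.frombuffer(g.sequence.encode(), dtype=np.uint8) for g in genomes]
    reads: list[tuple[str, str]] = []
    rows = []
    r = 0
    for gi, (genome, cnt) in enumerate(zip(genomes, counts)):
        starts = rng.integers(0, len(genome) - read_len + 1, cnt)
        for start in starts:
            arr = arrs[gi][start : start + read_len]
            if err_rate > 0:
                arr = _mutate(arr, err_rate, rng)
                n_err = int(np.count_nonzero(arr != arrs[gi][start : start + read_len]))
            else:
                n_err = 0
            rid = f"read_{r:07d}"
            reads.append((rid, _u8_to_seq(arr)))
            rows.append((rid, genome.id, int(start), n_err))
            r += 1
    truth = pd.DataFrame(rows, columns=["read_id", "genome", "start", "n_errors"])
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# ecology


@dataclass
class EcologyParams:
    """Defaults of the mesocosm-like forced host-virus system.

    Hosts are the four genomovars with staggered salinity and temperature
    niches (Hqrw1-like fittest at high stable salinity, Hqrw2-like with
    the widest salinity tolerance); each is preyed on by one cohort of
    lytic viruses.  Units: days, percent salts, degrees C; abundances are
    in percent-of-community-like arbitrary units (initial values are the
    study's day-0 genomovar abundances).
    """

    rmax: tuple = (0.6, 0.4, 0.45, 0.3)          # 1/day
    opt_s: tuple = (36.0, 28.0, 25.0, 33.0)      # % salts
    w_s: tuple = (4.0, 9.0, 4.0, 4.0)
    opt_t: tuple = (29.0, 15.0, 27.0, 17.0)      # deg C
    w_t: tuple = (13.0, 13.0, 13.0, 13.0)
    K: float = 70.0
    H0: tuple = (10.5, 7.3, 6.4, 1.6)
    V0: float = 5.0
    infection: float = 2e-3                      # a, per (virus unit * day)
    burst: float = 10.0                          # b
    decay: float = 0.4                           # m, 1/day
    immigration: float = 0.05                    # background inflow, units/day
    T_days: int = 813
    n_samples: int = 60
    dilution_interval: int = 200                 # days between dilution events
    ceiling: float = 36.0                        # % salts at saturation
    t_mean: float = 22.0
    t_amp: float = 8.0
    votus_per_cohort: tuple = (5, 10, 7, 8)
    dirichlet_conc: float = 5.0
    noise_sd: float = 0.2                        # lognormal sd of observed series


@dataclass
class EcologyTruth:
    days: np.ndarray                  # sampled days
    salinity: np.ndarray              # at sampled days
    temperature: np.ndarray
    host_abundance: pd.DataFrame      # genomovar x time, observed (noisy)
    virus_abundance: pd.DataFrame     # vOTU x time, observed (noisy)
    cohort_membership: dict[str, str]  # vOTU id -> planted cohort id
    host_of_cohort: dict[str, str]     # planted cohort id -> genomovar id
    host_true: pd.DataFrame            # noiseless daily-sampled trajectories
    cohort_true: pd.DataFrame


def forcing_series(
    T: int, floor: float, ceiling: float = 36.0, dilution_interval: int = 200,
    t_mean: float = 22.0, t_amp: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sawtooth salinity (instant dilution to the floor, linear evaporation
    back to the ceiling) plus a seasonal temperature cycle."""
    evap = (ceiling - floor) / (dilution_interval * 0.7)
    s = np.empty(T)
    cur = ceiling
    for t in range(T):
        if t > 0 and t % dilution_interval == 0:
            cur = floor
        elif t > 0:
            cur = min(ceiling, cur + evap)
        s[t] = cur
    temp = t_mean + t_amp * np.sin(2 * np.pi * np.arange(T) / 365.0)
    return s, temp


def simulate_ecology(
    regime: str = "D20",
    params: EcologyParams | None = None,
    seed: int = 0,
    noise_sd: float | None = None,
) -> EcologyTruth:
    """Run the forced host-virus system and emit sampled, noisy series.

    ``regime`` picks the dilution floor: "D13" dilutes to 13% salts
    (intense disturbance), "D20" to 20% (moderate)."""
    p = params or EcologyParams()
    if noise_sd is not None:
        p = EcologyParams(**{**p.__dict__, "noise_sd": noise_sd})
    floors = {"D13": 13.0, "D20": 20.0}
    if regime not in floors:
        raise ValueError(f"regime must be one of {sorted(floors)}")
    nG = len(p.rmax)
    for name in ("opt_s", "w_s", "opt_t", "w_t", "H0"):
        if len(getattr(p, name)) != nG:
            raise ValueError(f"parameter {name} must have length {nG}")
    s, temp = forcing_series(p.T_days, floors[regime], p.ceiling, p.dilution_interval, p.t_mean, p.t_amp)
    rmax = np.array(p.rmax); opt_s = np.array(p.opt_s); w_s = np.array(p.w_s)
    opt_t = np.array(p.opt_t); w_t = np.array(p.w_t)
    H = np.empty((p.T_days, nG)); V = np.empty((p.T_days, nG))
    H[0] = p.H0; V[0] = p.V0
    a, b, m = p.infection, p.burst, p.decay
    for t in range(p.T_days - 1):
        r = rmax * (1 - ((s[t] - opt_s) / w_s) ** 2) * (1 - ((temp[t] - opt_t) / w_t) ** 2)
        dH = r * H[t] * (1 - H[t].sum() / p.K) - a * H[t] * V[t] + p.immigration
        dV = b * a * H[t] * V[t] - m * V[t] + p.immigration
        H[t + 1] = np.maximum(H[t] + dH, 0.0)
        V[t + 1] = np.maximum(V[t] + dV, 0.0)
        if not (np.all(np.isfinite(H[t + 1])) and np.all(np.isfinite(V[t + 1]))) or H[t + 1].max() > 1e9 or V[t + 1].max() > 1e9:
            raise ValueError(f"unstable parameters: overflow at day {t + 1}")
    days = np.round(np.linspace(0, p.T_days - 1, p.n_samples)).astype(int)
    gv = [f"Hqrw{i+1}" for i in range(nG)]
    cohorts = [f"VC{i+1}" for i in range(nG)]
    host_true = pd.DataFrame(H[days].T, index=gv, columns=days)
    cohort_true = pd.DataFrame(V[days].T, index=cohorts, columns=days)
    rng = np.random.default_rng(seed)
    obs_host = host_true * np.exp(rng.normal(0.0, p.noise_sd, host_true.shape)) if p.noise_sd > 0 else host_true.copy()
    membership: dict[str, str] = {}
    rows = {}
    for c, coh in enumerate(cohorts):
        props = rng.dirichlet(np.full(p.votus_per_cohort[c], p.dirichlet_conc))
        for k in range(p.votus_per_cohort[c]):
            vid = f"v{c+1}_{k:02d}"
            membership[vid] = coh
            noise = np.exp(rng.normal(0.0, p.noise_sd, len(days))) if p.noise_sd > 0 else 1.0
            rows[vid] = V[days, c] * props[k] * noise
    virus_obs = pd.DataFrame(rows, index=days).T
    return EcologyTruth(
        days=days,
        salinity=s[days],
        temperature=temp[days],
        host_abundance=obs_host,
        virus_abundance=virus_obs,
        cohort_membership=membership,
        host_of_cohort=dict(zip(cohorts, gv)),
        host_true=host_true,
        cohort_true=cohort_true,
    )


def simulate_viral_contigs(
    votu_ids: list[str],
    variants_per_votu: int = 2,
    length_range: tuple[int, int] = (6000, 15000),
    variant_identity: float = 97.0,
    n_short: int = 3,
    seed: int = 0,
) -> tuple[list[GenomeRecord], dict[str, str]]:
    """One random representative per planted vOTU plus mutated variants
    (>=95% identity, so they dereplicate back together) and a few short
    decoys below the 5 kb gate.  Returns (contigs, contig -> vOTU truth)."""
    rng = np.random.default_rng(seed)
    contigs: list[GenomeRecord] = []
    truth: dict[str, str] = {}
    rate = (100.0 - variant_identity) / 100.0
    for vid in votu_ids:
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        base = _BASES[rng.integers(0, 4, L)]
        cid = f"{vid}_rep"
        contigs.append(GenomeRecord(id=cid, sequence=_u8_to_seq(base)))
        truth[cid] = vid
        for v in range(variants_per_votu):
            arr = _mutate(base, rate, rng)
            cut = int(rng.integers(0, L // 10 + 1))  # variants slightly shorter
            cid = f"{vid}_var{v+1}"
            contigs.append(GenomeRecord(id=cid, sequence=_u8_to_seq(arr[cut:])))
            truth[cid] = vid
    for i in range(n_short):
        L = int(rng.integers(1000, 4999))
        contigs.append(GenomeRecord(id=f"short_{i}", sequence=_u8_to_seq(_BASES[rng.integers(0, 4, L)])))
    return contigs, truth


# ---------------------------------------------------------------------------
# pangenome oracle


def heaps_presence(
    gamma: float, n_genomes: int = 60, scale: float = 500.0, seed: int = 0
) -> pd.DataFrame:
    """Genome x OG presence matrix whose expected rarefaction curve is
    exactly scale * k**gamma.

    The occupancy histogram (how many OGs occur in exactly j genomes) is
    solved by non-negative least squares against the hypergeometric
    detection probabilities, then each OG's carriers are a uniform random
    genome subset — exchangeable, so the curve holds for every sampling
    order."""
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must be in [0, 1]")
    N = n_genomes
    k = np.arange(1, N + 1)
    target = scale * k ** gamma
    lc = lambda n, r: gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)
    A = np.zeros((N, N))
    for j in range(1, N + 1):
        for kk in range(1, N + 1):
            A[kk - 1, j - 1] = 1.0 if N - j < kk else 1 - np.exp(lc(N - j, kk) - lc(N, kk))
    m, resid = nnls(A, target)
    counts = np.round(m).astype(int)
    rng = np.random.default_rng(seed)
    cols = []
    for j, cnt in enumerate(counts, start=1):
        for _ in range(cnt):
            col = np.zeros(N, dtype=bool)
            col[rng.choice(N, j, replace=False)] = True
            cols.append(col)
    M = np.array(cols).T
    return pd.DataFrame(
        M,
        index=[f"g{i:03d}" for i in range(N)],
        columns=[f"OG{i:05d}" for i in range(M.shape[1])],
    )
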