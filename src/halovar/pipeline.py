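"""End-to-end orchestration of the synthetic-to-cohorts workflow.

Stages (dependency order): simulate -> genomovars -> recruit ->
pangenome -> votus -> lsa -> cohorts.  Every stage writes its outputs to
the run directory, consumes only declared files or in-memory results of
earlier stages, and is hashed into a JSON manifest; re-running with the
same config and seed reproduces identical hashes for the deterministic
stages.  Per-stage seeds derive from the global seed as seed + stage
index.
"""
from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import map_reads
from .ani import ani_matrix, anir
from .cohorts import assign_cohorts, build_graph, cohort_abundance, mcl
from .genomovars import cluster_genomovars, quality_gate, quality_score
from .io import AbundanceMatrix, RunConfig, write_fasta, write_table
from .lsa import edges_to_frame, significant_edges
from .pangenome import greedy_cluster_genes, heaps_gamma, occurrence_class, og_presence_matrix
from .recruitment import abundance_from_alignments, filter_identity
from .synthetic import (
    EcologyParams,
    simulate_ecology,
    simulate_genomovar_genomes,
    simulate_reads,
    simulate_viral_contigs,
    write_fastq,
)

log = logging.getLogger("halovar")

STAGES = ["simulate", "genomovars", "recruit", "pangenome", "votus", "lsa", "cohorts"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def record(self, name: str, seed: int, outputs: dict[str, Path]) -> None:
        self.stages.append(
            {
                "name": name,
                "seed": seed,
                "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
            }
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "versions": self.versions,
                    "stages": self.stages,
                    "warnings": self.warnings,
                },
                fh,
                indent=2,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    config: RunConfig,
    outdir: str | Path | None = None,
    ancestor_len: int = 60_000,
    n_reads: int = 40_000,
) -> RunManifest:
    """Run every stage on the default synthetic scenario."""
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config),
        seed=config.rng_seed,
        versions={
            "halovar": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )
    ctx: dict = {}
    try:
        for index, name in enumerate(STAGES):
            seed = config.rng_seed + index
            outputs = _RUNNERS[name](config, ctx, out, seed, ancestor_len, n_reads)
            manifest.record(name, seed, outputs)
            log.info("stage %s done", name)
        _write_report(config, ctx, out)
        manifest.record("report", config.rng_seed, {"summary": out / "summary.txt"})
    finally:
        manifest.write(out / "manifest.json")
    return manifest


# --------------------------------------------------------------------- stages

def _stage_simulate(config, ctx, out, seed, ancestor_len, n_reads):
    genomes, truth = simulate_genomovar_genomes(ancestor_len=ancestor_len, seed=seed)
    ctx["genomes"], ctx["truth"] = genomes, truth
    write_fasta(genomes, out / "genomes.fasta")
    eco = simulate_ecology(regime=config.regime, seed=seed)
    ctx["eco"] = eco
    abund = pd.concat([eco.host_abundance, eco.virus_abundance])
    abund.columns = [f"d{int(c)}" for c in abund.columns]
    write_table(abund, out / "series.tsv")
    contigs, votu_truth = simulate_viral_contigs(sorted(eco.cohort_membership), seed=seed)
    ctx["contigs"], ctx["votu_truth"] = contigs, votu_truth
    write_fasta(contigs, out / "viral_contigs.fasta")
    weights = np.array(EcologyParams().H0)
    reps = [g for g in genomes if g.id.endswith("_s1")]
    reads, read_truth = simulate_reads(reps, weights, n_reads=n_reads, err_rate=0.001, seed=seed)
    ctx["reads"], ctx["read_truth"], ctx["reps"] = reads, read_truth, reps
    write_fastq(reads, out / "reads.fastq")
    read_truth.to_csv(out / "read_truth.tsv", sep="\t", index=False)
    return {
        "genomes": out / "genomes.fasta",
        "series": out / "series.tsv",
        "viral_contigs": out / "viral_contigs.fasta",
        "reads": out / "reads.fastq",
        "read_truth": out / "read_truth.tsv",
    }


def _stage_genomovars(config, ctx, out, seed, *_):
    genomes = quality_gate(ctx["genomes"])
    mat = ani_matrix(genomes)
    write_table(mat, out / "ani.tsv")
    quality = {g.id: quality_score(g.completeness, g.contamination) for g in genomes}
    clusters = cluster_genomovars(mat, ani_cut=config.genomovar_ani, quality=quality)
    ctx["clusters"] = clusters
    rows = [
        {"genomovar": c.genomovar_id, "member": m, "representative": c.representative,
         "mean_within_ani": c.mean_within_ani, "min_within_ani": c.min_within_ani}
        for c in clusters
        for m in c.members
    ]
    pd.DataFrame(rows).to_csv(out / "genomovar_clusters.tsv", sep="\t", index=False)
    return {"ani": out / "ani.tsv", "clusters": out / "genomovar_clusters.tsv"}


def _stage_recruit(config, ctx, out, seed, *_):
    genomes_by_id = {g.id: g for g in ctx["genomes"]}
    reps = [genomes_by_id[c.representative] for c in ctx["clusters"]]
    alns = map_reads(ctx["reads"], reps)
    ctx["alignments"] = alns
    norm, raw = abundance_from_alignments(
        alns,
        {r.id: len(r) for r in reps},
        total_reads=len(ctx["reads"]),
        min_identity=config.genomovar_identity,
        trim=config.tad_trim,
        effort=config.effort,
        seed=seed,
    )
    table = pd.DataFrame({"tad80_raw": raw, "abundance_normalized": norm})
    table["flagged_low_depth"] = raw < config.min_depth
    write_table(table, out / "genomovar_abundance.tsv")
    species = filter_identity(alns, config.species_identity)
    table2 = pd.DataFrame(
        {"anir": [anir(species, (config.species_identity, 100.0))]}, index=["species"]
    )
    write_table(table2, out / "anir.tsv")
    return {"abundance": out / "genomovar_abundance.tsv", "anir": out / "anir.tsv"}


def _stage_pangenome(config, ctx, out, seed, *_):
    truth = ctx["truth"]
    genes = [g for gid in truth.genomovar_of for g in truth.genes_of(gid)]
    ogs = greedy_cluster_genes(genes)
    ctx["ogs"] = ogs
    N = len(truth.genomovar_of)
    rows = [
        {"og_id": og.og_id, "representative": og.representative, "n_genomes": og.occurrence,
         "occurrence_class": occurrence_class(og.occurrence, N), "n_members": len(og.members)}
        for og in ogs
    ]
    pd.DataFrame(rows).to_csv(out / "orthology_groups.tsv", sep="\t", index=False)
    presence = og_presence_matrix(ogs, sorted(truth.genomovar_of))
    write_table(presence.astype(int), out / "og_presence.tsv")
    gamma = heaps_gamma(presence, seed=seed)
    ctx["gamma"] = gamma
    write_table(pd.DataFrame({"gamma": [gamma]}, index=["pangenome"]), out / "heaps_gamma.tsv")
    return {
        "ogs": out / "orthology_groups.tsv",
        "presence": out / "og_presence.tsv",
        "gamma": out / "heaps_gamma.tsv",
    }


def _stage_votus(config, ctx, out, seed, *_):
    from .votus import cluster_votus, length_gate

    gated = length_gate(ctx["contigs"], config.min_viral_len)
    votus = cluster_votus(gated, config.votu_identity, config.votu_coverage)
    ctx["votus"] = votus
    rows = [
        {"votu": v.votu_id, "representative": v.representative, "member": m, "rep_length": v.length}
        for v in votus
        for m in v.members
    ]
    pd.DataFrame(rows).to_csv(out / "votus.tsv", sep="\t", index=False)
    return {"votus": out / "votus.tsv"}


def _stage_lsa(config, ctx, out, seed, *_):
    eco = ctx["eco"]
    abund = pd.concat([eco.host_abundance, eco.virus_abundance])
    edges = significant_edges(
        abund,
        max_delay=config.max_delay,
        ls_cut=config.ls_cut,
        p_cut=config.p_cut,
        q_cut=config.q_cut,
        seed=seed,
    )
    ctx["edges"] = edges
    edges_to_frame(edges).to_csv(out / "ls_edges.tsv", sep="\t", index=False)
    return {"edges": out / "ls_edges.tsv"}


def _stage_cohorts(config, ctx, out, seed, *_):
    eco = ctx["eco"]
    hosts = list(eco.host_abundance.index)
    graph = build_graph(ctx["edges"], include_hosts=True, host_ids=hosts)
    cohorts_found = (
        assign_cohorts(mcl(graph), hosts, graph) if graph.number_of_nodes() else []
    )
    ctx["cohorts"] = cohorts_found
    rows = [
        {"cohort": c.cohort_id, "member": m, "assigned_genomovar": c.assigned_genomovar or "",
         "mean_abs_ls": c.mean_abs_ls}
        for c in cohorts_found
        for m in c.members
    ]
    pd.DataFrame(rows, columns=["cohort", "member", "assigned_genomovar", "mean_abs_ls"]).to_csv(
        out / "cohorts.tsv", sep="\t", index=False
    )
    if cohorts_found:
        vmat = AbundanceMatrix(values=eco.virus_abundance.copy())
        cohort_abundance(cohorts_found, vmat).to_tsv(out / "cohort_abundance.tsv")
    return {"cohorts": out / "cohorts.tsv"}


def _write_report(config, ctx, out) -> None:
    eco = ctx["eco"]
    lines = [
        f"halovar {__version__} run summary (regime {config.regime}, seed {config.rng_seed})",
        "",
        f"genomovars detected: {len(ctx['clusters'])}",
        f"orthology groups: {len(ctx['ogs'])}",
    ]
    N = len(ctx["truth"].genomovar_of)
    counts: dict[str, int] = {}
    for og in ctx["ogs"]:
        counts[occurrence_class(og.occurrence, N)] = counts.get(occurrence_class(og.occurrence, N), 0) + 1
    lines.append(
        "OG classes: " + ", ".join(f"{k}={counts.get(k, 0)}" for k in ("core", "common", "rare", "specific"))
    )
    lines.append(f"pangenome Heaps gamma: {ctx['gamma']:.3f}")
    lines.append(f"vOTUs: {len(ctx['votus'])}")
    assigned = [c for c in ctx["cohorts"] if c.assigned_genomovar]
    lines.append(f"viral cohorts: {len(ctx['cohorts'])} ({len(assigned)} assigned to a genomovar)")
    lines.append("")
    lines.append("abundance trends (slope of observed series per year):")
    t = np.arange(eco.host_abundance.shape[1])
    for name, row in eco.host_abundance.iterrows():
        slope = np.polyfit(t, row.to_numpy(), 1)[0] * 365 / 14
        lines.append(f"  {name}: {slope:+.2f}")
    for c in assigned:
        coh = eco.virus_abundance.loc[c.members].sum(axis=0).to_numpy()
        slope = np.polyfit(t, coh, 1)[0] * 365 / 14
        lines.append(f"  {c.cohort_id} (-> {c.assigned_genomovar}): {slope:+.2f}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


_RUNNERS = {
    "simulate": _stage_simulate,
    "genomovars": _stage_genomovars,
    "recruit": _stage_recruit,
    "pangenome": _stage_pangenome,
    "votus": _stage_votus,
    "lsa": _stage_lsa,
    "cohorts": _stage_cohorts,
}
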