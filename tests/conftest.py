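"""Shared fixtures: synthetic panels reused across test modules.

Everything is generated at test time with fixed seeds; the expensive
panels (whole-genome ANI matrix, read-mixture experiment) are built once
per session.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from halovar.align import map_reads
from halovar.ani import ani_matrix
from halovar.synthetic import simulate_genomovar_genomes, simulate_reads

MIXTURE_WEIGHTS = (0.6, 0.3, 0.1)


@pytest.fixture(scope="session")
def four_genomovar_panel():
    """12 genomes (4 genomovars x 3 strains) from a 200 kb ancestor at the
    study-like divergence targets: within-ANI ~99.7, between 98.7-99.3."""
    genomes, truth = simulate_genomovar_genomes(seed=1)
    return genomes, truth


@pytest.fixture(scope="session")
def panel_ani(four_genomovar_panel):
    genomes, _ = four_genomovar_panel
    return ani_matrix(genomes)


@pytest.fixture(scope="session")
def mixture_experiment():
    """3 genomovars at pairwise 99.0% ANI, 100 kb ancestor, one strain
    each; ~76k error-bearing reads drawn at weights 0.6/0.3/0.1 (~50X
    panel-average coverage) and mapped against all three genomes."""
    ani = pd.DataFrame(99.0, index=list("ABC"), columns=list("ABC"))
    np.fill_diagonal(ani.values, 100.0)
    genomes, truth = simulate_genomovar_genomes(
        ancestor_len=100_000,
        n_genomovars=3,
        strains_per_genomovar=1,
        ani_targets=ani,
        seed=2,
    )
    n_reads = int(50 * sum(len(g) for g in genomes) / 150)
    reads, read_truth = simulate_reads(
        genomes, MIXTURE_WEIGHTS, n_reads=n_reads, err_rate=0.001, seed=3
    )
    alignments = map_reads(reads, genomes)
    return genomes, truth, reads, read_truth, alignments
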