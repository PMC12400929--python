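import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halovar.io import AbundanceMatrix, GenomeRecord, ReadAlignment
from halovar.recruitment import (
    abundance_from_alignments,
    competitive_assign,
    depth_profile,
    effort_normalize,
    filter_identity,
    gene_copy_number,
    min_depth_filter,
    tad,
)
from halovar.synthetic import simulate_genomovar_genomes, simulate_reads
from halovar.align import map_reads


def _aln(rid, ref, nm, start=0, length=150):
    return ReadAlignment(rid, ref, start, length, nm)


class TestFilterIdentity:
    def test_one_mismatch_150bp_passes_genomovar_filter(self):
        assert filter_identity([_aln("r", "g", 1)], 99.3)

    def test_two_mismatches_150bp_fails_genomovar_filter(self):
        assert not filter_identity([_aln("r", "g", 2)], 99.3)

    def test_zero_threshold_keeps_everything(self):
        alns = [_aln(f"r{i}", "g", i) for i in range(10)]
        assert filter_identity(alns, 0.0) == alns


class TestCompetitiveAssign:
    def test_highest_identity_wins(self):
        alns = [_aln("r", "a", 1), _aln("r", "b", 0)]
        winners = competitive_assign(alns)
        assert [w.ref_id for w in winners] == ["b"]

    def test_longer_alignment_breaks_identity_tie(self):
        alns = [_aln("r", "a", 0, length=100), _aln("r", "b", 0, length=150)]
        assert competitive_assign(alns)[0].ref_id == "b"

    def test_random_tie_split_is_balanced(self):
        alns = []
        for i in range(10_000):
            alns += [_aln(f"r{i}", "a", 0), _aln(f"r{i}", "b", 0)]
        winners = competitive_assign(alns, seed=5, tie_policy="random")
        n_a = sum(w.ref_id == "a" for w in winners)
        # binomial(10^4, 0.5), 4 sigma
        assert abs(n_a - 5000) < 4 * math.sqrt(10_000 * 0.25)

    def test_drop_policy_discards_ambiguous_reads(self):
        alns = [_aln("r", "a", 0), _aln("r", "b", 0), _aln("s", "a", 0)]
        winners = competitive_assign(alns, tie_policy="drop")
        assert [w.read_id for w in winners] == ["s"]

    def test_reads_assigned_to_their_source_genomovar(self, mixture_experiment):
        """Error-bearing reads from one genomovar of a 99.0%-ANI panel are
        essentially never credited to a different genomovar."""
        genomes, truth, reads, read_truth, alignments = mixture_experiment
        kept = filter_identity(alignments, 99.3)
        winners = competitive_assign(kept, seed=0, tie_policy="drop")
        src = dict(zip(read_truth.read_id, read_truth.genome))
        cross = sum(1 for w in winners if src[w.read_id] != w.ref_id)
        assert cross / len(winners) < 0.05
        a_reads = [w for w in winners if src[w.read_id] == "A_s1"]
        assert sum(w.ref_id == "A_s1" for w in a_reads) / len(a_reads) >= 0.95


class TestDepthProfile:
    def test_single_read_span(self):
        d = depth_profile([_aln("r", "ref", 0, start=0)], 300)
        assert (d[:150] == 1).all() and (d[150:] == 0).all()

    def test_overlap_depth(self):
        d = depth_profile([_aln("a", "ref", 0, 0), _aln("b", "ref", 0, 100)], 300)
        assert d[120] == 2 and d[50] == 1 and d[260] == 0

    def test_read_past_end_rejected(self):
        with pytest.raises(ValueError):
            depth_profile([_aln("r", "ref", 0, start=200)], 300)

    def test_uniform_coverage_matches_lander_waterman(self):
        genomes, _ = simulate_genomovar_genomes(
            ancestor_len=50_000, n_genomovars=1, strains_per_genomovar=1, seed=1
        )
        L = len(genomes[0])
        n = int(50 * L / 150)
        reads, truth = simulate_reads(genomes, [1.0], n_reads=n, seed=2)
        alns = [
            ReadAlignment(r.read_id, "g", r.start, 150, 0) for r in truth.itertuples()
        ]
        d = depth_profile(alns, L)
        assert d[200:-200].mean() == pytest.approx(50.0, abs=3.0)


def _tad_oracle(values, trim=0.10):
    """Independent sort-trim-mean implementation (pure python)."""
    ordered = sorted(values)
    k = int(math.floor(trim * len(ordered)))
    kept = ordered[k : len(ordered) - k]
    return statistics.fmean(kept)


class TestTad:
    def test_constant_depth(self):
        assert tad(np.full(57, 5)) == 5.0

    def test_worked_example(self):
        assert tad(np.array([0, 0, 5, 5, 5, 5, 5, 5, 5, 100])) == 4.375

    def test_spike_island_trimmed_away(self):
        d = np.full(1000, 5)
        d[100:200] = 900  # 10% of positions
        assert tad(d) == 5.0

    def test_trim_half_rejected(self):
        with pytest.raises(ValueError):
            tad(np.arange(100), trim=0.5)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=10, max_size=400))
    def test_matches_independent_oracle(self, values):
        assert tad(np.array(values)) == pytest.approx(_tad_oracle(values))


class TestEffortNormalize:
    @pytest.mark.parametrize("t,n,expected", [(234.0, 10**8, 234.0), (10.0, 5 * 10**7, 20.0)])
    def test_examples(self, t, n, expected):
        assert effort_normalize(t, n) == expected

    def test_scaling_laws(self):
        assert effort_normalize(10.0, 2 * 10**8) == effort_normalize(10.0, 10**8) / 2
        assert effort_normalize(20.0, 10**8) == 2 * effort_normalize(10.0, 10**8)

    def test_zero_total_reads_rejected(self):
        with pytest.raises(ValueError):
            effort_normalize(1.0, 0)


class TestMinDepthFilter:
    def _mat(self, raw_values):
        values = pd.DataFrame({"s1": raw_values})
        return AbundanceMatrix(values.astype(float)), values.astype(float)

    def test_boundaries(self):
        m, raw = self._mat([9.9, 10.0, 250.0])
        out = min_depth_filter(m, raw)
        assert out.flags["s1"].tolist() == [True, False, False]

    def test_all_above_threshold_unchanged(self):
        m, raw = self._mat([15.0, 20.0])
        out = min_depth_filter(m, raw)
        assert not out.flags.any().any()


class TestGeneCopyNumber:
    def test_examples(self):
        assert gene_copy_number(468.0, 234.0) == 2.0
        assert gene_copy_number(0.0, 234.0) == 0.0
        assert math.isnan(gene_copy_number(10.0, 0.0))

    def test_single_copy_gene_near_one(self):
        genomes, _ = simulate_genomovar_genomes(
            ancestor_len=50_000, n_genomovars=1, strains_per_genomovar=1, seed=3
        )
        L = len(genomes[0])
        reads, truth = simulate_reads(genomes, [1.0], n_reads=int(50 * L / 150), seed=4)
        alns = [ReadAlignment(r.read_id, "g", r.start, 150, 0) for r in truth.itertuples()]
        depth = depth_profile(alns, L)
        gene = tad(depth[10_000:11_000])
        species = tad(depth)
        assert gene_copy_number(gene, species) == pytest.approx(1.0, abs=0.1)


class TestMixtureRecovery:
    def test_tad80_shares_recover_weights(self, mixture_experiment):
        """Competitive TAD80 at the 99.3% filter recovers planted mixture
        weights 0.6/0.3/0.1 within 10% relative."""
        genomes, truth, reads, read_truth, alignments = mixture_experiment
        norm, raw = abundance_from_alignments(
            alignments,
            {g.id: len(g) for g in genomes},
            total_reads=len(reads),
            min_identity=99.3,
            seed=0,
        )
        shares = (raw / raw.sum()).to_numpy()
        weights = np.array([0.6, 0.3, 0.1])
        assert np.all(np.abs(shares - weights) / weights <= 0.10)
        assert (raw >= 10.0).all()  # everything above the depth floor
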