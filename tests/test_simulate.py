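"""The sort-seq simulator: library, phenotype, gating and sequencing."""

import numpy as np
import pytest
from scipy import stats

from sortmut.core import Mutation, encode_seq
from sortmut.mutcall import call_mutations
from sortmut.readproc import merge_pairs, ReadRecord
from sortmut.simulate import (
    CellPool,
    EffectModel,
    Gate,
    Library,
    MutationEffect,
    assign_fluorescence,
    default_effect_model,
    default_gates,
    demo_reference,
    generate_library,
    grow_and_measure,
    sequence_pool,
    sort_cells,
)

PHRED = 33


class TestGenerateLibrary:
    def test_all_wild_type(self, ref):
        lib = generate_library(ref, 100, {0: 1.0}, seed=0)
        assert all(g == () for g in lib.clones)

    def test_region_weights_confine_mutations(self, ref):
        lib = generate_library(
            ref, 500, {1: 1.0}, region_weights={"core": 1.0, "flanks": 0.0}, seed=1
        )
        start, end = ref.mutated_region
        for g in lib.clones:
            assert start <= g[0].position < end

    def test_mutation_count_distribution_converges(self, ref):
        n = 10_000
        lib = generate_library(ref, n, seed=2)
        counts = np.array([len(g) for g in lib.clones])
        p1 = 0.35  # default single-mutant mass
        observed = (counts == 1).mean()
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(observed - p1) < 3 * se

    def test_positions_distinct_within_clone(self, ref):
        lib = generate_library(ref, 300, {4: 1.0}, seed=3)
        for g in lib.clones:
            assert len({m.position for m in g}) == len(g) == 4

    def test_bad_distribution_rejected(self, ref):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_library(ref, 10, {0: 0.5, 1: 0.4}, seed=0)


class TestFluorescence:
    def test_wild_type_control_is_basal(self):
        m = EffectModel(basal_log_fluorescence=3.0, srna_repression=1.0, noise_sd=0.0)
        assert assign_fluorescence((), "control", m) == 3.0

    def test_wild_type_srna_is_repressed(self):
        m = EffectModel(basal_log_fluorescence=3.0, srna_repression=1.0, noise_sd=0.0)
        assert assign_fluorescence((), "srna", m) == 2.0

    def test_full_regulation_loss_restores_basal(self, ref):
        mut = Mutation(45, ref.sequence[45], "A" if ref.sequence[45] != "A" else "G")
        m = EffectModel(
            basal_log_fluorescence=3.0,
            srna_repression=1.0,
            effects={mut: MutationEffect(regulation_loss=1.0)},
            noise_sd=0.0,
        )
        assert assign_fluorescence((mut,), "srna", m) == 3.0

    def test_unknown_mutation_is_silent(self, ref):
        mut = Mutation(10, ref.sequence[10], "A" if ref.sequence[10] != "A" else "G")
        m = EffectModel(noise_sd=0.0)
        assert assign_fluorescence((mut,), "control", m) == m.basal_log_fluorescence


class TestGates:
    def test_gate_interval_validation(self):
        with pytest.raises(ValueError, match="lo"):
            Gate("bad", 2.0, 2.0)

    def test_default_gates_shape(self):
        gates = default_gates(EffectModel())
        assert gates["all"].lo == -np.inf and gates["all"].hi == np.inf
        assert gates["high"].lo > gates["low"].hi  # disjoint by construction

    def test_sorting_respects_gates_and_target(self, ref):
        lib = generate_library(ref, 200, seed=4)
        model = default_effect_model(ref)
        rng = np.random.default_rng(5)
        culture = grow_and_measure(lib, "srna", model, 20_000, rng)
        gates = default_gates(model)
        pools = sort_cells(culture, gates, 1000, rng)
        for name in ("high", "low"):
            pool = pools[name]
            assert len(pool) <= 1000
            assert gates[name].contains(pool.fluorescence).all()
        assert len(pools["all"]) == 1000  # subsampled from everything

    def test_disjoint_gates_give_disjoint_pools(self, ref):
        lib = generate_library(ref, 100, seed=6)
        model = default_effect_model(ref)
        rng = np.random.default_rng(7)
        culture = grow_and_measure(lib, "srna", model, 5000, rng)
        gates = default_gates(model)
        pools = sort_cells(culture, gates, 10**9, rng)
        high = set(map(tuple, np.c_[pools["high"].clone_indices, pools["high"].fluorescence]))
        low = set(map(tuple, np.c_[pools["low"].clone_indices, pools["low"].fluorescence]))
        assert not high & low

    def test_empty_gate_warns(self, ref):
        lib = generate_library(ref, 10, {0: 1.0}, seed=8)
        model = EffectModel(noise_sd=0.0)
        rng = np.random.default_rng(9)
        culture = grow_and_measure(lib, "control", model, 100, rng)
        with pytest.warns(UserWarning, match="empty"):
            pools = sort_cells(culture, {"g": Gate("g", 90.0, 99.0)}, 10, rng)
        assert len(pools["g"]) == 0

    def test_mixture_tail_occupancy(self):
        # two clone classes with known means: high-gate occupancy must match
        # the normal tail probability of the mixture
        ref = demo_reference()
        mut = Mutation(45, ref.sequence[45], "A")
        model = EffectModel(
            basal_log_fluorescence=3.0,
            srna_repression=1.0,
            effects={mut: MutationEffect(regulation_loss=1.0)},
            noise_sd=0.3,
        )
        lib = Library(ref, [(), (mut,)])  # 50/50 mixture of repressed/escaped
        rng = np.random.default_rng(10)
        n = 40_000
        culture = grow_and_measure(lib, "srna", model, n, rng)
        gate = default_gates(model)["high"]
        p_expected = 0.5 * stats.norm.sf(gate.lo, 2.0, 0.3) + 0.5 * stats.norm.sf(
            gate.lo, 3.0, 0.3
        )
        observed = gate.contains(culture.fluorescence).mean()
        se = np.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(observed - p_expected) < 3 * se


@pytest.fixture(scope="module")
def small_pool(ref):
    lib = generate_library(ref, 50, seed=20)
    rng = np.random.default_rng(21)
    return grow_and_measure(lib, "control", default_effect_model(ref), 400, rng)


class TestSequencing:
    def test_geometry_violation_rejected(self, small_pool):
        with pytest.raises(ValueError, match="read_length"):
            sequence_pool(small_pool, 60, 30, np.random.default_rng(0))

    def test_error_free_reads_reconstruct_genotypes(self, ref, small_pool):
        rng = np.random.default_rng(22)
        r1s, r2s = sequence_pool(small_pool, 100, 30, rng, error_free=True)
        for (rid1, s1, q1), (rid2, s2, q2), ci in zip(
            r1s, r2s, small_pool.clone_indices
        ):
            m = merge_pairs(
                ReadRecord(rid1, s1, np.frombuffer(q1.encode(), np.uint8) - PHRED),
                ReadRecord(rid2, s2, np.frombuffer(q2.encode(), np.uint8) - PHRED),
            )
            genotype = small_pool.library.clones[int(ci)]
            assert tuple(call_mutations(m.seq, ref)) == genotype

    def test_flat_q30_error_rate(self, ref, small_pool):
        rng = np.random.default_rng(23)
        r1s, _ = sequence_pool(small_pool, 100, 30, rng)
        clone_seqs = small_pool.library.mutant_sequences()
        mismatches = total = 0
        for (rid, s, _), ci in zip(r1s, small_pool.clone_indices):
            truth = clone_seqs[int(ci), :100]
            mismatches += int((encode_seq(s) != truth).sum())
            total += 100
        rate = mismatches / total
        se = np.sqrt(0.001 * 0.999 / total)
        assert abs(rate - 0.001) < 3 * se

    def test_same_seed_identical_reads(self, small_pool):
        a = sequence_pool(small_pool, 100, 30, np.random.default_rng(24))
        b = sequence_pool(small_pool, 100, 30, np.random.default_rng(24))
        assert a == b


class TestEndToEndTruth:
    def test_error_free_matrix_equals_truth(self, error_free_experiment):
        exp = error_free_experiment
        assert exp.matrix.counts.equals(
            exp.truth[exp.matrix.counts.columns].astype(int)
        )

    def test_byte_determinism(self, tmp_path):
        import filecmp
        from sortmut.simulate import SamplePlan, simulate_experiment

        kw = dict(
            plan=[SamplePlan("srna", "all", 1, 300)],
            n_clones=100,
            n_cells_per_replicate=1000,
            seed=33,
        )
        simulate_experiment(tmp_path / "a", **kw)
        simulate_experiment(tmp_path / "b", **kw)
        for f in (tmp_path / "a").iterdir():
            assert (tmp_path / "b" / f.name).read_bytes() == f.read_bytes()
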