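"""Simulator: library construction, clonal dynamics, read generation."""

import numpy as np
import pytest
from scipy import stats

from clonetrace import (
    BarcodeLibrary,
    ReadSimConfig,
    RouteParams,
    StageSpec,
    apply_recurrence_route,
    build_count_table,
    evolve_stage,
    generate_reads,
    initialize_population,
    jensen_shannon_divergence,
    make_library,
    shannon_index,
)
from clonetrace.simdata import measure_population, parse_barcode_id, simulate_cohort


def _pairwise_min_distance(modules):
    mat = np.frombuffer("".join(modules).encode(), dtype=np.uint8).reshape(len(modules), -1)
    dmin = mat.shape[1] + 1
    for i in range(len(modules)):
        d = (mat[i + 1 :] != mat[i]).sum(axis=1)
        if d.size:
            dmin = min(dmin, int(d.min()))
    return dmin


class TestMakeLibrary:
    def test_degenerate_single_pair(self):
        lib = make_library(1, 1, min_pairwise_distance=5, seed=1)
        assert lib.n_barcodes == 1
        assert lib.barcode_id(1, 1) == "1:1"

    def test_pairwise_distance_holds_exhaustively(self):
        lib = make_library(150, 150, min_pairwise_distance=5, seed=7)
        assert lib.n_barcodes == 22_500
        assert _pairwise_min_distance(lib.left_modules) >= 5
        assert _pairwise_min_distance(lib.right_modules) >= 5

    def test_deterministic_given_seed(self):
        a = make_library(30, 30, 5, seed=7)
        b = make_library(30, 30, 5, seed=7)
        assert a == b

    def test_impossible_distance_raises(self):
        # > 4^18 modules at distance 18 cannot exist; even d=18 at n=300 must fail fast
        with pytest.raises(RuntimeError, match="Hamming distance"):
            make_library(300, 1, min_pairwise_distance=18, seed=0)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            make_library(0, 5, 5, seed=0)


class TestLibraryType:
    def test_rejects_bad_modules(self):
        with pytest.raises(ValueError):
            BarcodeLibrary(("ACGT",), ("A" * 18,))
        with pytest.raises(ValueError):
            BarcodeLibrary(("A" * 18, "A" * 18), ("C" * 18,))

    def test_barcode_sequence_roundtrip(self, small_library):
        seq = small_library.barcode_sequence("3:7")
        assert len(seq) == 40
        assert seq[:18] == small_library.left_modules[2]
        assert seq[18:22] == small_library.linker
        assert parse_barcode_id("3:7") == (3, 7)


class TestInitializePopulation:
    def test_maximal_evenness_is_uniform(self, small_library):
        pop = initialize_population(small_library, 4, 10, evenness=1.0, seed=0)
        assert pop.n_clones == 4
        assert (pop.cells == 10).all()

    def test_shannon_near_log_n_at_high_evenness(self):
        lib = make_library(150, 150, 5, seed=3)
        pop = initialize_population(lib, 17_000, 5000, evenness=0.98, seed=3)
        h = shannon_index(pop.abundance())
        assert abs(h - np.log(17_000)) / np.log(17_000) < 0.05

    def test_top_clone_below_one_percent_near_even(self):
        lib = make_library(150, 150, 5, seed=4)
        pop = initialize_population(lib, 17_000, 5000, evenness=0.97, seed=5)
        assert pop.abundance().max() < 0.01
        assert pop.total_cells == 17_000 * 5000

    def test_empty_request_rejected(self, small_library):
        with pytest.raises(ValueError):
            initialize_population(small_library, 0, 10, 1.0, seed=0)

    def test_exceeding_pair_space_rejected(self, small_library):
        with pytest.raises(ValueError, match="pair space"):
            initialize_population(small_library, 401, 10, 1.0, seed=0)


class TestEvolveStage:
    def test_neutral_no_bottleneck_is_identity(self, small_population):
        stage = StageSpec("primary", bottleneck_size=small_population.total_cells,
                          growth_generations=0)
        out = evolve_stage(small_population, stage,
                           shared_fitness=np.zeros(small_population.n_clones), seed=1)
        assert (out.cells == small_population.cells).all()

    def test_extreme_bottleneck_single_survivor(self, small_population):
        stage = StageSpec("primary", bottleneck_size=1, growth_generations=0)
        out = evolve_stage(small_population, stage, seed=2)
        assert out.n_surviving == 1
        assert out.abundance().iloc[0] == 1.0

    def test_bottleneck_larger_than_population_rejected(self, small_population):
        stage = StageSpec("primary", bottleneck_size=small_population.total_cells + 1,
                          growth_generations=0)
        with pytest.raises(ValueError, match="without replacement"):
            evolve_stage(small_population, stage, seed=0)

    def test_extinct_clones_stay_extinct(self, small_population):
        tight = StageSpec("primary", bottleneck_size=20, growth_generations=3,
                          fitness_scale=0.2)
        out = evolve_stage(small_population, tight, seed=3)
        dead = out.cells == 0
        assert dead.any()
        again = evolve_stage(out, StageSpec("residual_early", 10, 4, 0.3), seed=4)
        assert (again.cells[dead] == 0).all()

    def test_neutral_limit_preserves_expected_abundance(self, small_population):
        # with s=0 the expected frequencies equal the input; deviation ~ 1/sqrt(cells)
        stage = StageSpec("primary", bottleneck_size=small_population.total_cells,
                          growth_generations=3)
        out = evolve_stage(small_population, stage,
                           shared_fitness=np.zeros(small_population.n_clones), seed=5)
        assert np.abs(out.frequencies() - small_population.frequencies()).max() < 0.02

    def test_shared_fitness_reproducible_dominance(self):
        lib = make_library(40, 40, 5, seed=21)
        pool = initialize_population(lib, 1000, 500, evenness=0.98, seed=22)
        stage = StageSpec("primary", bottleneck_size=50_000, growth_generations=8,
                          fitness_scale=0.3)
        s = np.random.default_rng(23).normal(0, stage.fitness_scale, pool.n_clones)
        rep1 = evolve_stage(pool, stage, shared_fitness=s, seed=24)
        rep2 = evolve_stage(pool, stage, shared_fitness=s, seed=25)
        rho = stats.spearmanr(rep1.frequencies(), rep2.frequencies()).statistic
        assert rho > 0.8
        between = jensen_shannon_divergence(rep1.abundance(), rep2.abundance())
        to_pool = jensen_shannon_divergence(rep1.abundance(), pool.abundance())
        assert between < to_pool


class TestRecurrenceRoutes:
    def test_denovo_full_dominance_is_monoclonal(self, selected_population):
        out = apply_recurrence_route(selected_population, "denovo_driver",
                                     RouteParams(dominant_fraction=1.0), seed=1)
        assert out.n_surviving == 1
        assert shannon_index(out.abundance()) == 0.0

    def test_denovo_partial_dominance_reaches_fraction(self, selected_population):
        out = apply_recurrence_route(selected_population, "denovo_driver",
                                     RouteParams(dominant_fraction=0.95), seed=2)
        assert out.abundance().max() >= 0.95

    def test_polyclonal_zero_noise_preserves_ranks(self, selected_population):
        out = apply_recurrence_route(selected_population, "polyclonal",
                                     RouteParams(fitness_noise=0.0), seed=3)
        before = selected_population.cells[selected_population.cells > 0]
        after = out.cells[selected_population.cells > 0]
        assert (np.argsort(before, kind="stable") == np.argsort(after, kind="stable")).all()

    def test_polyclonal_profile_stays_similar(self, selected_population):
        params = RouteParams()
        out = apply_recurrence_route(selected_population, "polyclonal", params, seed=4)
        jsd = jensen_shannon_divergence(out.abundance(), selected_population.abundance())
        assert jsd < params.similarity_threshold

    def test_dominant_preexisting_keeps_top_clone(self, selected_population):
        top_before = selected_population.abundance().idxmax()
        out = apply_recurrence_route(selected_population, "dominant_preexisting", seed=5)
        assert out.abundance().idxmax() == top_before
        assert out.abundance().max() >= 0.95

    def test_unknown_route_rejected(self, selected_population):
        with pytest.raises(ValueError, match="unknown recurrence route"):
            apply_recurrence_route(selected_population, "spontaneous", seed=0)


class TestGenerateReads:
    def test_error_free_reads_fully_recovered(self, small_library, selected_population,
                                              fastq_factory):
        path, truth = fastq_factory(selected_population, n_reads=2000)
        table = build_count_table({"s": path}, small_library)
        assert table.qc["s"]["assigned"] == 2000
        expected = truth["barcode_id"].value_counts()
        got = table.sample_counts("s")
        assert got.sort_index().equals(expected.sort_index().astype(np.int64))

    def test_zero_reads_empty_outputs(self, small_library, small_population, tmp_path):
        cfg = ReadSimConfig(n_reads=0, seed=0)
        path = tmp_path / "empty.fastq"
        truth = generate_reads(small_population, small_library, cfg, str(path))
        assert truth.empty
        assert path.read_bytes() == b""

    def test_byte_identical_for_same_seed(self, small_library, small_population, tmp_path):
        cfg = ReadSimConfig(n_reads=500, substitution_rate=0.01,
                            fraction_low_quality=0.1, seed=9)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        generate_reads(small_population, small_library, cfg, str(p1))
        generate_reads(small_population, small_library, cfg, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_monoclonal_reads_collapse_to_one_barcode(self, small_library, tmp_path):
        pop = initialize_population(small_library, 1, 1000, 1.0, seed=1)
        cfg = ReadSimConfig(n_reads=10_000, substitution_rate=0.01, seed=2)
        path = tmp_path / "mono.fastq"
        generate_reads(pop, small_library, cfg, str(path))
        table = build_count_table({"s": path}, small_library)
        assert len(table.df) == 1
        # >= 3 errors in one half occurs with probability ~8e-4/half
        assert 10_000 - table.qc["s"]["assigned"] <= 30

    def test_low_quality_fraction_fails_qc(self, small_library, small_population,
                                           fastq_factory):
        path, _ = fastq_factory(small_population, n_reads=4000,
                                fraction_low_quality=0.25, seed=3, name="lq.fastq")
        table = build_count_table({"s": path}, small_library)
        frac = table.qc["s"]["discarded"]["low_quality"] / 4000
        assert 0.20 < frac < 0.30

    def test_extinct_population_rejected(self, small_library):
        pop = initialize_population(small_library, 3, 10, 1.0, seed=0)
        pop.cells[:] = 0
        cfg = ReadSimConfig(n_reads=10, seed=0)
        with pytest.raises(ValueError, match="extinct"):
            generate_reads(pop, small_library, cfg, "/dev/null")


class TestCohortSimulation:
    def test_stage_profiles_and_fitness_sharing(self):
        cohort = simulate_cohort(n_replicates=2, seed=5)
        stages = cohort["stages"]
        assert set(stages) == {"primary", "residual_early", "residual_late"}
        # replicates share per-stage fitness vectors
        a, b = stages["primary"]
        assert (a.fitness["primary"] == b.fitness["primary"]).all()
        # late-residual fitness inherits the early-residual ranking (corr 1.0)
        final = stages["residual_late"][0]
        r_early = final.fitness["residual_early"]
        r_late = final.fitness["residual_late"]
        rho = stats.spearmanr(r_early, r_late).statistic
        assert rho > 0.999

    def test_measurement_detects_subset(self):
        cohort = simulate_cohort(n_replicates=1, seed=6)
        primary = cohort["stages"]["primary"][0]
        counts = measure_population(primary, 97_000, seed=7)
        assert counts.sum() == 97_000
        assert 0 < len(counts) < primary.n_clones
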