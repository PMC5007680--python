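import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parafit import (
    CircuitVersion,
    LatencyModel,
    OperatorBudget,
    ScheduleError,
    TopLevelConfig,
    build_msr_schedule,
    build_selection_schedule,
    comparator_reduce,
    enumerate_experiment_grid,
    evaluation_latency,
    execute_trace,
    msr,
    operator_requirements,
    parse_controller_name,
    run_msr_schedule,
    run_selection_schedule,
    subset_fitness,
    SelectionFitnessConfig,
)
from parafit.dataflow_schedule import check_dependencies
from naive_reference import naive_best, naive_msr


class TestCircuitVersion:
    def test_parse_msr_names(self):
        v = CircuitVersion.parse("msr-f8x8")
        assert (v.model, v.I, v.J) == ("partial", 8, 8)
        assert v.name == "msr-f8x8"
        v = CircuitVersion.parse("a4x4")
        assert (v.model, v.I, v.J) == ("full", 4, 4)
        assert v.name == "msr-a4x4"

    def test_parse_gene_selection(self):
        assert CircuitVersion.parse("gene-selection").model == "gene-selection"

    def test_parse_garbage(self):
        with pytest.raises(ScheduleError):
            CircuitVersion.parse("msr-x3y4")

    def test_parse_controller_name(self):
        info = parse_controller_name("controller-f16x8-NF6-NC3")
        assert info == {"model": "partial", "I": 16, "J": 8, "NF": 6, "NC": 3}

    def test_parse_controller_bad_nc(self):
        with pytest.raises(ScheduleError):
            parse_controller_name("controller-f16x8-NF6-NC4")


class TestOperatorRequirements:
    def test_partial_8x8(self):
        b = operator_requirements("msr-f8x8")
        assert (b.adders, b.multipliers, b.dividers, b.converters) == (8, 8, 8, 8)

    def test_full_4x4(self):
        b = operator_requirements("msr-a4x4")
        assert (b.adders, b.multipliers, b.dividers, b.converters) == (16, 16, 16, 16)

    def test_full_rectangular(self):
        b = operator_requirements("msr-a2x3")
        assert (b.adders, b.multipliers, b.dividers, b.converters) == (6, 6, 6, 6)

    def test_partial_rectangular_uses_max(self):
        b = operator_requirements("msr-f16x8")
        assert b.adders == 16

    def test_gene_selection_one_of_each(self):
        b = operator_requirements("gene-selection")
        assert (b.adders, b.multipliers, b.dividers, b.converters) == (1, 1, 1, 1)


class TestMsrScheduleStructure:
    def test_partial_has_six_steps(self):
        assert build_msr_schedule("msr-f8x8").n_steps == 6

    def test_full_has_five_steps(self):
        assert build_msr_schedule("msr-a4x4").n_steps == 5

    @pytest.mark.parametrize("ver,expected", [
        ("msr-f4x4", 6), ("msr-f16x8", 6), ("msr-f30x50", 6), ("msr-f2x2", 6),
        ("msr-a2x3", 5), ("msr-a5x5", 5), ("msr-a8x8", 5),
    ])
    def test_step_counts_independent_of_size(self, ver, expected):
        assert build_msr_schedule(ver).n_steps == expected

    def test_residue_step_widths(self):
        full = build_msr_schedule("msr-a4x4")
        partial = build_msr_schedule("msr-f4x4")
        full_res = next(s for s in full.steps if s.name == "residues")
        part_res = next(s for s in partial.steps if s.name == "residues")
        assert full_res.width == 16  # all I*J residues concurrent
        assert part_res.width <= operator_requirements("msr-f4x4").adders
        assert part_res.width == 4  # row-parallel

    def test_dependency_soundness_all_versions(self):
        for ver in ("msr-f2x2", "msr-f8x8", "msr-f16x8", "msr-a4x4", "msr-a5x5"):
            check_dependencies(build_msr_schedule(ver))  # raises on violation

    def test_budget_usage_within_requirements(self):
        for ver in ("msr-f8x8", "msr-f16x8", "msr-a4x4"):
            trace = build_msr_schedule(ver)
            req = operator_requirements(ver)
            for step in trace.steps:
                for group in step.groups:
                    unit = {"sum": "adders", "residue": "adders", "div": "dividers",
                            "conv": "converters", "msq": "multipliers"}[group.op]
                    assert group.width <= getattr(req, unit)

    def test_insufficient_budget_names_step(self):
        bad = OperatorBudget(adders=8, multipliers=8, dividers=0, converters=8)
        with pytest.raises(ScheduleError, match="divider"):
            build_msr_schedule("msr-f8x8", budget=bad)

    def test_rejects_gene_selection_version(self):
        with pytest.raises(ScheduleError):
            build_msr_schedule("gene-selection")


class TestScheduleExecution:
    @pytest.mark.parametrize("ver", ["msr-f2x2", "msr-f4x4", "msr-f8x8",
                                     "msr-f16x8", "msr-a2x3", "msr-a4x4", "msr-a5x5"])
    def test_msr_trace_matches_direct(self, ver, rng):
        v = CircuitVersion.parse(ver)
        trace = build_msr_schedule(v)
        for _ in range(5):
            x = rng.uniform(-50, 50, size=(v.I, v.J))
            assert run_msr_schedule(trace, x) == pytest.approx(msr(x), rel=1e-12)

    def test_msr_trace_matches_naive_oracle(self, rng):
        trace = build_msr_schedule("msr-f5x3")
        x = rng.normal(size=(5, 3))
        assert run_msr_schedule(trace, x) == pytest.approx(naive_msr(x), rel=1e-10)

    def test_tiny_example(self, tiny_matrix):
        trace = build_msr_schedule("msr-f2x2")
        assert run_msr_schedule(trace, tiny_matrix) == pytest.approx(0.0625)

    def test_shape_mismatch(self, rng):
        trace = build_msr_schedule("msr-f4x4")
        with pytest.raises(ValueError, match="shape"):
            run_msr_schedule(trace, rng.normal(size=(3, 4)))

    def test_selection_trace_matches_direct(self):
        trace = build_selection_schedule()
        F = run_selection_schedule(trace, w1=0.75, A=0.8, w2=0.25, M=100, R=25)
        assert F == pytest.approx(0.7875, rel=1e-12)
        cfg = SelectionFitnessConfig(w1=0.75, w2=0.25, M=100)
        assert F == pytest.approx(subset_fitness(0.8, 25, cfg), rel=1e-12)

    def test_selection_trace_random_operands(self, rng):
        trace = build_selection_schedule()
        for _ in range(50):
            w1, w2 = rng.uniform(0, 1, size=2)
            A = rng.uniform(0, 1)
            M = int(rng.integers(1, 500))
            R = int(rng.integers(0, M + 1))
            direct = subset_fitness(A, R, SelectionFitnessConfig(w1, w2, M))
            assert run_selection_schedule(trace, w1, A, w2, M, R) == \
                pytest.approx(direct, rel=1e-12, abs=1e-15)

    def test_execute_trace_step_isolation(self):
        # outputs must not be readable within their own macro-step
        trace = build_msr_schedule("msr-f2x2")
        env = {f"b_{i}_{j}": 1.0 for i in range(2) for j in range(2)}
        out = execute_trace(trace, env)
        assert out["MSR"] == pytest.approx(0.0)
        assert out["tsum"] == pytest.approx(4.0)


class TestSelectionScheduleStructure:
    def test_four_macro_steps(self):
        assert build_selection_schedule().n_steps == 4

    def test_first_step_width_three(self):
        trace = build_selection_schedule()
        assert trace.steps[0].width == 3

    def test_four_distinct_operator_types(self):
        trace = build_selection_schedule()
        used = set()
        for step in trace.steps:
            used.update(step.unit_ops().keys())
        assert used == {"adders", "multipliers", "dividers", "converters"}

    def test_dependency_soundness(self):
        check_dependencies(build_selection_schedule())


class TestComparatorReduce:
    def test_worked_example(self):
        r = comparator_reduce([3.2, 1.1, 7.5, 0.4], "maximize")
        assert (r.best, r.rounds, r.comparisons) == (7.5, 2, 3)

    def test_single_value(self):
        r = comparator_reduce([42.0])
        assert (r.best, r.rounds, r.comparisons) == (42.0, 0, 0)

    def test_eight_equal_values_tie_rule(self):
        r = comparator_reduce([5.0] * 8, "maximize")
        assert (r.best_index, r.rounds, r.comparisons) == (0, 3, 7)

    def test_minimize(self):
        r = comparator_reduce([3.0, -1.0, 2.0], "minimize")
        assert r.best == -1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            comparator_reduce([])

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            comparator_reduce([1.0], "argmax")

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=64),
           st.sampled_from(["maximize", "minimize"]))
    def test_matches_bruteforce(self, values, direction):
        r = comparator_reduce(values, direction)
        assert r.best == naive_best(values, direction)
        assert r.comparisons == len(values) - 1
        expected_rounds = 0 if len(values) == 1 else math.ceil(math.log2(len(values)))
        assert r.rounds == expected_rounds

    def test_nf6_matches_nc3_controller(self):
        # 6 values -> first round uses 3 comparators, 3 rounds total
        r = comparator_reduce(list(range(6)), "maximize")
        assert (r.best, r.rounds, r.comparisons) == (5.0, 3, 5)


class TestTopLevelConfig:
    def test_nc_derived(self):
        top = TopLevelConfig(NF=6)
        assert top.NC == 3

    def test_nc_must_be_half(self):
        with pytest.raises(ValueError):
            TopLevelConfig(NF=6, NC=4)


class TestEvaluationLatency:
    def test_single_unit_single_individual(self):
        trace = build_msr_schedule("msr-f4x4")
        rep = evaluation_latency(trace, top=TopLevelConfig(NF=1), population=1)
        assert rep.parallel_cycles == trace.cycles

    def test_one_full_batch(self):
        trace = build_msr_schedule("msr-f8x8")
        lat = trace.latency
        rep = evaluation_latency(trace, lat, TopLevelConfig(NF=8), population=8)
        assert rep.parallel_cycles == trace.cycles + 3 * lat.compare
        assert rep.batches == 1

    def test_batching(self):
        trace = build_selection_schedule()
        rep = evaluation_latency(trace, top=TopLevelConfig(NF=4), population=10)
        assert rep.batches == 3

    def test_speedup_at_least_one(self):
        for ver in ("msr-f8x8", "msr-a4x4"):
            trace = build_msr_schedule(ver)
            for nf in (1, 2, 8, 16):
                rep = evaluation_latency(trace, top=TopLevelConfig(NF=nf),
                                         population=32)
                assert rep.speedup >= 1.0

    def test_monotone_in_nf(self):
        trace = build_msr_schedule("msr-f8x8")
        for population in (1, 5, 8, 17, 64):
            prev = None
            for nf in range(1, population + 1):
                rep = evaluation_latency(trace, top=TopLevelConfig(NF=nf),
                                         population=population)
                if prev is not None:
                    assert rep.parallel_cycles <= prev
                prev = rep.parallel_cycles

    def test_population_validation(self):
        trace = build_selection_schedule()
        with pytest.raises(ValueError):
            evaluation_latency(trace, population=0)

    def test_latency_model_validation(self):
        with pytest.raises(ValueError):
            LatencyModel(divide=0)


class TestExperimentGrid:
    def test_gene_selection_grid_size(self):
        assert len(enumerate_experiment_grid("gene-selection")) == 36

    def test_biclustering_grid_size(self):
        assert len(enumerate_experiment_grid("biclustering")) == 48

    def test_unknown_problem(self):
        with pytest.raises(ValueError):
            enumerate_experiment_grid("sudoku")

    def test_entries_unique_and_named(self):
        entries = enumerate_experiment_grid("biclustering")
        names = {e.name for e in entries}
        assert len(names) == 48
        cases = {e.case for e in entries}
        assert cases == {"f4x4", "f8x8", "f16x8", "f16x16", "f30x50", "f32x64",
                         "a4x4", "a5x5"}

    def test_gene_selection_nf_cases(self):
        entries = enumerate_experiment_grid("gene-selection")
        assert {e.case for e in entries} == {f"NF{n}" for n in (8, 16, 32, 64, 128, 256)}
        # every listed version's schedule must be buildable
        for case in {e.case for e in enumerate_experiment_grid("biclustering")}:
            build_msr_schedule(f"msr-{case}")
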