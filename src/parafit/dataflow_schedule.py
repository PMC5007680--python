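"""Simulator of fine-grained parallel fitness-evaluation schedules.

A *schedule* is an ordered list of macro-steps. Each macro-step holds
task groups that run concurrently and whose tasks never consume another
same-step task's output. Tasks are concrete dataflow operations (named
inputs, named output), so every trace is numerically executable: running
a trace must reproduce the direct fitness value exactly — the schedule
is a reordering, never a re-definition.

Two MSR schedules are modelled: the *partially parallelized* variant
('f', six macro-steps, residues computed row-parallel but
column-sequential) and the *fully parallelized* variant ('a', five
macro-steps, all residues concurrent). The gene-selection fitness has a
four-step micro-schedule whose first step runs three operations at once.

Latency accounting is deliberately coarse (an invented cost model): ops
of each unit type within a step are spread over the budgeted units;
sequential latency executes one operation per cycle-slot. Real circuit
latencies depend on the vendor operator cores, so the per-operator cycle
counts here are config-overridable placeholders.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ScheduleError",
    "LatencyModel",
    "OperatorBudget",
    "CircuitVersion",
    "TopLevelConfig",
    "Task",
    "TaskGroup",
    "MacroStep",
    "ScheduleTrace",
    "ReduceResult",
    "LatencyReport",
    "ExperimentConfig",
    "operator_requirements",
    "build_msr_schedule",
    "build_selection_schedule",
    "check_dependencies",
    "execute_trace",
    "run_msr_schedule",
    "run_selection_schedule",
    "comparator_reduce",
    "evaluation_latency",
    "enumerate_experiment_grid",
    "parse_controller_name",
    "SYNTHESIS_PROFILES",
    "OPERATOR_OPTIMIZATIONS",
    "GENE_SELECTION_NF_CASES",
    "BICLUSTERING_CASES",
]


class ScheduleError(ValueError):
    """Raised for infeasible schedules or malformed circuit versions."""


UNIT_TYPES = ("adders", "multipliers", "dividers", "converters", "comparators")


@dataclass(frozen=True)
class LatencyModel:
    """Cycles per operation for each operator unit type."""

    add: int = 1
    multiply: int = 1
    divide: int = 8
    convert: int = 1
    compare: int = 1
    clock_ns: float | None = None

    def __post_init__(self) -> None:
        for name in ("add", "multiply", "divide", "convert", "compare"):
            if getattr(self, name) < 1:
                raise ValueError(f"latency {name} must be >= 1")

    def unit_latency(self, unit: str) -> int:
        return {
            "adders": self.add,
            "multipliers": self.multiply,
            "dividers": self.divide,
            "converters": self.convert,
            "comparators": self.compare,
        }[unit]


@dataclass(frozen=True)
class OperatorBudget:
    """Counts of operator units available to one fitness circuit."""

    adders: int = 0
    multipliers: int = 0
    dividers: int = 0
    converters: int = 0
    comparators: int = 0

    def __post_init__(self) -> None:
        for name in UNIT_TYPES:
            if getattr(self, name) < 0:
                raise ValueError(f"operator count {name} must be >= 0")

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in UNIT_TYPES}


_MSR_NAME = re.compile(r"^(?:msr-)?([fa])(\d+)x(\d+)$")


@dataclass(frozen=True)
class CircuitVersion:
    """A circuit implementation version: MSR model + matrix size, or gene selection."""

    model: str  # "partial" | "full" | "gene-selection"
    I: int | None = None
    J: int | None = None

    def __post_init__(self) -> None:
        if self.model == "gene-selection":
            if self.I is not None or self.J is not None:
                raise ScheduleError("gene-selection version takes no matrix size")
            return
        if self.model not in ("partial", "full"):
            raise ScheduleError(f"unknown circuit model {self.model!r}")
        if self.I is None or self.J is None or self.I < 1 or self.J < 1:
            raise ScheduleError(f"MSR version needs I >= 1 and J >= 1, got {self.I}x{self.J}")

    @property
    def model_letter(self) -> str:
        return {"partial": "f", "full": "a"}[self.model]

    @property
    def name(self) -> str:
        if self.model == "gene-selection":
            return "gene-selection"
        return f"msr-{self.model_letter}{self.I}x{self.J}"

    @classmethod
    def parse(cls, text: str) -> "CircuitVersion":
        if text == "gene-selection":
            return cls("gene-selection")
        m = _MSR_NAME.match(text)
        if not m:
            raise ScheduleError(f"cannot parse circuit version {text!r}")
        model = "partial" if m.group(1) == "f" else "full"
        return cls(model, int(m.group(2)), int(m.group(3)))


@dataclass(frozen=True)
class TopLevelConfig:
    """Top-level controller: NF parallel fitness units, NC = NF // 2 comparators."""

    NF: int
    NC: int | None = None

    def __post_init__(self) -> None:
        if self.NF < 1:
            raise ValueError(f"NF must be >= 1, got {self.NF}")
        nc = self.NF // 2 if self.NC is None else self.NC
        if nc != self.NF // 2:
            raise ValueError(f"NC must equal NF // 2 = {self.NF // 2}, got {nc}")
        object.__setattr__(self, "NC", nc)


# ---------------------------------------------------------------------------
# Tasks and traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Task:
    """One dataflow operation: named/literal args -> named output.

    Ops: sum (adder reduction), add, sub, isub (integer subtract on the
    adder), mul, div, conv (int-to-float), residue (b - rm - cm + om, 3
    adder ops), msq (mean of squares then divide: args are the values
    plus a final divisor).
    """

    op: str
    args: tuple
    out: str

    def unit_ops(self) -> dict[str, int]:
        n = len(self.args)
        if self.op == "sum":
            return {"adders": max(n - 1, 0)}
        if self.op in ("add", "sub", "isub"):
            return {"adders": 1}
        if self.op == "residue":
            return {"adders": 3}
        if self.op == "mul":
            return {"multipliers": 1}
        if self.op == "div":
            return {"dividers": 1}
        if self.op == "conv":
            return {"converters": 1}
        if self.op == "msq":
            k = n - 1  # last arg is the divisor
            return {"multipliers": k, "adders": max(k - 1, 0), "dividers": 1}
        raise ScheduleError(f"unknown task op {self.op!r}")


@dataclass(frozen=True)
class TaskGroup:
    """Tasks of one kind running concurrently on ``width`` parallel lanes."""

    op: str
    tasks: tuple[Task, ...]
    width: int
    note: str = ""

    @property
    def count(self) -> int:
        return len(self.tasks)

    def as_record(self) -> dict:
        return {"op": self.op, "count": self.count, "width": self.width, "note": self.note}


@dataclass(frozen=True)
class MacroStep:
    name: str
    groups: tuple[TaskGroup, ...]

    @property
    def width(self) -> int:
        """Total concurrent lanes across the step's task groups."""
        return sum(g.width for g in self.groups)

    def tasks(self) -> Iterable[Task]:
        for g in self.groups:
            yield from g.tasks

    def unit_ops(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for t in self.tasks():
            for unit, n in t.unit_ops().items():
                totals[unit] = totals.get(unit, 0) + n
        return totals


@dataclass(frozen=True)
class ScheduleTrace:
    version: str
    steps: tuple[MacroStep, ...]
    budget: OperatorBudget
    latency: LatencyModel
    cycles: int
    sequential_cycles: int

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def as_records(self) -> list[dict]:
        return [
            {"step": i + 1, "name": s.name, "width": s.width,
             "groups": [g.as_record() for g in s.groups]}
            for i, s in enumerate(self.steps)
        ]


def _step_cycles(step: MacroStep, budget: OperatorBudget, lat: LatencyModel) -> int:
    worst = 0
    for unit, n_ops in step.unit_ops().items():
        if n_ops == 0:
            continue
        units = getattr(budget, unit)
        if units < 1:
            raise ScheduleError(
                f"step '{step.name}': {n_ops} {unit[:-1]} operation(s) required "
                f"but the budget provides 0 {unit}"
            )
        worst = max(worst, math.ceil(n_ops / units) * lat.unit_latency(unit))
    return worst


def _finish_trace(version: str, steps: Sequence[MacroStep],
                  budget: OperatorBudget, lat: LatencyModel) -> ScheduleTrace:
    cycles = sum(_step_cycles(s, budget, lat) for s in steps)
    sequential = sum(
        n * lat.unit_latency(unit)
        for s in steps for unit, n in s.unit_ops().items()
    )
    trace = ScheduleTrace(version, tuple(steps), budget, lat, cycles, sequential)
    check_dependencies(trace)
    return trace


def check_dependencies(trace: ScheduleTrace) -> None:
    """Verify no macro-step task reads a value produced within the same step."""
    for k, step in enumerate(trace.steps, start=1):
        outs = {t.out for t in step.tasks()}
        if len(outs) != sum(1 for _ in step.tasks()):
            raise ScheduleError(f"step {k} '{step.name}': duplicate task outputs")
        for t in step.tasks():
            clash = [a for a in t.args if isinstance(a, str) and a in outs]
            if clash:
                raise ScheduleError(
                    f"step {k} '{step.name}': task {t.out} consumes same-step "
                    f"output(s) {clash}"
                )


# ---------------------------------------------------------------------------
# Schedule builders
# ---------------------------------------------------------------------------

def operator_requirements(v: CircuitVersion | str) -> OperatorBudget:
    """Operator units a circuit version instantiates.

    Partial MSR model: max(I, J) units of each of the four arithmetic
    types (8x8 -> 8 of each). Full model: I*J of each (4x4 -> 16 of
    each). Gene selection: one adder, multiplier, divider and converter.
    """
    if isinstance(v, str):
        v = CircuitVersion.parse(v)
    if v.model == "gene-selection":
        return OperatorBudget(adders=1, multipliers=1, dividers=1, converters=1)
    n = max(v.I, v.J) if v.model == "partial" else v.I * v.J
    return OperatorBudget(adders=n, multipliers=n, dividers=n, converters=n)


def _msr_tasks(I: int, J: int):
    b = lambda i, j: f"b_{i}_{j}"
    row_sums = tuple(Task("sum", tuple(b(i, j) for j in range(J)), f"rsum_{i}")
                     for i in range(I))
    col_sums = tuple(Task("sum", tuple(b(i, j) for i in range(I)), f"csum_{j}")
                     for j in range(J))
    consts = (
        Task("conv", (float(J),), "J_f"),
        Task("conv", (float(I),), "I_f"),
        Task("conv", (float(I * J),), "IJ_f"),
    )
    total = Task("sum", tuple(f"rsum_{i}" for i in range(I)), "tsum")
    row_means = tuple(Task("div", (f"rsum_{i}", "J_f"), f"rmean_{i}") for i in range(I))
    col_means = tuple(Task("div", (f"csum_{j}", "I_f"), f"cmean_{j}") for j in range(J))
    omean = Task("div", ("tsum", "IJ_f"), "omean")
    resid = tuple(
        Task("residue", (b(i, j), f"rmean_{i}", f"cmean_{j}", "omean"), f"r_{i}_{j}")
        for i in range(I) for j in range(J)
    )
    final = Task("msq", tuple(f"r_{i}_{j}" for i in range(I) for j in range(J)) + ("IJ_f",),
                 "MSR")
    return row_sums, col_sums, consts, total, row_means, col_means, omean, resid, final


def build_msr_schedule(version: CircuitVersion | str,
                       budget: OperatorBudget | None = None,
                       latency: LatencyModel | None = None) -> ScheduleTrace:
    """Build the macro-step schedule for an MSR circuit version.

    The partial model ('f') emits exactly six macro-steps; the full
    model ('a') exactly five. Executing the trace reproduces the MSR.
    """
    v = CircuitVersion.parse(version) if isinstance(version, str) else version
    if v.model not in ("partial", "full"):
        raise ScheduleError(f"not an MSR version: {v.name}")
    budget = operator_requirements(v) if budget is None else budget
    lat = LatencyModel() if latency is None else latency
    I, J = v.I, v.J
    (row_sums, col_sums, consts, total, row_means,
     col_means, omean, resid, final) = _msr_tasks(I, J)

    step1 = MacroStep("row-col-sums", (
        TaskGroup("sum", row_sums, width=min(I, budget.adders), note="row sums"),
        TaskGroup("sum", col_sums, width=min(J, budget.adders), note="column sums"),
        TaskGroup("conv", consts, width=min(3, budget.converters),
                  note="size constants to float"),
    ))
    g_total = TaskGroup("sum", (total,), width=1, note="total sum")
    g_rmeans = TaskGroup("div", row_means, width=min(I, budget.dividers), note="row means")
    g_cmeans = TaskGroup("div", col_means, width=min(J, budget.dividers), note="column means")
    g_omean = TaskGroup("div", (omean,), width=1, note="overall mean")
    g_final = TaskGroup("msq", (final,), width=min(I * J, budget.multipliers),
                        note="parallel squaring, adder-tree reduction, final divide")

    if v.model == "partial":
        steps = (
            step1,
            MacroStep("total-sum+row-means", (g_total, g_rmeans)),
            MacroStep("col-means", (g_cmeans,)),
            MacroStep("overall-mean", (g_omean,)),
            MacroStep("residues", (
                TaskGroup("residue", resid, width=min(I, budget.adders),
                          note="row-parallel, column-sequential"),
            )),
            MacroStep("squared-residue-reduction", (g_final,)),
        )
    else:
        steps = (
            step1,
            MacroStep("total-sum+row-means+col-means", (g_total, g_rmeans, g_cmeans)),
            MacroStep("overall-mean", (g_omean,)),
            MacroStep("residues", (
                TaskGroup("residue", resid, width=min(I * J, budget.adders),
                          note="fully parallel"),
            )),
            MacroStep("squared-residue-reduction", (g_final,)),
        )
    return _finish_trace(v.name, steps, budget, lat)


def build_selection_schedule(budget: OperatorBudget | None = None,
                             latency: LatencyModel | None = None) -> ScheduleTrace:
    """Four-macro-step schedule of the gene-selection fitness circuit.

    Step 1 runs three operations in parallel: w1*A, w2/M and the integer
    subtract M - R. Then: int-to-float conversion, multiply, final add.
    """
    v = CircuitVersion("gene-selection")
    budget = operator_requirements(v) if budget is None else budget
    lat = LatencyModel() if latency is None else latency
    steps = (
        MacroStep("parallel-operands", (
            TaskGroup("mul", (Task("mul", ("w1", "A"), "w1A"),), width=1, note="w1 * A"),
            TaskGroup("div", (Task("div", ("w2", "M"), "w2_over_M"),), width=1,
                      note="w2 / M"),
            TaskGroup("isub", (Task("isub", ("M", "R"), "M_minus_R"),), width=1,
                      note="M - R (integer)"),
        )),
        MacroStep("convert", (
            TaskGroup("conv", (Task("conv", ("M_minus_R",), "M_minus_R_f"),), width=1,
                      note="int-to-float of M - R"),
        )),
        MacroStep("size-term", (
            TaskGroup("mul", (Task("mul", ("w2_over_M", "M_minus_R_f"), "size_term"),),
                      width=1, note="(w2 / M) * (M - R)"),
        )),
        MacroStep("final-add", (
            TaskGroup("add", (Task("add", ("w1A", "size_term"), "F"),), width=1,
                      note="F = w1*A + size term"),
        )),
    )
    return _finish_trace(v.name, steps, budget, lat)


# ---------------------------------------------------------------------------
# Numeric execution of traces
# ---------------------------------------------------------------------------

def _exec_task(task: Task, env: Mapping[str, float]) -> float:
    vals = [env[a] if isinstance(a, str) else float(a) for a in task.args]
    if task.op == "sum":
        total = 0.0
        for x in vals:  # left-to-right, like a chained adder
            total += x
        return total
    if task.op == "add":
        return vals[0] + vals[1]
    if task.op in ("sub", "isub"):
        return vals[0] - vals[1]
    if task.op == "mul":
        return vals[0] * vals[1]
    if task.op == "div":
        return vals[0] / vals[1]
    if task.op == "conv":
        return float(vals[0])
    if task.op == "residue":
        b, rm, cm, om = vals
        return b - rm - cm + om
    if task.op == "msq":
        *xs, d = vals
        s = 0.0
        for x in xs:
            s += x * x
        return s / d
    raise ScheduleError(f"unknown task op {task.op!r}")


def execute_trace(trace: ScheduleTrace, env: Mapping[str, float]) -> dict[str, float]:
    """Run a trace on concrete inputs, returning the full value environment.

    Outputs of a macro-step only become visible to the next step, which
    dynamically enforces the dependency-soundness invariant.
    """
    env = dict(env)
    for step in trace.steps:
        produced: dict[str, float] = {}
        for task in step.tasks():
            produced[task.out] = _exec_task(task, env)
        env.update(produced)
    return env


def run_msr_schedule(trace: ScheduleTrace, values) -> float:
    """Execute an MSR trace on a matrix and return the scheduled MSR value."""
    import numpy as np

    v = np.asarray(values.values if hasattr(values, "values") else values, dtype=float)
    ver = CircuitVersion.parse(trace.version)
    if v.shape != (ver.I, ver.J):
        raise ValueError(f"matrix shape {v.shape} does not match version {trace.version}")
    env = {f"b_{i}_{j}": float(v[i, j])
           for i in range(ver.I) for j in range(ver.J)}
    return execute_trace(trace, env)["MSR"]


def run_selection_schedule(trace: ScheduleTrace, w1: float, A: float,
                           w2: float, M: int, R: int) -> float:
    """Execute the gene-selection trace on concrete operands, returning F."""
    env = {"w1": float(w1), "A": float(A), "w2": float(w2),
           "M": float(M), "R": float(R)}
    return execute_trace(trace, env)["F"]


# ---------------------------------------------------------------------------
# Comparator reduction tree and latency model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReduceResult:
    best: float
    best_index: int
    rounds: int
    comparisons: int


def comparator_reduce(values: Sequence[float], direction: str = "maximize") -> ReduceResult:
    """Pairwise-halving comparator tree over NF fitness values.

    Each round compares survivors in pairs (an odd one passes through as
    a bye). Ties keep the earlier-index value. Total comparisons are
    NF - 1 and rounds are ceil(log2(NF)) (0 for a single value).
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"direction must be maximize or minimize, got {direction!r}")
    vals = [float(x) for x in values]
    if not vals:
        raise ValueError("comparator_reduce needs at least one value")
    keep_first = (lambda a, b: a >= b) if direction == "maximize" else (lambda a, b: a <= b)
    survivors = list(enumerate(vals))
    rounds = 0
    comparisons = 0
    while len(survivors) > 1:
        rounds += 1
        nxt = []
        for p in range(0, len(survivors) - 1, 2):
            (ia, a), (ib, bb) = survivors[p], survivors[p + 1]
            comparisons += 1
            nxt.append((ia, a) if keep_first(a, bb) else (ib, bb))
        if len(survivors) % 2:
            nxt.append(survivors[-1])
        survivors = nxt
    idx, best = survivors[0]
    return ReduceResult(best=best, best_index=idx, rounds=rounds, comparisons=comparisons)


def _tree_rounds(k: int) -> int:
    return (k - 1).bit_length() if k >= 1 else 0  # == ceil(log2 k), 0 for k = 1


@dataclass(frozen=True)
class LatencyReport:
    parallel_cycles: int
    sequential_cycles: int
    speedup: float
    batches: int


def evaluation_latency(trace: ScheduleTrace, lat: LatencyModel | None = None,
                       top: TopLevelConfig | None = None,
                       population: int = 1) -> LatencyReport:
    """Simulated cycles to evaluate a population and reduce to the best value.

    Parallel: the population is processed in ceil(population / NF)
    batches of the trace latency each; all values then feed one pairwise
    comparator tree (batch winners are folded into the same tree), whose
    critical path is ceil(log2(population)) compare rounds. Sequential:
    one operation per cycle-slot, one individual at a time.
    """
    if population < 1:
        raise ValueError(f"population must be >= 1, got {population}")
    lat = trace.latency if lat is None else lat
    top = TopLevelConfig(NF=1) if top is None else top
    batches = math.ceil(population / top.NF)
    parallel = batches * trace.cycles + _tree_rounds(population) * lat.compare
    sequential = population * trace.sequential_cycles
    return LatencyReport(
        parallel_cycles=parallel,
        sequential_cycles=sequential,
        speedup=sequential / parallel,
        batches=batches,
    )


# ---------------------------------------------------------------------------
# Synthesis-experiment grid
# ---------------------------------------------------------------------------

SYNTHESIS_PROFILES = ("default", "timing-physical", "timing-no-iob")
OPERATOR_OPTIMIZATIONS = ("dsp", "logic")
GENE_SELECTION_NF_CASES = (8, 16, 32, 64, 128, 256)
BICLUSTERING_CASES = ("f4x4", "f8x8", "f16x8", "f16x16", "f30x50", "f32x64",
                      "a4x4", "a5x5")


@dataclass(frozen=True)
class ExperimentConfig:
    problem: str
    case: str
    profile: str
    operator_opt: str
    name: str


def enumerate_experiment_grid(problem: str) -> list[ExperimentConfig]:
    """Enumerate the synthesis-experiment grid for a problem.

    Gene selection: 6 NF cases x 3 profiles x 2 operator optimizations
    (36 entries). Biclustering: 8 circuit versions x 3 x 2 (48 entries).
    """
    entries: list[ExperimentConfig] = []
    if problem == "gene-selection":
        for nf in GENE_SELECTION_NF_CASES:
            for profile in SYNTHESIS_PROFILES:
                for opt in OPERATOR_OPTIMIZATIONS:
                    name = f"controller-geneselection-NF{nf}-NC{nf // 2}-{profile}-{opt}"
                    entries.append(ExperimentConfig(problem, f"NF{nf}", profile, opt, name))
    elif problem == "biclustering":
        for case in BICLUSTERING_CASES:
            for profile in SYNTHESIS_PROFILES:
                for opt in OPERATOR_OPTIMIZATIONS:
                    name = f"msr-{case}-{profile}-{opt}"
                    entries.append(ExperimentConfig(problem, case, profile, opt, name))
    else:
        raise ValueError(f"unknown problem {problem!r}; "
                         "expected 'gene-selection' or 'biclustering'")
    return entries


_CONTROLLER_NAME = re.compile(r"^controller-([fa])(\d+)x(\d+)-NF(\d+)-NC(\d+)$")


def parse_controller_name(name: str) -> dict:
    """Parse a controller name like ``controller-f16x8-NF6-NC3``."""
    m = _CONTROLLER_NAME.match(name)
    if not m:
        raise ScheduleError(f"cannot parse controller name {name!r}")
    model = "partial" if m.group(1) == "f" else "full"
    nf, nc = int(m.group(4)), int(m.group(5))
    if nc != nf // 2:
        raise ScheduleError(f"{name!r}: NC={nc} is not NF//2={nf // 2}")
    return {"model": model, "I": int(m.group(2)), "J": int(m.group(3)),
            "NF": nf, "NC": nc}
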