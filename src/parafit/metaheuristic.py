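"""Seeded generational evolutionary algorithm over both fitness functions.

One EA core (tournament selection, uniform crossover, per-bit mutation,
elitism) serves two problems: gene-subset selection (maximize F) and
bicluster search. The evaluation phase reports simulated sequential vs
NF-parallel latency through the dataflow-schedule model, and picks the
per-generation best with the comparator reduction tree.

Bicluster objectives
--------------------
``msr``        maximize -MSR (reported values are un-negated). With a
               small minimum bicluster size this converges onto tiny
               near-zero-MSR submatrices, which is the faithful reading
               of pure MSR minimization.
``coherence``  vol_frac * (var - penalty * MSR), where vol_frac is the
               fraction of matrix cells covered and var the variance of
               the block's cells. By the two-way ANOVA decomposition
               var - MSR is the variance explained by row + column
               effects, so the score is the additive signal captured by
               the block, with excess residual penalized. This is the
               objective that can actually recover a planted additive
               bicluster: i.i.d. noise blocks of any size have the same
               MSR scale as a planted additive block with equal noise
               (pure MSR cannot tell them apart), but var ~ 1.2 * MSR
               for noise, so with penalty > 1.2 noise blocks score
               negative while signal-bearing coherent blocks score
               positive and grow with size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataflow_schedule import (
    LatencyModel,
    LatencyReport,
    ReduceResult,
    ScheduleTrace,
    TopLevelConfig,
    build_msr_schedule,
    build_selection_schedule,
    comparator_reduce,
    evaluation_latency,
)
from .expression_io import ExpressionMatrix, GeneSubset, LabeledDataset
from .msr_fitness import msr
from .selection_fitness import SelectionFitnessConfig, evaluate_subset

__all__ = [
    "ConfigError",
    "EAConfig",
    "Individual",
    "EvolveResult",
    "evolve",
    "evaluate_population",
    "jaccard",
]


class ConfigError(ValueError):
    """Raised for infeasible EA configurations."""


@dataclass
class EAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1 / genome length
    tournament_size: int = 2
    seed: int = 0
    eval_NF: int = 8
    elitism: int = 1
    # gene-selection knobs
    w1: float = 0.75
    w2: float = 0.25
    classifier: str = "nearest-centroid"
    # biclustering knobs
    min_rows: int = 2
    min_cols: int = 2
    bicluster_objective: str = "msr"
    coherence_penalty: float = 3.0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ConfigError(f"population_size must be >= 2, got {self.population_size}")
        if self.generations < 1:
            raise ConfigError(f"generations must be >= 1, got {self.generations}")
        for name in ("crossover_rate",):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {r}")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError(f"mutation_rate must lie in [0, 1], got {self.mutation_rate}")
        if self.tournament_size < 2:
            raise ConfigError(f"tournament_size must be >= 2, got {self.tournament_size}")
        if self.population_size < self.tournament_size:
            raise ConfigError(
                f"population_size ({self.population_size}) must be >= "
                f"tournament_size ({self.tournament_size})"
            )
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ConfigError(f"elitism must lie in [0, population_size), got {self.elitism}")
        if self.eval_NF < 1:
            raise ConfigError(f"eval_NF must be >= 1, got {self.eval_NF}")
        if self.bicluster_objective not in ("msr", "coherence"):
            raise ConfigError(
                f"bicluster_objective must be 'msr' or 'coherence', "
                f"got {self.bicluster_objective!r}"
            )


@dataclass
class Individual:
    genome: np.ndarray
    fitness: float | None = None

    def copy(self) -> "Individual":
        return Individual(self.genome.copy(), self.fitness)


@dataclass
class EvolveResult:
    best: Individual
    history: list[dict]
    latency_report: LatencyReport
    metrics: dict


def jaccard(a: Sequence[int], b: Sequence[int]) -> float:
    """Jaccard overlap of two index sets."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def _decode_bicluster(genome: np.ndarray, I: int):
    rows = np.flatnonzero(genome[:I])
    cols = np.flatnonzero(genome[I:])
    return rows, cols


def _bicluster_score(parent: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                     objective: str, penalty: float = 3.0) -> float:
    sub = parent[np.ix_(rows, cols)]
    m = msr(sub)
    if objective == "msr":
        return -m
    var = float(sub.var())
    vol_frac = sub.size / parent.size
    return vol_frac * (var - penalty * m)


def evaluate_population(pop: Sequence[Individual],
                        fitness_fn: Callable[[np.ndarray], float],
                        top: TopLevelConfig | None = None,
                        trace: ScheduleTrace | None = None,
                        latency: LatencyModel | None = None,
                        ) -> tuple[np.ndarray, ReduceResult, LatencyReport | None]:
    """Evaluate every individual; pick the best via the comparator tree.

    Fitness values are cached on the individuals. The latency report
    (if a trace is given) simulates ceil(len(pop) / NF) parallel batches.
    """
    if not pop:
        raise ValueError("population must be non-empty")
    for ind in pop:
        if ind.fitness is None:
            ind.fitness = float(fitness_fn(ind.genome))
    values = np.array([ind.fitness for ind in pop], dtype=float)
    best = comparator_reduce(values, "maximize")
    report = None
    if trace is not None:
        report = evaluation_latency(trace, latency, top, population=len(pop))
    return values, best, report


def _repair_selection(genome: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not genome.any():
        genome[rng.integers(genome.size)] = True
    return genome


def _repair_bicluster(genome: np.ndarray, I: int, J: int, min_rows: int,
                      min_cols: int, rng: np.random.Generator) -> np.ndarray:
    for lo, hi, need in ((0, I, min(min_rows, I)), (I, I + J, min(min_cols, J))):
        side = genome[lo:hi]
        deficit = need - int(side.sum())
        if deficit > 0:
            off = np.flatnonzero(~side)
            side[rng.choice(off, size=deficit, replace=False)] = True
    return genome


def evolve(problem: str, data, cfg: EAConfig) -> EvolveResult:
    """Run the EA on ``selection`` (LabeledDataset) or ``biclustering``
    (ExpressionMatrix) and return best individual, history and the
    simulated evaluation-latency report.

    Deterministic given ``cfg.seed``; with elitism the per-generation
    best fitness is monotone non-decreasing.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    if problem == "selection":
        if not isinstance(data, LabeledDataset):
            raise ConfigError("selection problem needs a LabeledDataset")
        L = data.M
        sel_cfg = SelectionFitnessConfig(cfg.w1, cfg.w2, data.M)

        def fitness_fn(genome: np.ndarray) -> float:
            return evaluate_subset(data, GeneSubset(genome), sel_cfg, cfg.classifier)

        def repair(genome: np.ndarray) -> np.ndarray:
            return _repair_selection(genome, rng)

        trace = build_selection_schedule()
    elif problem == "biclustering":
        if not isinstance(data, ExpressionMatrix):
            raise ConfigError("biclustering problem needs an ExpressionMatrix")
        I, J = data.shape
        L = I + J
        parent = data.values

        def fitness_fn(genome: np.ndarray) -> float:
            rows, cols = _decode_bicluster(genome, I)
            return _bicluster_score(parent, rows, cols, cfg.bicluster_objective,
                                    cfg.coherence_penalty)

        def repair(genome: np.ndarray) -> np.ndarray:
            return _repair_bicluster(genome, I, J, cfg.min_rows, cfg.min_cols, rng)

        trace = build_msr_schedule(f"msr-f{I}x{J}")
    else:
        raise ConfigError(f"unknown problem {problem!r}")

    mut_rate = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / L
    top = TopLevelConfig(NF=cfg.eval_NF)

    pop = [Individual(repair(rng.random(L) < 0.5)) for _ in range(cfg.population_size)]
    history: list[dict] = []
    seq_total = 0
    par_total = 0

    for gen in range(cfg.generations):
        values, best, report = evaluate_population(pop, fitness_fn, top, trace)
        seq_total += report.sequential_cycles
        par_total += report.parallel_cycles
        history.append({
            "generation": gen,
            "best": float(best.best),
            "mean": float(values.mean()),
        })
        if gen == cfg.generations - 1:
            break
        order = np.argsort(-values, kind="stable")
        new_pop = [pop[i].copy() for i in order[:cfg.elitism]]
        while len(new_pop) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                winner = max(contenders, key=lambda i: (values[i], -i))
                parents.append(pop[winner].genome)
            if rng.random() < cfg.crossover_rate:
                take_first = rng.random(L) < 0.5
                children = [np.where(take_first, parents[0], parents[1]),
                            np.where(take_first, parents[1], parents[0])]
            else:
                children = [parents[0].copy(), parents[1].copy()]
            for child in children:
                if len(new_pop) >= cfg.population_size:
                    break
                child = child ^ (rng.random(L) < mut_rate)
                new_pop.append(Individual(repair(child)))
        pop = new_pop

    values = np.array([ind.fitness for ind in pop], dtype=float)
    best_idx = int(np.argmax(values))
    best = pop[best_idx]
    latency_report = LatencyReport(
        parallel_cycles=par_total,
        sequential_cycles=seq_total,
        speedup=seq_total / par_total,
        batches=math.ceil(cfg.population_size / cfg.eval_NF) * cfg.generations,
    )

    if problem == "selection":
        subset = GeneSubset(best.genome)
        metrics = {"F": float(best.fitness), "R": subset.R, "M": subset.M,
                   "genes": list(subset.indices())}
    else:
        rows, cols = _decode_bicluster(best.genome, data.shape[0])
        metrics = {
            "score": float(best.fitness),
            "msr": float(msr(data.values[np.ix_(rows, cols)])),
            "rows": [int(i) for i in rows],
            "cols": [int(j) for j in cols],
        }
    return EvolveResult(best=best, history=history,
                        latency_report=latency_report, metrics=metrics)
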