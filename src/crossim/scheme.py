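"""Multi-cycle recurrent selection: cycle execution, evaluation metrics,
replicated experiments and matched-pair comparison statistics.

A benchmark run proceeds per replicate as follows.  A genome and trait
architecture are drawn, a 200-plant F8 initial population is built from one
fully heterozygous F1, and effects are rescaled so the initial genetic
variance is 1.  A lasso prediction model is trained on the initial
population's phenotypes and shared by all strategies of the replicate, so
that within a replicate strategies differ only in their selection decisions
(matched pairs).  Each strategy then runs five selection cycles; the model is
retrained on the current population at odd-numbered cycles (1, 3, 5; the
cycle-1 model being the shared initial fit) and reused at even cycles.

Per cycle the new 200-plant F2 population is summarised by: its maximum
genetic value (MGV, the genetic-gain criterion), the proportions of trait
loci fixed for the favorable allele, fixed for the unfavorable allele, and
still segregating, and the selection accuracy (Pearson correlation between
PVs and true GVs).  The initial population is reported as cycle 0.  Once a
population is completely fixed at every trait locus no selection can change
it, so the last cycle's record is carried forward to the end of the scheme.

Strategies are compared per cycle with a matched paired t-test on the
replicate MGVs, Bonferroni-adjusted for the number of comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .genome import (
    TraitArchitecture,
    build_genome,
    sample_effects,
    scale_effects_to_unit_variance,
)
from .meiosis import Population, make_initial_population
from .prediction import PredictionModel, TrainingData, fit_model, predict
from .strategies import F1_ALLOTMENT, next_generation, select_strategy_P, \
    select_strategy_S
from .trait import genetic_values, phenotype_population

__all__ = [
    "SimParams",
    "Condition",
    "CycleRecord",
    "PairedTestResult",
    "ExperimentResult",
    "parse_strategy",
    "population_fully_fixed",
    "compute_metrics",
    "run_cycle",
    "run_experiment",
    "matched_pair_test",
    "ALL_STRATEGIES",
]

ALL_STRATEGIES = ("S1", "S5", "S10", "P1", "P5", "P10")


@dataclass(frozen=True)
class SimParams:
    """Progeny-simulation settings for the S strategies: F1 per candidate
    cross, F2 per F1, and the tail size k used for scoring."""

    n_f1: int = 5
    n_f2_per_f1: int = 40
    k: int = 10


@dataclass(frozen=True)
class Condition:
    """One benchmark condition: number of trait loci and heritability."""

    n_qtl: int
    h2: float


@dataclass(frozen=True)
class CycleRecord:
    """Evaluation metrics of one cycle's F2 population."""

    cycle: int
    mgv: float
    prop_fixed_favorable: float
    prop_fixed_unfavorable: float
    prop_unfixed: float
    accuracy: float  # NaN when PV or GV variance is zero
    model_updated: bool

    def __post_init__(self):
        s = (
            self.prop_fixed_favorable
            + self.prop_fixed_unfavorable
            + self.prop_unfixed
        )
        if abs(s - 1.0) > 1e-12:
            raise ParameterError("fixation proportions must sum to 1")


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    p_adjusted: float
    n_pairs: int


def parse_strategy(label: str) -> Tuple[str, int]:
    """'S10' -> ('S', 10); valid labels are S1/S5/S10/P1/P5/P10."""
    label = label.strip().upper()
    if len(label) >= 2 and label[0] in "SP":
        try:
            n = int(label[1:])
        except ValueError:
            n = -1
        if n in F1_ALLOTMENT:
            return label[0], n
    raise ParameterError(f"unknown strategy label {label!r}")


def population_fully_fixed(pop: Population) -> bool:
    """True when every trait locus is homozygous for one allele in every
    individual — no selection decision can alter such a population."""
    codes = pop.codes()
    return bool(np.all((codes.min(axis=0) == codes.max(axis=0)) &
                       (codes.min(axis=0) != 0)))


def compute_metrics(
    pop: Population,
    model: PredictionModel,
    arch: TraitArchitecture,
    cycle: int = 0,
    model_updated: bool = False,
) -> CycleRecord:
    """Summarise a population: MGV, fixation proportions, selection accuracy.

    A locus is fixed favorable iff every individual is homozygous for the
    favorable allele, fixed unfavorable iff every individual is homozygous
    for the other allele, and unfixed otherwise.  Accuracy is the Pearson
    correlation between PVs and GVs over individuals; when either has zero
    variance (e.g. an intercept-only model) it is undefined and reported as
    NaN with a warning.
    """
    codes = pop.codes()
    gv = genetic_values(codes, arch)
    mgv = float(gv.max())
    fav_code = np.where(arch.favorable == 0, 1, -1).astype(np.int8)
    cmin = codes.min(axis=0)
    cmax = codes.max(axis=0)
    mono = cmin == cmax
    fixed_fav = mono & (cmin == fav_code)
    fixed_unfav = mono & (cmin == -fav_code)
    n_loci = codes.shape[1]
    n_fav = int(fixed_fav.sum())
    n_unfav = int(fixed_unfav.sum())
    p_fav = n_fav / n_loci
    p_unfav = n_unfav / n_loci
    p_unfixed = (n_loci - n_fav - n_unfav) / n_loci
    pv = predict(model, codes)
    if np.ptp(pv) == 0.0 or np.ptp(gv) == 0.0:
        warnings.warn(
            "selection accuracy undefined (zero-variance PV or GV); "
            "reporting NaN",
            stacklevel=2,
        )
        acc = float("nan")
    else:
        acc = float(np.corrcoef(pv, gv)[0, 1])
    return CycleRecord(
        cycle=cycle,
        mgv=mgv,
        prop_fixed_favorable=float(p_fav),
        prop_fixed_unfavorable=float(p_unfav),
        prop_unfixed=float(p_unfixed),
        accuracy=acc,
        model_updated=model_updated,
    )


def run_cycle(
    pop: Population,
    model: PredictionModel,
    strategy: str,
    arch: TraitArchitecture,
    h2: float,
    cycle_index: int,
    rng: np.random.Generator,
    sim: SimParams = SimParams(),
    n_f2_total: int = 200,
    direction: str = "high",
    refit: Optional[bool] = None,
) -> Tuple[Population, PredictionModel, CycleRecord]:
    """Run one selection cycle and return (next population, model, record).

    The model is refit on the current population's codes and freshly drawn
    phenotypes when ``refit`` is true (default: at odd-numbered cycles);
    the record summarises the F2 population this cycle produces.
    """
    kind, n_crosses = parse_strategy(strategy)
    if refit is None:
        refit = cycle_index % 2 == 1
    if refit:
        _, y = phenotype_population(pop, arch, h2, rng)
        model = fit_model(
            TrainingData(pop.codes(), y, pop.gmap.locus_ids), rng=rng
        )
    if kind == "P":
        plan = select_strategy_P(pop, model, n_crosses, direction=direction)
    else:
        plan = select_strategy_S(
            pop, model, n_crosses,
            n_f1=sim.n_f1, n_f2_per_f1=sim.n_f2_per_f1, k=sim.k,
            direction=direction, rng=rng,
        )
    nxt = next_generation(plan, pop, n_f2_total=n_f2_total, rng=rng,
                          generation=f"F2c{cycle_index}")
    record = compute_metrics(
        nxt, model, arch, cycle=cycle_index,
        model_updated=(cycle_index % 2 == 1),
    )
    return nxt, model, record


@dataclass
class ExperimentResult:
    """Long-format metric table of a replicated benchmark plus metadata.

    ``table`` columns: strategy, n_qtl, h2, replicate, cycle, mgv,
    prop_fixed_fav, prop_fixed_unfav, prop_unfixed, accuracy, model_updated.
    """

    table: pd.DataFrame
    seed: int
    n_replicates: int
    n_cycles: int
    strategies: tuple
    conditions: tuple

    def metric(
        self,
        strategy: str,
        cycle: int,
        metric: str,
        n_qtl: Optional[int] = None,
        h2: Optional[float] = None,
    ) -> np.ndarray:
        """Per-replicate values of one metric, ordered by replicate index."""
        t = self.table
        sel = (t["strategy"] == strategy) & (t["cycle"] == cycle)
        if n_qtl is not None:
            sel &= t["n_qtl"] == n_qtl
        if h2 is not None:
            sel &= t["h2"] == h2
        sub = t[sel].sort_values("replicate")
        return sub[metric].to_numpy()

    def compare(
        self,
        strategy_a: str,
        strategy_b: str,
        cycle: int,
        metric: str = "mgv",
        n_comparisons: int = 1,
        n_qtl: Optional[int] = None,
        h2: Optional[float] = None,
    ) -> PairedTestResult:
        a = self.metric(strategy_a, cycle, metric, n_qtl=n_qtl, h2=h2)
        b = self.metric(strategy_b, cycle, metric, n_qtl=n_qtl, h2=h2)
        return matched_pair_test(a, b, n_comparisons=n_comparisons)


def run_experiment(
    strategies: Sequence[str] = ALL_STRATEGIES,
    conditions: Sequence[Condition] = (Condition(n_qtl=30, h2=0.6),),
    n_replicates: int = 50,
    n_cycles: int = 5,
    seed: int = 0,
    n_groups: int = 20,
    length_cM: float = 150.0,
    population_size: int = 200,
    sim: SimParams = SimParams(),
    direction: str = "high",
    include_cycle0: bool = True,
) -> ExperimentResult:
    """Replicated multi-strategy benchmark under one or more conditions.

    Within each replicate all strategies start from the same initial
    population, trait architecture and cycle-1 prediction model, and consume
    independent downstream random streams, so per-replicate differences
    between strategies reflect selection decisions only.  Identical seeds
    yield identical results.
    """
    strategies = [parse_strategy(s)[0] + str(parse_strategy(s)[1])
                  for s in strategies]
    if not strategies or not conditions:
        raise ParameterError("need at least one strategy and one condition")
    if n_replicates < 1 or n_cycles < 1:
        raise ParameterError("n_replicates and n_cycles must be >= 1")
    master = np.random.SeedSequence(seed)
    cond_seeds = master.spawn(len(conditions))
    rows: List[dict] = []
    for cond, cond_ss in zip(conditions, cond_seeds):
        rep_seeds = cond_ss.spawn(n_replicates)
        for rep, rep_ss in enumerate(rep_seeds):
            streams = rep_ss.spawn(1 + len(strategies))
            rng0 = np.random.default_rng(streams[0])
            gmap = build_genome(n_groups, length_cM, cond.n_qtl, rng0)
            arch = sample_effects(cond.n_qtl, rng=rng0)
            pop0 = make_initial_population(gmap, population_size, rng0)
            arch = scale_effects_to_unit_variance(arch, pop0)
            _, y0 = phenotype_population(pop0, arch, cond.h2, rng0)
            model0 = fit_model(
                TrainingData(pop0.codes(), y0, gmap.locus_ids), rng=rng0
            )
            for s_i, strat in enumerate(strategies):
                rng = np.random.default_rng(streams[1 + s_i])
                pop, model = pop0, model0
                prev: Optional[CycleRecord] = None
                if include_cycle0:
                    rec0 = compute_metrics(pop0, model0, arch, cycle=0)
                    rows.append(_row(strat, cond, rep, rec0))
                for c in range(1, n_cycles + 1):
                    if prev is not None and population_fully_fixed(pop):
                        rec = replace(prev, cycle=c, model_updated=False)
                    else:
                        pop, model, rec = run_cycle(
                            pop, model, strat, arch, cond.h2, c, rng,
                            sim=sim, n_f2_total=population_size,
                            direction=direction,
                            refit=(c % 2 == 1 and c > 1),
                        )
                    rows.append(_row(strat, cond, rep, rec))
                    prev = rec
    table = pd.DataFrame(rows)
    return ExperimentResult(
        table=table,
        seed=seed,
        n_replicates=n_replicates,
        n_cycles=n_cycles,
        strategies=tuple(strategies),
        conditions=tuple(conditions),
    )


def _row(strategy: str, cond: Condition, rep: int, rec: CycleRecord) -> dict:
    return {
        "strategy": strategy,
        "n_qtl": cond.n_qtl,
        "h2": cond.h2,
        "replicate": rep,
        "cycle": rec.cycle,
        "mgv": rec.mgv,
        "prop_fixed_fav": rec.prop_fixed_favorable,
        "prop_fixed_unfav": rec.prop_fixed_unfavorable,
        "prop_unfixed": rec.prop_unfixed,
        "accuracy": rec.accuracy,
        "model_updated": rec.model_updated,
    }


def matched_pair_test(
    a: np.ndarray, b: np.ndarray, n_comparisons: int = 1
) -> PairedTestResult:
    """Two-sided paired t-test of per-replicate values with a Bonferroni
    adjustment: p_adjusted = min(1, p * n_comparisons).

    Replicate i of ``a`` and ``b`` must come from the same initial population
    (the match pairing).  If every difference is zero the test is degenerate
    and reported as t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ParameterError("need two equal-length vectors with >= 2 pairs")
    if n_comparisons < 1:
        raise ParameterError("n_comparisons must be >= 1")
    d = a - b
    if np.all(d == 0.0):
        return PairedTestResult(t=0.0, p=1.0, p_adjusted=1.0, n_pairs=a.size)
    res = stats.ttest_rel(a, b)
    t, p = float(res.statistic), float(res.pvalue)
    return PairedTestResult(
        t=t, p=p, p_adjusted=min(1.0, p * n_comparisons), n_pairs=a.size
    )
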