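"""Parent-selection strategies and the in-silico progeny cross-ranking engine.

Two families of strategies pick the crosses that found the next generation of
a recurrent selection scheme:

* P strategies rank *plants* by their own prediction value (PV) and cross the
  top plants — one cross (P1), or the top 5 / top 10 plants chained in a
  round-robin design (P5, P10).
* S strategies rank *crosses*: for every unordered pair of plants, F2 progeny
  of the pair are simulated through the genetic map and scored by the mean PV
  of their best k members, and the top-scoring 1 / 5 / 10 pairs are crossed
  (S1, S5, S10).  Scoring by a top (or bottom) tail rewards crosses whose
  progeny distribution has both a good mean and a large variance — the
  segregation the simulation makes visible before any plant is crossed.

Every strategy allocates the same budget of 10 F1 plants per cycle (10, 2 or
1 F1 per cross for 1, 5 or 10 crosses) so strategies differ only in how the
crosses are chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import ParameterError, StructuralError
from .genome import GeneticMap
from .meiosis import DiploidIndividual, Population, gamete_batch
from .prediction import PredictionModel, predict

__all__ = [
    "CrossCandidate",
    "PlannedCross",
    "CrossingPlan",
    "F1_ALLOTMENT",
    "enumerate_cross_pairs",
    "round_robin_pairs",
    "simulate_cross_progeny",
    "score_cross",
    "rank_all_crosses",
    "select_strategy_P",
    "select_strategy_S",
    "next_generation",
    "top_k_for_fraction",
]

#: F1 plants allotted per cross so that every plan totals 10 F1.
F1_ALLOTMENT = {1: 10, 5: 2, 10: 1}

_CHUNK_CROSSES = 1024  # fixed so rng consumption (hence output) is reproducible


@dataclass(frozen=True)
class CrossCandidate:
    """One scored parent pair.  ``parent1 < parent2`` are indices into the
    candidate population; ``score`` is the mean PV of the k best (direction
    'high') or k worst ('low') simulated progeny; ``progeny_pv_variance`` is
    the sample variance of all simulated progeny PVs."""

    parent1: int
    parent2: int
    parent1_id: str
    parent2_id: str
    score: float
    progeny_pv_variance: float
    n_simulated: int
    rank: Optional[int] = None

    def __post_init__(self):
        if self.parent1 == self.parent2:
            raise ParameterError("self-crosses are not candidate crosses")


@dataclass(frozen=True)
class PlannedCross:
    parent1: int
    parent2: int
    n_f1: int
    candidate: Optional[CrossCandidate] = None


@dataclass(frozen=True)
class CrossingPlan:
    crosses: Tuple[PlannedCross, ...]
    strategy: str
    direction: str = "high"

    def __post_init__(self):
        object.__setattr__(self, "crosses", tuple(self.crosses))

    @property
    def total_f1(self) -> int:
        return sum(c.n_f1 for c in self.crosses)


def enumerate_cross_pairs(n: int) -> Tuple[np.ndarray, np.ndarray]:
    """All C(n, 2) unordered distinct pairs (i < j), no self-crosses."""
    if n < 2:
        raise ParameterError("need at least two parents to enumerate crosses")
    return np.triu_indices(n, k=1)


def round_robin_pairs(plants) -> List[Tuple[int, int]]:
    """Chain crossing design over ``plants``: (p1,p2), (p2,p3), ..., (pk,p1)."""
    plants = list(plants)
    k = len(plants)
    if k < 3:
        raise ParameterError("round-robin chain needs at least 3 plants")
    return [(plants[i], plants[(i + 1) % k]) for i in range(k)]


def top_k_for_fraction(n_progeny: int, fraction: float = 0.05) -> int:
    """Number of progeny in the scored tail: floor(fraction * n), at least 1
    (10 of 200, 12 of 250 at the default 5%)."""
    if not 0.0 < fraction <= 1.0:
        raise ParameterError("fraction must be in (0, 1]")
    return max(1, int(np.floor(fraction * n_progeny)))


# ---------------------------------------------------------------------------
# progeny simulation
# ---------------------------------------------------------------------------


def _marker_context(gmap: GeneticMap, model: PredictionModel):
    """Map the model's markers onto the map.

    Returns ``(idx, coef_map_order)`` where ``idx`` is the sorted map index of
    each model marker and ``coef_map_order`` the coefficients aligned to that
    order, so progeny codes can be simulated at the marker loci only.
    """
    lookup = {lid: i for i, lid in enumerate(gmap.locus_ids)}
    try:
        raw = np.array([lookup[m] for m in model.marker_ids], dtype=np.int64)
    except KeyError as exc:
        raise StructuralError(f"model marker {exc.args[0]!r} not on the map")
    order = np.argsort(raw, kind="stable")
    return raw[order], model.coef[order]


def _simulate_f2_bdose(
    par1_haps: np.ndarray,
    par2_haps: np.ndarray,
    flip_p: np.ndarray,
    n_f1: int,
    n_f2_per_f1: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate F2 families for C crosses at once.

    ``par1_haps``/``par2_haps`` are (C, 2, L) haplotypes of the two parents of
    each cross.  For each cross, ``n_f1`` F1 are drawn (one gamete from each
    parent) and each F1 is selfed ``n_f2_per_f1`` times.  Returns the
    founder-B allele dose (0, 1 or 2; genotype code = 1 - dose) of every F2,
    shape (C, n_f1 * n_f2_per_f1, L).
    """
    C, _, L = par1_haps.shape
    rep = np.repeat(np.arange(C), n_f1)
    f1_h1 = gamete_batch(par1_haps[rep, 0], par1_haps[rep, 1], flip_p, rng)
    f1_h2 = gamete_batch(par2_haps[rep, 0], par2_haps[rep, 1], flip_p, rng)
    idx = np.repeat(np.arange(C * n_f1), n_f2_per_f1)
    ga = gamete_batch(f1_h1[idx], f1_h2[idx], flip_p, rng)
    gb = gamete_batch(f1_h1[idx], f1_h2[idx], flip_p, rng)
    np.add(ga, gb, out=ga)
    return ga.reshape(C, n_f1 * n_f2_per_f1, L)


def _pv_from_bdose(bdose: np.ndarray, coef: np.ndarray, intercept: float):
    """PV = mu + (1 - dose) @ beta, evaluated without materialising codes."""
    coef32 = coef.astype(np.float32)
    base = np.float32(intercept + coef.sum())
    return base - bdose.astype(np.float32) @ coef32


def simulate_cross_progeny(
    p1: DiploidIndividual,
    p2: DiploidIndividual,
    gmap: GeneticMap,
    model: PredictionModel,
    n_f1: int,
    n_f2_per_f1: int,
    rng: np.random.Generator,
    return_codes: bool = False,
):
    """Simulate one candidate cross: ``n_f1`` F1 genotypes from p1 x p2, each
    selfed ``n_f2_per_f1`` times, and the PV of every resulting F2.

    Returns the PV vector (length n_f1 * n_f2_per_f1), or ``(pvs, codes)``
    with the F2 marker codes when ``return_codes`` is set.
    """
    if n_f1 < 1 or n_f2_per_f1 < 1:
        raise ParameterError("n_f1 and n_f2_per_f1 must be >= 1")
    idx, coef = _marker_context(gmap, model)
    flip_p = gmap.flip_probs(idx)
    par1 = np.stack([p1.hap1[idx], p1.hap2[idx]])[None]
    par2 = np.stack([p2.hap1[idx], p2.hap2[idx]])[None]
    dose = _simulate_f2_bdose(par1, par2, flip_p, n_f1, n_f2_per_f1, rng)[0]
    codes = (1 - dose.astype(np.int16)).astype(np.int8)
    pvs = model.intercept + codes.astype(float) @ coef
    if return_codes:
        return pvs, codes
    return pvs


def score_cross(progeny_pvs: np.ndarray, k: int, direction: str = "high"):
    """Score a simulated F2 family: mean of its k largest PVs (direction
    'high') or k smallest ('low'), plus the sample variance of all PVs."""
    pvs = np.asarray(progeny_pvs, dtype=float)
    n = pvs.size
    if direction not in ("high", "low"):
        raise ParameterError("direction must be 'high' or 'low'")
    if k < 1 or k > n:
        raise ParameterError(f"k = {k} outside [1, {n}]")
    if direction == "high":
        tail = np.partition(pvs, n - k)[n - k:]
    else:
        tail = np.partition(pvs, k - 1)[:k]
    var = float(np.var(pvs, ddof=1)) if n > 1 else 0.0
    return float(tail.mean()), var


def rank_all_crosses(
    pop: Population,
    model: PredictionModel,
    gmap: Optional[GeneticMap] = None,
    n_f1: int = 5,
    n_f2_per_f1: int = 40,
    k: int = 10,
    direction: str = "high",
    rng: Optional[np.random.Generator] = None,
) -> List[CrossCandidate]:
    """Enumerate and score every pairwise cross of ``pop``.

    For each of the C(n, 2) unordered parent pairs an F2 family of
    ``n_f1 * n_f2_per_f1`` progeny is simulated at the model's marker loci and
    scored by :func:`score_cross`.  The returned candidates are sorted best
    first (descending score for 'high', ascending for 'low'), ties broken by
    ascending parent indices, with ``rank`` filled in starting at 1.
    """
    gmap = pop.gmap if gmap is None else gmap
    if rng is None:
        rng = np.random.default_rng()
    n = len(pop)
    n_prog = n_f1 * n_f2_per_f1
    if direction not in ("high", "low"):
        raise ParameterError("direction must be 'high' or 'low'")
    if n_f1 < 1 or n_f2_per_f1 < 1:
        raise ParameterError("n_f1 and n_f2_per_f1 must be >= 1")
    if k < 1 or k > n_prog:
        raise ParameterError(f"k = {k} outside [1, {n_prog}]")
    i1, i2 = enumerate_cross_pairs(n)
    idx, coef = _marker_context(gmap, model)
    flip_p = gmap.flip_probs(idx)
    haps = pop.haplotypes[:, :, idx]
    n_pairs = i1.size
    scores = np.empty(n_pairs)
    variances = np.empty(n_pairs)
    ddof = 1 if n_prog > 1 else 0
    for lo in range(0, n_pairs, _CHUNK_CROSSES):
        hi = min(lo + _CHUNK_CROSSES, n_pairs)
        dose = _simulate_f2_bdose(
            haps[i1[lo:hi]], haps[i2[lo:hi]], flip_p, n_f1, n_f2_per_f1, rng
        )
        pvs = _pv_from_bdose(dose, coef, model.intercept)
        if direction == "high":
            tail = np.partition(pvs, n_prog - k, axis=1)[:, n_prog - k:]
        else:
            tail = np.partition(pvs, k - 1, axis=1)[:, :k]
        scores[lo:hi] = tail.mean(axis=1)
        variances[lo:hi] = pvs.var(axis=1, ddof=ddof)
    sort_key = -scores if direction == "high" else scores
    order = np.lexsort((i2, i1, sort_key))
    return [
        CrossCandidate(
            parent1=int(i1[j]),
            parent2=int(i2[j]),
            parent1_id=pop.ids[i1[j]],
            parent2_id=pop.ids[i2[j]],
            score=float(scores[j]),
            progeny_pv_variance=float(variances[j]),
            n_simulated=n_prog,
            rank=r + 1,
        )
        for r, j in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# strategy plans
# ---------------------------------------------------------------------------


def _rank_plants_by_pv(pop: Population, model: PredictionModel, direction: str):
    codes = pop.codes()
    idx, coef = _marker_context(pop.gmap, model)
    pv = model.intercept + codes[:, idx].astype(float) @ coef
    key = -pv if direction == "high" else pv
    # ties broken by ascending individual index (lexsort is stable on keys)
    return np.lexsort((np.arange(len(pop)), key)), pv


def select_strategy_P(
    pop: Population,
    model: PredictionModel,
    n_crosses: int,
    direction: str = "high",
) -> CrossingPlan:
    """Phenotype-free conventional selection: rank plants by their own PV.

    P1 crosses the top two plants (10 F1); P5 and P10 chain the top 5 / top 10
    plants in a round-robin design (2 / 1 F1 per cross).
    """
    if n_crosses not in F1_ALLOTMENT:
        raise ParameterError("n_crosses must be one of 1, 5, 10")
    need = 2 if n_crosses == 1 else n_crosses
    if len(pop) < need:
        raise ParameterError(
            f"P{n_crosses} needs at least {need} plants, got {len(pop)}"
        )
    order, _ = _rank_plants_by_pv(pop, model, direction)
    if n_crosses == 1:
        pairs = [(int(order[0]), int(order[1]))]
    else:
        pairs = round_robin_pairs(int(i) for i in order[:n_crosses])
    n_f1 = F1_ALLOTMENT[n_crosses]
    crosses = tuple(
        PlannedCross(parent1=min(a, b), parent2=max(a, b), n_f1=n_f1)
        for a, b in pairs
    )
    return CrossingPlan(crosses=crosses, strategy=f"P{n_crosses}",
                        direction=direction)


def select_strategy_S(
    pop: Population,
    model: PredictionModel,
    n_crosses: int,
    gmap: Optional[GeneticMap] = None,
    n_f1: int = 5,
    n_f2_per_f1: int = 40,
    k: int = 10,
    direction: str = "high",
    rng: Optional[np.random.Generator] = None,
) -> CrossingPlan:
    """Simulation-based selection: rank all pairwise crosses by simulated
    progeny and keep the top ``n_crosses`` (1, 5 or 10)."""
    if n_crosses not in F1_ALLOTMENT:
        raise ParameterError("n_crosses must be one of 1, 5, 10")
    n = len(pop)
    if n < 2 or (n * (n - 1)) // 2 < n_crosses:
        raise ParameterError(
            f"S{n_crosses} needs at least {n_crosses} candidate pairs"
        )
    ranking = rank_all_crosses(
        pop, model, gmap=gmap, n_f1=n_f1, n_f2_per_f1=n_f2_per_f1,
        k=k, direction=direction, rng=rng,
    )
    alloc = F1_ALLOTMENT[n_crosses]
    crosses = tuple(
        PlannedCross(
            parent1=c.parent1, parent2=c.parent2, n_f1=alloc, candidate=c
        )
        for c in ranking[:n_crosses]
    )
    return CrossingPlan(crosses=crosses, strategy=f"S{n_crosses}",
                        direction=direction)


def next_generation(
    plan: CrossingPlan,
    pop: Population,
    n_f2_total: int = 200,
    rng: Optional[np.random.Generator] = None,
    generation: str = "F2",
) -> Population:
    """Execute a crossing plan: generate each cross's allotted F1 plants,
    self every F1 an equal number of times, and pool all F2 into a single
    population of ``n_f2_total``."""
    if rng is None:
        rng = np.random.default_rng()
    total_f1 = plan.total_f1
    if total_f1 < 1:
        raise ParameterError("crossing plan allots no F1 plants")
    if n_f2_total % total_f1 != 0:
        raise ParameterError(
            f"n_f2_total = {n_f2_total} not divisible by {total_f1} F1 plants"
        )
    n_per_f1 = n_f2_total // total_f1
    flip_p = pop.gmap.flip_probs()
    p1_idx = np.repeat(
        [c.parent1 for c in plan.crosses], [c.n_f1 for c in plan.crosses]
    )
    p2_idx = np.repeat(
        [c.parent2 for c in plan.crosses], [c.n_f1 for c in plan.crosses]
    )
    f1_h1 = gamete_batch(
        pop.haplotypes[p1_idx, 0], pop.haplotypes[p1_idx, 1], flip_p, rng
    )
    f1_h2 = gamete_batch(
        pop.haplotypes[p2_idx, 0], pop.haplotypes[p2_idx, 1], flip_p, rng
    )
    rep = np.repeat(np.arange(total_f1), n_per_f1)
    ga = gamete_batch(f1_h1[rep], f1_h2[rep], flip_p, rng)
    gb = gamete_batch(f1_h1[rep], f1_h2[rep], flip_p, rng)
    haps = np.stack([ga, gb], axis=1)
    ids = tuple(
        f"{generation}_{p1_idx[f]}x{p2_idx[f]}_f{f}_{j}"
        for f in range(total_f1)
        for j in range(n_per_f1)
    )
    return Population(
        haplotypes=haps, gmap=pop.gmap, ids=ids, generation=generation
    )
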