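"""Meiosis, crossing, selfing and single-seed-descent inbreeding.

Crossovers follow a no-interference model: on a linkage group of length L cM
the crossover count is Poisson(L/100) with positions uniform on the group,
which is exactly the process behind the Haldane map function.  Two equivalent
implementations are provided:

* :func:`sample_gamete` simulates the crossover events of a single meiosis
  explicitly (and can report the crossover count);
* :func:`gamete_batch` simulates many gametes at once using the interval
  formulation — the parental phase at the first locus of each group is a fair
  coin and flips between consecutive loci with the Haldane recombination
  fraction of their distance.  Because a Poisson process has independent
  increments, the two formulations give identical joint distributions at the
  mapped loci; the batch path exists because ranking every pairwise cross of a
  population requires millions of gametes.

Founder alleles are labelled 0 (founder A) and 1 (founder B); a haplotype is a
uint8 vector over the mapped loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError, StructuralError
from .genome import GeneticMap

__all__ = [
    "ALLELE_A",
    "ALLELE_B",
    "DiploidIndividual",
    "Population",
    "sample_gamete",
    "gamete_batch",
    "self_population_haplotypes",
    "cross",
    "self_",
    "ssd_advance",
    "make_initial_population",
]

ALLELE_A = 0
ALLELE_B = 1


@dataclass
class DiploidIndividual:
    """Two haplotypes over the loci of a genetic map, plus bookkeeping."""

    hap1: np.ndarray
    hap2: np.ndarray
    gmap: GeneticMap
    id: Optional[str] = None
    pedigree: Optional[dict] = None

    def __post_init__(self):
        self.hap1 = np.ascontiguousarray(self.hap1, dtype=np.uint8)
        self.hap2 = np.ascontiguousarray(self.hap2, dtype=np.uint8)
        L = self.gmap.n_loci
        if self.hap1.shape != (L,) or self.hap2.shape != (L,):
            raise StructuralError("haplotypes must have one allele per map locus")
        if self.hap1.max(initial=0) > 1 or self.hap2.max(initial=0) > 1:
            raise StructuralError("founder-allele labels must be 0 (A) or 1 (B)")

    def codes(self) -> np.ndarray:
        """Genotype codes: +1 = AA, 0 = AB, -1 = BB."""
        return (1 - self.hap1.astype(np.int16) - self.hap2).astype(np.int8)

    @property
    def is_homozygous(self) -> bool:
        return bool(np.all(self.hap1 == self.hap2))


@dataclass
class Population:
    """An ordered set of diploid individuals sharing one genetic map.

    Haplotypes are stored as a (n, 2, n_loci) uint8 array, the layout every
    vectorised operation in the package works on.
    """

    haplotypes: np.ndarray
    gmap: GeneticMap
    ids: tuple
    generation: str = ""

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.ids = tuple(self.ids)
        n = len(self.ids)
        if n < 1:
            raise ParameterError("a population needs at least one member")
        if self.haplotypes.shape != (n, 2, self.gmap.n_loci):
            raise StructuralError(
                "haplotype array must be (n individuals, 2, n map loci)"
            )

    def __len__(self) -> int:
        return len(self.ids)

    def codes(self) -> np.ndarray:
        """(n, n_loci) genotype code matrix: +1 = AA, 0 = AB, -1 = BB."""
        s = self.haplotypes.sum(axis=1, dtype=np.int16)
        return (1 - s).astype(np.int8)

    def individual(self, i: int) -> DiploidIndividual:
        return DiploidIndividual(
            hap1=self.haplotypes[i, 0].copy(),
            hap2=self.haplotypes[i, 1].copy(),
            gmap=self.gmap,
            id=self.ids[i],
        )

    @classmethod
    def from_individuals(
        cls, individuals: Sequence[DiploidIndividual], generation: str = ""
    ) -> "Population":
        if not individuals:
            raise ParameterError("a population needs at least one member")
        gmap = individuals[0].gmap
        for ind in individuals:
            if ind.gmap is not gmap and ind.gmap != gmap:
                raise StructuralError("all members must share one genetic map")
        haps = np.stack(
            [np.stack([ind.hap1, ind.hap2]) for ind in individuals]
        )
        ids = tuple(
            ind.id if ind.id is not None else f"ind{i:04d}"
            for i, ind in enumerate(individuals)
        )
        return cls(haplotypes=haps, gmap=gmap, ids=ids, generation=generation)


# ---------------------------------------------------------------------------
# gamete simulation
# ---------------------------------------------------------------------------


def _sample_phases(
    flip_p: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, L) boolean phase matrix: False = read haplotype 1, True = 2."""
    flips = rng.random((n, flip_p.size), dtype=np.float32) < flip_p
    np.logical_xor.accumulate(flips, axis=1, out=flips)
    return flips


def gamete_batch(
    hap1: np.ndarray,
    hap2: np.ndarray,
    flip_p: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one gamete per row of ``hap1``/``hap2``.

    ``hap1[i]`` and ``hap2[i]`` are the two haplotypes of the parent of gamete
    i (already gathered to (n, L) uint8); ``flip_p`` comes from
    :meth:`GeneticMap.flip_probs` for the loci represented.
    """
    ph = _sample_phases(flip_p, hap1.shape[0], rng)
    return np.where(ph, hap2, hap1)


def self_population_haplotypes(
    haps: np.ndarray, flip_p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Self every individual of a (n, 2, L) haplotype array once, returning
    one offspring per individual (the single-seed-descent step)."""
    ga = gamete_batch(haps[:, 0], haps[:, 1], flip_p, rng)
    gb = gamete_batch(haps[:, 0], haps[:, 1], flip_p, rng)
    return np.stack([ga, gb], axis=1)


def sample_gamete(
    parent: DiploidIndividual,
    gmap: Optional[GeneticMap] = None,
    rng: Optional[np.random.Generator] = None,
    return_detail: bool = False,
):
    """Simulate one meiosis of ``parent`` by explicit crossover events.

    Per linkage group: crossover count ~ Poisson(length/100), positions
    uniform on the group, starting parental phase a fair coin; the gamete
    carries, at every locus, the allele of the currently active parental
    haplotype.  With ``return_detail`` the total crossover count is returned
    alongside the haplotype.
    """
    gmap = parent.gmap if gmap is None else gmap
    if rng is None:
        rng = np.random.default_rng()
    if parent.hap1.shape != (gmap.n_loci,):
        raise StructuralError("parent is not defined on this map")
    out = np.empty(gmap.n_loci, dtype=np.uint8)
    n_crossovers = 0
    for g in range(gmap.n_groups):
        L = gmap.group_lengths[g]
        k = int(rng.poisson(L / 100.0))
        xo = np.sort(rng.uniform(0.0, L, size=k))
        start = int(rng.integers(0, 2))
        idx = gmap.group_loci(g)
        if idx.size:
            crossings = np.searchsorted(xo, gmap.pos_cM[idx], side="left")
            phase = (start + crossings) % 2
            out[idx] = np.where(phase == 1, parent.hap2[idx], parent.hap1[idx])
        n_crossovers += k
    if return_detail:
        return out, n_crossovers
    return out


# ---------------------------------------------------------------------------
# crossing and inbreeding
# ---------------------------------------------------------------------------


def cross(
    p1: DiploidIndividual,
    p2: DiploidIndividual,
    rng: np.random.Generator,
    id: Optional[str] = None,
) -> DiploidIndividual:
    """One offspring of p1 x p2: haplotype 1 is a gamete of p1, haplotype 2 a
    gamete of p2."""
    if p1.gmap is not p2.gmap and p1.gmap != p2.gmap:
        raise StructuralError("parents are defined on different maps")
    h1 = sample_gamete(p1, p1.gmap, rng)
    h2 = sample_gamete(p2, p2.gmap, rng)
    return DiploidIndividual(
        hap1=h1,
        hap2=h2,
        gmap=p1.gmap,
        id=id,
        pedigree={"parents": (p1.id, p2.id)},
    )


def self_(
    p: DiploidIndividual, rng: np.random.Generator, id: Optional[str] = None
) -> DiploidIndividual:
    """Self-pollinate ``p`` once (a cross of the plant with itself)."""
    return cross(p, p, rng, id=id)


def ssd_advance(
    p: DiploidIndividual, n_generations: int, rng: np.random.Generator
) -> DiploidIndividual:
    """Advance one lineage by ``n_generations`` successive single-offspring
    selfings (single-seed descent).  ``n_generations = 0`` returns the input
    unchanged."""
    if n_generations < 0:
        raise ParameterError("n_generations must be >= 0")
    ind = p
    for t in range(n_generations):
        ind = self_(ind, rng, id=f"{p.id}.s{t + 1}" if p.id else None)
    return ind


def make_initial_population(
    gmap: GeneticMap,
    n: int = 200,
    rng: Optional[np.random.Generator] = None,
    id_prefix: str = "F8",
) -> Population:
    """Build the initial inbred population of a biparental breeding study.

    A single F1, heterozygous at every locus (founder-A haplotype over
    founder-B haplotype), is selfed to give ``n`` independent F2 offspring;
    each F2 lineage is then advanced by single-seed descent through six more
    selfings to the F8 generation.  Seven meioses separate each returned line
    from the F1, so the expected residual heterozygosity per locus is 2^-7
    (about 0.78%).
    """
    if n < 2:
        raise ParameterError("initial population needs n >= 2")
    if rng is None:
        rng = np.random.default_rng()
    L = gmap.n_loci
    flip_p = gmap.flip_probs()
    f1 = np.empty((n, 2, L), dtype=np.uint8)
    f1[:, 0] = ALLELE_A
    f1[:, 1] = ALLELE_B
    haps = f1
    for _ in range(7):  # F1 -> F2, then F2 -> F8 by SSD
        haps = self_population_haplotypes(haps, flip_p, rng)
    ids = tuple(f"{id_prefix}_{i:04d}" for i in range(n))
    return Population(haplotypes=haps, gmap=gmap, ids=ids, generation="F8")
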