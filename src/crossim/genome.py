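"""Simulated genome construction: linkage maps and additive trait architectures.

The simulated species is diploid with ``n_groups`` linkage groups of equal
genetic length (in centimorgans).  A quantitative trait is controlled by
``n_qtl`` biallelic loci scattered uniformly at random over the groups; each
locus carries an additive effect whose magnitude is drawn from a gamma
distribution (a long-tailed architecture: many small effects, a few large
ones).  Effects are subsequently rescaled by a single constant so that the
genetic variance of a reference population equals one, which fixes the trait
unit for the whole study.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import DegeneratePopulationError, ParameterError, StructuralError

__all__ = [
    "GeneticMap",
    "TraitArchitecture",
    "haldane_r",
    "build_genome",
    "sample_effects",
    "scale_effects_to_unit_variance",
]


def haldane_r(d_cM):
    """Recombination fraction for a map distance ``d_cM`` (centimorgans).

    Under crossovers without interference (a Poisson process along the
    chromosome) the probability that an odd number of crossovers falls in an
    interval of length d is r = (1 - exp(-2 d / 100)) / 2, which is bounded by
    1/2 and increases monotonically with distance.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass(frozen=True, eq=False)
class GeneticMap:
    """Ordered loci on a set of linkage groups.

    Parameters
    ----------
    group_lengths
        Genetic length of each linkage group in cM; all must be positive.
    locus_ids
        One identifier per locus, unique, in map order.
    locus_group
        Integer index of the linkage group of each locus (0-based).
    pos_cM
        Position of each locus within its group, in [0, group length].
    group_names
        Optional display names for the groups (defaults to 1..n).

    Loci are stored sorted by (group, position); the constructor rejects
    unsorted input rather than silently reordering, so that locus indices are
    stable identifiers throughout the package.
    """

    group_lengths: np.ndarray
    locus_ids: tuple
    locus_group: np.ndarray
    pos_cM: np.ndarray
    group_names: Optional[tuple] = None

    def __post_init__(self):
        object.__setattr__(
            self, "group_lengths", np.asarray(self.group_lengths, dtype=float)
        )
        object.__setattr__(self, "locus_ids", tuple(self.locus_ids))
        object.__setattr__(
            self, "locus_group", np.asarray(self.locus_group, dtype=np.int64)
        )
        object.__setattr__(self, "pos_cM", np.asarray(self.pos_cM, dtype=float))
        if self.group_lengths.ndim != 1 or self.group_lengths.size < 1:
            raise ParameterError("at least one linkage group is required")
        if np.any(self.group_lengths <= 0):
            raise ParameterError("linkage group lengths must be positive")
        n = len(self.locus_ids)
        if self.locus_group.shape != (n,) or self.pos_cM.shape != (n,):
            raise StructuralError("locus arrays must have one entry per locus id")
        if len(set(self.locus_ids)) != n:
            raise StructuralError("locus ids must be unique")
        if n == 0:
            raise ParameterError("a map needs at least one locus")
        if self.locus_group.min() < 0 or self.locus_group.max() >= self.n_groups:
            raise StructuralError("locus group index out of range")
        if np.any(self.pos_cM < 0) or np.any(
            self.pos_cM > self.group_lengths[self.locus_group]
        ):
            raise StructuralError("locus positions must lie within their group")
        order_ok = np.all(np.diff(self.locus_group) >= 0)
        within = np.all(
            (np.diff(self.pos_cM) >= 0) | (np.diff(self.locus_group) > 0)
        )
        if not (order_ok and within):
            raise StructuralError("loci must be sorted by (group, position)")
        if self.group_names is not None:
            object.__setattr__(self, "group_names", tuple(self.group_names))
            if len(self.group_names) != self.n_groups:
                raise StructuralError("one name per linkage group required")

    def __eq__(self, other):
        if self is other:
            return True
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return (
            self.locus_ids == other.locus_ids
            and np.array_equal(self.group_lengths, other.group_lengths)
            and np.array_equal(self.locus_group, other.locus_group)
            and np.array_equal(self.pos_cM, other.pos_cM)
        )

    __hash__ = object.__hash__

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_groups(self) -> int:
        return int(self.group_lengths.size)

    def group_name(self, g: int):
        return self.group_names[g] if self.group_names is not None else g + 1

    def group_loci(self, g: int) -> np.ndarray:
        """Indices of the loci on group ``g`` (map order)."""
        return np.flatnonzero(self.locus_group == g)

    def flip_probs(self, locus_idx: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-locus phase-flip probabilities for gamete simulation.

        Entry j is the probability that the parental phase changes between
        locus j-1 and locus j of the (sub)map: the Haldane recombination
        fraction of the inter-locus distance, or 1/2 at the first locus of
        each linkage group (the starting phase of every group is a fair coin).

        ``locus_idx`` restricts the map to a sorted subset of loci; because a
        Poisson crossover process has independent increments, the restriction
        of meiosis to a subset of loci is governed by exactly these
        probabilities.
        """
        if locus_idx is None:
            grp = self.locus_group
            pos = self.pos_cM
        else:
            locus_idx = np.asarray(locus_idx, dtype=np.int64)
            if locus_idx.size and np.any(np.diff(locus_idx) <= 0):
                raise StructuralError("locus subset must be sorted and unique")
            grp = self.locus_group[locus_idx]
            pos = self.pos_cM[locus_idx]
        d = np.diff(pos, prepend=pos[0] if pos.size else 0.0)
        p = haldane_r(d)
        new_group = np.ones(pos.size, dtype=bool)
        if pos.size > 1:
            new_group[1:] = grp[1:] != grp[:-1]
        p[new_group] = 0.5
        return p


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive effects and favorable-allele identity for the trait loci.

    ``effects`` holds non-negative effect magnitudes (trait units per
    favorable-allele dose), one per locus of the associated map.
    ``favorable`` records which founder allele carries the positive dose at
    each locus (0 = founder A, 1 = founder B).  The genetic value of an
    individual is sum_j s_j * effect_j * code_j with s_j = +1 when the
    favorable allele is A and -1 otherwise, so the favorable homozygote always
    contributes +effect_j.
    """

    effects: np.ndarray
    favorable: np.ndarray
    scaled: bool = False

    def __post_init__(self):
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=float))
        object.__setattr__(
            self, "favorable", np.asarray(self.favorable, dtype=np.uint8)
        )
        if self.effects.ndim != 1 or self.effects.size < 1:
            raise ParameterError("effects must be a non-empty vector")
        if not np.all(np.isfinite(self.effects)) or np.any(self.effects < 0):
            raise ParameterError("effect magnitudes must be finite and >= 0")
        if self.favorable.shape != self.effects.shape:
            raise StructuralError("one favorable-allele flag per effect")
        if np.any(self.favorable > 1):
            raise StructuralError("favorable-allele flags must be 0 (A) or 1 (B)")

    @property
    def n_loci(self) -> int:
        return int(self.effects.size)

    @property
    def signed_effects(self) -> np.ndarray:
        """Effect of one extra dose of founder allele A at each locus."""
        return self.effects * (1.0 - 2.0 * self.favorable)

    @property
    def max_genetic_value(self) -> float:
        """GV of the ideal genotype, homozygous favorable everywhere."""
        return float(self.effects.sum())


def build_genome(
    n_groups: int,
    length_cM: float,
    n_qtl: int,
    rng: np.random.Generator,
) -> GeneticMap:
    """Place ``n_qtl`` trait loci uniformly at random on ``n_groups`` equal
    linkage groups of ``length_cM`` centimorgans.

    Each locus draws its group uniformly and its position uniformly on
    [0, length_cM]; loci are then sorted by (group, position) and labelled
    q0001, q0002, ... in map order.
    """
    if n_groups < 1 or n_qtl < 1:
        raise ParameterError("n_groups and n_qtl must be >= 1")
    if length_cM <= 0:
        raise ParameterError("length_cM must be positive")
    grp = rng.integers(0, n_groups, size=n_qtl)
    pos = rng.uniform(0.0, length_cM, size=n_qtl)
    order = np.lexsort((pos, grp))
    ids = tuple(f"q{i + 1:04d}" for i in range(n_qtl))
    return GeneticMap(
        group_lengths=np.full(n_groups, float(length_cM)),
        locus_ids=ids,
        locus_group=grp[order],
        pos_cM=pos[order],
    )


def sample_effects(
    n_qtl: int,
    shape: float = 0.4,
    scale: float = 1.66,
    sign_mode: str = "random",
    rng: Optional[np.random.Generator] = None,
) -> TraitArchitecture:
    """Draw unscaled effect magnitudes i.i.d. Gamma(shape, scale).

    ``sign_mode`` controls which founder allele is favorable at each locus:
    ``"random"`` (default) assigns founder A or B with probability 1/2 each,
    so both founders of a biparental population contribute favorable alleles;
    ``"all_positive"`` makes founder A favorable everywhere (the symmetric
    architecture used in classical genomic-selection simulations).
    """
    if n_qtl < 1:
        raise ParameterError("n_qtl must be >= 1")
    if shape <= 0 or scale <= 0:
        raise ParameterError("gamma shape and scale must be positive")
    if sign_mode not in ("random", "all_positive"):
        raise ParameterError(f"unknown sign_mode {sign_mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    effects = rng.gamma(shape, scale, size=n_qtl)
    if sign_mode == "random":
        favorable = rng.integers(0, 2, size=n_qtl).astype(np.uint8)
    else:
        favorable = np.zeros(n_qtl, dtype=np.uint8)
    return TraitArchitecture(effects=effects, favorable=favorable, scaled=False)


def scale_effects_to_unit_variance(
    arch: TraitArchitecture, reference_pop
) -> TraitArchitecture:
    """Rescale all effects by one constant so the reference population has
    genetic variance exactly 1.

    ``reference_pop`` is any object with a ``codes()`` method returning the
    (n individuals x n loci) genotype code matrix (+1/0/-1).  The sample
    variance (ddof=1) of the genetic values defines the genetic variance.
    Scaling is a pure rescaling: the ranking of effect magnitudes, and the
    favorable-allele assignment, are unchanged.
    """
    codes = np.asarray(reference_pop.codes(), dtype=float)
    if codes.ndim != 2 or codes.shape[1] != arch.n_loci:
        raise StructuralError("reference population does not match architecture")
    if codes.shape[0] < 2:
        raise DegeneratePopulationError(
            "genetic variance undefined for fewer than two individuals"
        )
    gv = codes @ arch.signed_effects
    var = float(np.var(gv, ddof=1))
    if var <= 0.0 or not np.isfinite(var):
        raise DegeneratePopulationError(
            "reference population has zero genetic variance (all loci fixed?)"
        )
    c = 1.0 / np.sqrt(var)
    return replace(arch, effects=arch.effects * c, scaled=True)
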