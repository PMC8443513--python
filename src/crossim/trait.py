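"""Genotype codes, genetic values and phenotypes.

The trait is purely additive: the genetic value (GV) of a plant is the sum
over loci of the signed effect times the genotype code (+1 homozygous founder
A, 0 heterozygous, -1 homozygous founder B).  Phenotypes add an environmental
deviation drawn from N(0, sigma2_e), where sigma2_e is set from the trait
heritability h2 and the (fixed) genetic variance of the initial population:

    h2 = sigma2_g / (sigma2_g + sigma2_e)   =>   sigma2_e = sigma2_g (1-h2)/h2

sigma2_e is held constant across selection cycles even as genetic variance
erodes, and environmental deviations are drawn fresh every time a population
is phenotyped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ParameterError, StructuralError
from .genome import TraitArchitecture
from .meiosis import DiploidIndividual, Population

__all__ = [
    "TraitObservation",
    "genotype_codes",
    "genetic_values",
    "environmental_variance",
    "phenotype",
    "phenotype_population",
]


@dataclass(frozen=True)
class TraitObservation:
    """One phenotyping event: genetic value, environmental deviation and
    their sum, with the heritability that generated the deviation."""

    gv: float
    env: float
    phenotype: float
    h2: float
    individual_id: Optional[str] = None


def genotype_codes(
    ind: Union[DiploidIndividual, Population],
    loci: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Genotype codes of an individual (vector) or population (matrix),
    optionally restricted to a subset of locus indices (map order)."""
    codes = ind.codes()
    if loci is None:
        return codes
    loci = np.asarray(loci, dtype=np.int64)
    if loci.size and (loci.min() < 0 or loci.max() >= codes.shape[-1]):
        raise StructuralError("locus index outside the map")
    return codes[..., loci]


def genetic_values(codes: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """GV = codes @ signed effects; accepts a single code vector or a
    (n, n_loci) matrix."""
    codes = np.asarray(codes, dtype=float)
    if codes.shape[-1] != arch.n_loci:
        raise StructuralError(
            f"code length {codes.shape[-1]} != number of effects {arch.n_loci}"
        )
    return codes @ arch.signed_effects


def environmental_variance(h2: float, sigma2_g: float = 1.0) -> float:
    """sigma2_e implied by heritability ``h2`` at genetic variance
    ``sigma2_g`` (exactly 0 when h2 == 1)."""
    if not 0.0 < h2 <= 1.0:
        raise ParameterError("heritability must be in (0, 1]")
    if sigma2_g < 0:
        raise ParameterError("genetic variance must be >= 0")
    if h2 == 1.0:
        return 0.0
    return sigma2_g * (1.0 - h2) / h2


def phenotype(
    gv: float,
    h2: float,
    sigma2_g: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    individual_id: Optional[str] = None,
) -> TraitObservation:
    """Phenotype a single plant: gv plus a fresh environmental deviation."""
    var_e = environmental_variance(h2, sigma2_g)
    if var_e == 0.0:
        env = 0.0
    else:
        if rng is None:
            rng = np.random.default_rng()
        env = float(rng.normal(0.0, np.sqrt(var_e)))
    return TraitObservation(
        gv=float(gv),
        env=env,
        phenotype=float(gv) + env,
        h2=h2,
        individual_id=individual_id,
    )


def phenotype_population(
    pop: Population,
    arch: TraitArchitecture,
    h2: float,
    rng: Optional[np.random.Generator] = None,
    sigma2_g: float = 1.0,
):
    """Phenotype every member of ``pop``.

    Returns ``(gv, phenotypes)`` as float arrays of length n; at h2 = 1 the
    two are identical.
    """
    gv = genetic_values(pop.codes(), arch)
    var_e = environmental_variance(h2, sigma2_g)
    if var_e == 0.0:
        return gv, gv.copy()
    if rng is None:
        rng = np.random.default_rng()
    env = rng.normal(0.0, np.sqrt(var_e), size=gv.shape)
    return gv, gv + env
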