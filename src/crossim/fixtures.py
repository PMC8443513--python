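"""Synthetic empirical-mode input generator.

Real deployments of the cross-ranking engine start from a genotyped panel of
recombinant inbred lines (RILs), a genetic map, and a marker-effect model
trained on the panel's phenotypes.  This module fabricates a complete,
internally consistent set of those inputs by simulation — a biparental
panel produced by an F2 generation plus single-seed descent to F8, genotyped
at a genome-wide marker set of which a small subset carries trait effects —
shaped by default like a soybean RIL panel: 194 lines, 513 mapped markers,
29 effect markers.  Everything is written as TSV so the empirical-mode CLI
runs with no external data; files are byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import numpy as np

from .errors import ParameterError
from .genome import (
    build_genome,
    sample_effects,
    scale_effects_to_unit_variance,
)
from .io import GenotypeTable, write_effects, write_genotypes, write_map, \
    write_phenotypes
from .meiosis import make_initial_population
from .prediction import TrainingData, fit_model, write_model
from .trait import environmental_variance, genetic_values

__all__ = ["generate_fixture"]


def generate_fixture(
    out_dir,
    n_lines: int = 194,
    n_markers_total: int = 513,
    n_effect_markers: int = 29,
    n_groups: int = 20,
    length_cM: float = 150.0,
    h2: float = 0.6,
    seed: int = 0,
) -> Dict[str, Path]:
    """Simulate a genotyped RIL panel and write all empirical-mode inputs.

    Writes ``map.tsv`` (all markers), ``genotypes.tsv`` (n_lines x
    n_markers_total codes), ``effects.tsv`` (true effects of the effect-marker
    subset), ``phenotypes.tsv`` (true GV + phenotype per line) and
    ``model.tsv`` (a lasso model fitted to the panel's phenotypes at the
    effect markers).  Returns a dict of paths keyed by file role.
    """
    if n_effect_markers > n_markers_total:
        raise ParameterError("n_effect_markers must be <= n_markers_total")
    if n_effect_markers < 1 or n_lines < 2:
        raise ParameterError("need >= 1 effect marker and >= 2 lines")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    gmap = build_genome(n_groups, length_cM, n_markers_total, rng)
    panel = make_initial_population(gmap, n_lines, rng, id_prefix="RIL")
    effect_idx = np.sort(
        rng.choice(n_markers_total, size=n_effect_markers, replace=False)
    )
    effect_ids = tuple(gmap.locus_ids[i] for i in effect_idx)
    arch = sample_effects(n_effect_markers, rng=rng)

    sub_codes = panel.codes()[:, effect_idx]

    class _PanelAtEffectMarkers:
        @staticmethod
        def codes():
            return sub_codes

    arch = scale_effects_to_unit_variance(arch, _PanelAtEffectMarkers)
    gv = genetic_values(sub_codes, arch)

    var_e = environmental_variance(h2, 1.0)
    phen = gv + (rng.normal(0.0, np.sqrt(var_e), size=gv.shape)
                 if var_e > 0 else 0.0)

    model = fit_model(
        TrainingData(sub_codes, phen, effect_ids),
        n_folds=min(10, n_lines),  # tiny panels still get a valid CV
        rng=rng,
    )

    paths = {
        "map": out / "map.tsv",
        "genotypes": out / "genotypes.tsv",
        "effects": out / "effects.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "model": out / "model.tsv",
    }
    write_map(gmap, paths["map"])
    write_genotypes(
        GenotypeTable(ids=panel.ids, marker_ids=gmap.locus_ids,
                      codes=panel.codes()),
        paths["genotypes"],
    )
    write_effects(arch, effect_ids, paths["effects"])
    write_phenotypes(panel.ids, phen, paths["phenotypes"], gv=gv)
    write_model(model, paths["model"])
    return paths
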