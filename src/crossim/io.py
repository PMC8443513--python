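"""Readers and writers for the package's tab-separated file formats.

All coordinates are genetic-map positions in centimorgans; genotypes are
biallelic codes (+1 homozygous founder A, 0 heterozygous, -1 homozygous
founder B) or two-letter allele calls convertible via a founder-allele key.
Floats are written with 17 significant digits so every writer/reader pair is
a lossless round-trip and identical seeds give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParseError, StructuralError
from .genome import GeneticMap, TraitArchitecture
from .meiosis import ALLELE_A, ALLELE_B, Population
from .prediction import PredictionModel, read_model, write_model  # noqa: F401
from .strategies import CrossCandidate

__all__ = [
    "GenotypeTable",
    "write_map",
    "read_map",
    "write_genotypes",
    "read_genotypes",
    "write_effects",
    "read_effects",
    "write_phenotypes",
    "write_ranking",
    "ranking_frame",
    "write_results",
    "write_population",
    "read_population",
    "write_model",
    "read_model",
    "write_run_log",
]

_F = ".17g"


def _fmt(x: float) -> str:
    return format(float(x), _F)


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


def write_map(gmap: GeneticMap, path) -> None:
    """TSV with `#group <name> <length>` header comments (one per linkage
    group, preserving group lengths) then `locus_id  group  pos_cM` rows in
    map order."""
    with open(path, "w") as fh:
        for g in range(gmap.n_groups):
            fh.write(f"#group\t{gmap.group_name(g)}\t{_fmt(gmap.group_lengths[g])}\n")
        fh.write("locus_id\tgroup\tpos_cM\n")
        for i, lid in enumerate(gmap.locus_ids):
            g = int(gmap.locus_group[i])
            fh.write(f"{lid}\t{gmap.group_name(g)}\t{_fmt(gmap.pos_cM[i])}\n")


def read_map(path) -> GeneticMap:
    """Parse a map TSV; loci are sorted by (group, position) on read.

    Group lengths come from `#group` header comments when present, otherwise
    each group's length defaults to its largest marker position (crossovers
    beyond the last marker cannot affect marker genotypes).
    """
    group_order: List[str] = []
    lengths: Dict[str, float] = {}
    records = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    data_started = False
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#group\t"):
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}: malformed #group header (line {ln})")
            name = parts[1]
            try:
                lengths[name] = float(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric group length (line {ln})"
                ) from exc
            group_order.append(name)
            continue
        if line.startswith("#"):
            continue
        if not data_started:
            if line.split("\t")[:3] != ["locus_id", "group", "pos_cM"]:
                raise ParseError(f"{path}: missing column header (line {ln})")
            data_started = True
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path}: expected 3 columns (line {ln})")
        lid, grp, pos = parts
        try:
            pos_f = float(pos)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric position (line {ln})") from exc
        if pos_f < 0:
            raise ParseError(f"{path}: negative position (line {ln})")
        records.append((lid, grp, pos_f))
    if not records:
        raise ParseError(f"{path}: no loci found")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})[0]
        raise ParseError(f"{path}: duplicate locus id {dup!r}")
    groups_seen = []
    for _, g, _ in records:
        if g not in groups_seen:
            groups_seen.append(g)
    if group_order:
        missing = [g for g in groups_seen if g not in group_order]
        if missing:
            raise ParseError(f"{path}: group {missing[0]!r} has no #group header")
        names = group_order
    else:
        def _numkey(s):
            try:
                return (0, float(s), s)
            except ValueError:
                return (1, 0.0, s)
        names = sorted(groups_seen, key=_numkey)
    gidx = {name: i for i, name in enumerate(names)}
    grp_arr = np.array([gidx[r[1]] for r in records])
    pos_arr = np.array([r[2] for r in records])
    order = np.lexsort((np.array(ids), pos_arr, grp_arr))
    glen = np.empty(len(names))
    for name, i in gidx.items():
        if name in lengths:
            glen[i] = lengths[name]
        else:
            on_g = pos_arr[grp_arr == i]
            glen[i] = max(on_g.max(), 1e-9) if on_g.size else 1.0
    return GeneticMap(
        group_lengths=glen,
        locus_ids=tuple(np.array(ids)[order]),
        locus_group=grp_arr[order],
        pos_cM=pos_arr[order],
        group_names=tuple(names),
    )


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeTable:
    """A rectangular individuals-by-markers matrix of genotype codes."""

    ids: tuple
    marker_ids: tuple
    codes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        object.__setattr__(
            self, "codes", np.asarray(self.codes, dtype=np.int8)
        )
        if self.codes.shape != (len(self.ids), len(self.marker_ids)):
            raise StructuralError("codes must be (n individuals, n markers)")
        if self.codes.size and (self.codes.min() < -1 or self.codes.max() > 1):
            raise DataError("genotype codes must be -1, 0 or +1")

    def to_population(self, gmap: GeneticMap) -> Population:
        """Rebuild haplotypes from codes for progeny simulation.

        Codes carry no phase, so heterozygous loci are assigned the arbitrary
        phase (A, B); immaterial for (near-)fully homozygous inbred lines.
        Marker columns are reordered to map order; every map locus must be
        present.
        """
        if set(self.marker_ids) != set(gmap.locus_ids):
            raise StructuralError("genotype markers do not match the map loci")
        col = {m: j for j, m in enumerate(self.marker_ids)}
        perm = np.array([col[m] for m in gmap.locus_ids])
        codes = self.codes[:, perm]
        hap1 = np.where(codes == -1, ALLELE_B, ALLELE_A).astype(np.uint8)
        hap2 = np.where(codes <= 0, ALLELE_B, ALLELE_A).astype(np.uint8)
        return Population(
            haplotypes=np.stack([hap1, hap2], axis=1),
            gmap=gmap,
            ids=self.ids,
            generation="input",
        )


def write_genotypes(table: GenotypeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\t" + "\t".join(table.marker_ids) + "\n")
        for i, iid in enumerate(table.ids):
            fh.write(
                iid + "\t" + "\t".join(str(int(c)) for c in table.codes[i]) + "\n"
            )


def read_genotypes(path, allele_key: Optional[Dict[str, str]] = None) -> GenotypeTable:
    """Read a genotype TSV (header of marker ids, first column individual id).

    Cells are -1/0/+1 codes, or two-letter allele calls (e.g. ``CT``) when
    ``allele_key`` maps each marker id to the letter that is founder allele A
    (code = dose of the founder-A letter minus one).  A missing or malformed
    cell raises a data error naming its row and column; nothing is imputed.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "individual_id":
        raise ParseError(f"{path}: malformed header (line 1)")
    markers = header[1:]
    if len(set(markers)) != len(markers):
        raise ParseError(f"{path}: duplicate marker id in header")
    ids, rows = [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise DataError(
                f"{path}: row {parts[0]!r} has {len(parts) - 1} cells, "
                f"expected {len(markers)} (line {ln})"
            )
        iid = parts[0]
        row = np.empty(len(markers), dtype=np.int8)
        for j, cell in enumerate(parts[1:]):
            cell = cell.strip()
            if not cell:
                raise DataError(
                    f"{path}: missing genotype at row {iid!r}, "
                    f"column {markers[j]!r}"
                )
            if cell in ("-1", "0", "1", "+1"):
                row[j] = int(cell)
            elif len(cell) == 2 and allele_key is not None:
                a = allele_key.get(markers[j])
                if a is None:
                    raise DataError(
                        f"{path}: no allele key for marker {markers[j]!r}"
                    )
                row[j] = cell.count(a) - 1
            else:
                raise DataError(
                    f"{path}: unreadable genotype {cell!r} at row {iid!r}, "
                    f"column {markers[j]!r}"
                )
        ids.append(iid)
        rows.append(row)
    return GenotypeTable(
        ids=tuple(ids), marker_ids=tuple(markers), codes=np.array(rows)
    )


# ---------------------------------------------------------------------------
# effects, phenotypes, rankings, results
# ---------------------------------------------------------------------------


def write_effects(arch: TraitArchitecture, locus_ids: Sequence[str], path) -> None:
    """TSV `locus_id  effect  favorable_allele` (favorable allele as A/B)."""
    if len(locus_ids) != arch.n_loci:
        raise StructuralError("one locus id per effect")
    with open(path, "w") as fh:
        fh.write("locus_id\teffect\tfavorable_allele\n")
        for lid, e, f in zip(locus_ids, arch.effects, arch.favorable):
            fh.write(f"{lid}\t{_fmt(e)}\t{'A' if f == 0 else 'B'}\n")


def read_effects(path) -> "tuple[tuple, TraitArchitecture]":
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != ["locus_id", "effect",
                                             "favorable_allele"]:
        raise ParseError(f"{path}: missing effects header (line 1)")
    ids, eff, fav = [], [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3 or parts[2] not in ("A", "B"):
            raise ParseError(f"{path}: malformed effects row (line {ln})")
        ids.append(parts[0])
        try:
            eff.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric effect (line {ln})") from exc
        fav.append(0 if parts[2] == "A" else 1)
    return tuple(ids), TraitArchitecture(
        effects=np.array(eff), favorable=np.array(fav, dtype=np.uint8)
    )


def write_phenotypes(ids: Sequence[str], phenotypes: np.ndarray, path,
                     gv: Optional[np.ndarray] = None) -> None:
    """TSV `individual_id  [gv]  phenotype` (gv column only when known)."""
    with open(path, "w") as fh:
        if gv is None:
            fh.write("individual_id\tphenotype\n")
            for iid, p in zip(ids, phenotypes):
                fh.write(f"{iid}\t{_fmt(p)}\n")
        else:
            fh.write("individual_id\tgv\tphenotype\n")
            for iid, g, p in zip(ids, gv, phenotypes):
                fh.write(f"{iid}\t{_fmt(g)}\t{_fmt(p)}\n")


def ranking_frame(candidates: Sequence[CrossCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [c.rank for c in candidates],
            "parent1": [c.parent1_id for c in candidates],
            "parent2": [c.parent2_id for c in candidates],
            "score": [c.score for c in candidates],
            "progeny_variance": [c.progeny_pv_variance for c in candidates],
            "n_simulated": [c.n_simulated for c in candidates],
        }
    )


def write_ranking(candidates: Sequence[CrossCandidate], path) -> None:
    """TSV `rank  parent1  parent2  score  progeny_variance  n_simulated`,
    best cross first."""
    with open(path, "w") as fh:
        fh.write("rank\tparent1\tparent2\tscore\tprogeny_variance\tn_simulated\n")
        for c in candidates:
            fh.write(
                f"{c.rank}\t{c.parent1_id}\t{c.parent2_id}\t{_fmt(c.score)}"
                f"\t{_fmt(c.progeny_pv_variance)}\t{c.n_simulated}\n"
            )


def write_results(table: pd.DataFrame, path) -> None:
    """Long-format benchmark metric table as TSV."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# populations (lossless haplotype round-trip)
# ---------------------------------------------------------------------------


def write_population(pop: Population, codes_path, haplotypes_path) -> None:
    """Coded-genotype TSV plus a companion haplotype TSV (two rows per
    individual, A/B letters) for a lossless round-trip."""
    table = GenotypeTable(
        ids=pop.ids, marker_ids=pop.gmap.locus_ids, codes=pop.codes()
    )
    write_genotypes(table, codes_path)
    with open(haplotypes_path, "w") as fh:
        fh.write("individual_id\thap\t" + "\t".join(pop.gmap.locus_ids) + "\n")
        for i, iid in enumerate(pop.ids):
            for h in (0, 1):
                alleles = "\t".join(
                    "A" if a == ALLELE_A else "B"
                    for a in pop.haplotypes[i, h]
                )
                fh.write(f"{iid}\t{h + 1}\t{alleles}\n")


def read_population(haplotypes_path, gmap: GeneticMap,
                    generation: str = "") -> Population:
    with open(haplotypes_path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{haplotypes_path}: empty haplotype file")
    header = lines[0].split("\t")
    if header[:2] != ["individual_id", "hap"]:
        raise ParseError(f"{haplotypes_path}: malformed header (line 1)")
    if tuple(header[2:]) != gmap.locus_ids:
        raise StructuralError(
            f"{haplotypes_path}: locus columns do not match the map"
        )
    haps: Dict[str, dict] = {}
    order: List[str] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header) or parts[1] not in ("1", "2"):
            raise ParseError(f"{haplotypes_path}: malformed row (line {ln})")
        iid = parts[0]
        try:
            vec = np.array(
                [ALLELE_A if a == "A" else ALLELE_B if a == "B" else -1
                 for a in parts[2:]],
                dtype=np.int16,
            )
        except ValueError as exc:  # pragma: no cover - defensive
            raise ParseError(f"{haplotypes_path}: bad allele (line {ln})") from exc
        if (vec < 0).any():
            raise ParseError(
                f"{haplotypes_path}: allele letters must be A/B (line {ln})"
            )
        if iid not in haps:
            haps[iid] = {}
            order.append(iid)
        haps[iid][parts[1]] = vec.astype(np.uint8)
    arr = []
    for iid in order:
        if set(haps[iid]) != {"1", "2"}:
            raise ParseError(
                f"{haplotypes_path}: individual {iid!r} needs exactly two "
                "haplotype rows"
            )
        arr.append(np.stack([haps[iid]["1"], haps[iid]["2"]]))
    return Population(
        haplotypes=np.stack(arr), gmap=gmap, ids=tuple(order),
        generation=generation,
    )


def write_run_log(path, **entries) -> None:
    """Structured JSON run log (seed, parameters, versions)."""
    from . import __version__

    payload = {"crossim_version": __version__}
    payload.update(entries)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
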