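"""Data model and TSV readers/writers for hemizygous microsatellite cohorts.

The package works on single X chromosomes: every record is one hemizygous
haplotype (one fragment-length allele per marker), labelled ``disease`` when
it carries the disease mutation and ``control`` otherwise.  Physical marker
positions (Mb) are converted to recombination fractions against the mutation
locus with the 1 Mb ~ 1 cM rule, theta = |Mb distance| * 0.01, clamped to
[0, 0.5].  At the sub-centimorgan distances typical of an Xq28 founder region
the Haldane and Kosambi map functions are indistinguishable from this linear
rule, so no map function is applied.

File dialect: UTF-8, tab-separated, ``#`` comment lines permitted, ``NA``
marks a missing allele.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

MISSING = "NA"
GROUPS = ("disease", "control")


class CohortFormatError(ValueError):
    """Raised when a marker map or chromosome table file is malformed."""


@dataclass(frozen=True)
class Marker:
    """A microsatellite marker on chromosome X.

    Parameters
    ----------
    name : unique marker label (e.g. ``DXS1108``).
    position_mb : physical position in megabases, > 0.
    xq_band : optional cytogenetic band.
    repeat_unit : optional repeat motif (e.g. ``CA``).
    allele_range_bp : optional (min, max) observed fragment lengths in bp.
    """

    name: str
    position_mb: float
    xq_band: str | None = None
    repeat_unit: str | None = None
    allele_range_bp: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.position_mb > 0:
            raise ValueError(f"marker {self.name}: position_mb must be > 0")


@dataclass(frozen=True)
class MarkerMap:
    """Ordered flanking markers plus the position of the disease mutation.

    Markers are stored sorted by physical position.  Recombination fractions
    to the mutation (``theta``) are always derived from positions, never
    stored, so the two can not drift apart.
    """

    markers: tuple[Marker, ...]
    mutation_position_mb: float

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names in map")
        if not self.mutation_position_mb > 0:
            raise ValueError("mutation_position_mb must be > 0")
        ordered = tuple(sorted(self.markers, key=lambda m: m.position_mb))
        object.__setattr__(self, "markers", ordered)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    @property
    def theta(self) -> np.ndarray:
        """Per-marker recombination fraction to the mutation (1 Mb ~ 1 cM)."""
        pos = np.array([m.position_mb for m in self.markers])
        return np.clip(np.abs(pos - self.mutation_position_mb) * 0.01, 0.0, 0.5)

    def theta_of(self, name: str) -> float:
        return float(self.theta[self.index_of(name)])

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def __len__(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class ChromosomeRecord:
    """One hemizygous chromosome: per-marker fragment lengths in bp.

    ``alleles`` follows the marker order of the associated map; ``None``
    marks a failed/missing genotype.
    """

    sample_id: str
    family_id: str
    group: str
    alleles: tuple[int | None, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def complete(self) -> bool:
        return all(a is not None for a in self.alleles)


@dataclass(frozen=True)
class ChromosomeTable:
    """A cohort of hemizygous chromosomes genotyped on a shared marker map."""

    map: MarkerMap
    records: tuple[ChromosomeRecord, ...]

    def __post_init__(self) -> None:
        m = len(self.map)
        for rec in self.records:
            if len(rec.alleles) != m:
                raise ValueError(
                    f"record {rec.sample_id}: {len(rec.alleles)} alleles, "
                    f"map has {m} markers"
                )

    @property
    def n_disease(self) -> int:
        return sum(r.group == "disease" for r in self.records)

    @property
    def n_control(self) -> int:
        return sum(r.group == "control" for r in self.records)

    def subset(self, group: str) -> tuple[ChromosomeRecord, ...]:
        return tuple(r for r in self.records if r.group == group)

    def alleles_at(self, marker: str, group: str) -> list[int]:
        """Non-missing alleles at one marker within one group (pairwise deletion)."""
        idx = self.map.index_of(marker)
        return [
            r.alleles[idx]
            for r in self.subset(group)
            if r.alleles[idx] is not None
        ]


def one_per_family(records: Iterable[ChromosomeRecord]) -> tuple[ChromosomeRecord, ...]:
    """Keep the first chromosome per family (unrelated index cases only).

    Related patients share the founder haplotype trivially, so only one
    chromosome per family is informative; extras are dropped with a warning.
    """
    seen: dict[str, ChromosomeRecord] = {}
    extras = 0
    for rec in records:
        if rec.family_id in seen:
            extras += 1
        else:
            seen[rec.family_id] = rec
    if extras:
        logger.warning("dropped %d related chromosomes (same family_id)", extras)
    return tuple(seen.values())


def unrelated_disease(table: ChromosomeTable) -> tuple[ChromosomeRecord, ...]:
    """Disease chromosomes restricted to one per family."""
    return one_per_family(table.subset("disease"))


# ---------------------------------------------------------------------------
# readers


def _rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            yield lineno, [cell.strip() for cell in row]


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a tab-separated marker map.

    Required columns: ``name``, ``position_mb``; optional metadata columns
    ``xq_band``, ``repeat_unit``, ``allele_min_bp``, ``allele_max_bp`` and a
    ``role`` column in which exactly one row, the mutation locus, carries the
    value ``mutation``.
    """
    rows = iter(_rows(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise CohortFormatError(f"{path}: empty file") from None
    col = {name: i for i, name in enumerate(header)}
    for required in ("name", "position_mb"):
        if required not in col:
            raise CohortFormatError(f"{path}: missing column {required!r}")

    def get(row: list[str], name: str) -> str | None:
        i = col.get(name)
        if i is None or i >= len(row) or row[i] in ("", MISSING):
            return None
        return row[i]

    markers: list[Marker] = []
    mutation_pos: float | None = None
    for lineno, row in rows:
        name = get(row, "name")
        pos_s = get(row, "position_mb")
        if name is None or pos_s is None:
            raise CohortFormatError(f"{path}:{lineno}: missing name or position")
        try:
            pos = float(pos_s)
        except ValueError:
            raise CohortFormatError(
                f"{path}:{lineno}: non-numeric position {pos_s!r}"
            ) from None
        if get(row, "role") == "mutation":
            if mutation_pos is not None:
                raise CohortFormatError(f"{path}:{lineno}: duplicate mutation row")
            mutation_pos = pos
            continue
        lo, hi = get(row, "allele_min_bp"), get(row, "allele_max_bp")
        markers.append(
            Marker(
                name=name,
                position_mb=pos,
                xq_band=get(row, "xq_band"),
                repeat_unit=get(row, "repeat_unit"),
                allele_range_bp=(int(lo), int(hi)) if lo and hi else None,
            )
        )
    if mutation_pos is None:
        raise CohortFormatError(f"{path}: no row with role=mutation")
    if len({m.name for m in markers}) != len(markers):
        raise CohortFormatError(f"{path}: duplicate marker names")
    return MarkerMap(markers=tuple(markers), mutation_position_mb=mutation_pos)


def _parse_allele(cell: str, path: str | Path, lineno: int) -> int | None:
    if cell in ("", MISSING):
        return None
    try:
        return int(cell)
    except ValueError:
        raise CohortFormatError(
            f"{path}:{lineno}: non-integer allele {cell!r}"
        ) from None


def read_chromosomes(path: str | Path, marker_map: MarkerMap) -> ChromosomeTable:
    """Read a tab-separated chromosome table validated against ``marker_map``.

    Columns: ``sample_id``, ``family_id``, ``group`` then one bp-integer
    column per marker (``NA`` = missing).  Records with every allele missing
    are rejected with a logged count.
    """
    rows = iter(_rows(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise CohortFormatError(f"{path}: empty file") from None
    expected = ["sample_id", "family_id", "group", *marker_map.names]
    if header != expected:
        raise CohortFormatError(
            f"{path}: header {header} does not match map; expected {expected}"
        )
    records: list[ChromosomeRecord] = []
    n_all_missing = 0
    for lineno, row in rows:
        if len(row) != len(expected):
            raise CohortFormatError(
                f"{path}:{lineno}: {len(row)} columns, expected {len(expected)}"
            )
        sample_id, family_id, group = row[:3]
        if group not in GROUPS:
            raise CohortFormatError(f"{path}:{lineno}: unknown group {group!r}")
        alleles = tuple(_parse_allele(c, path, lineno) for c in row[3:])
        if all(a is None for a in alleles):
            n_all_missing += 1
            continue
        records.append(
            ChromosomeRecord(
                sample_id=sample_id, family_id=family_id, group=group, alleles=alleles
            )
        )
    if n_all_missing:
        logger.warning("rejected %d all-missing records in %s", n_all_missing, path)
    return ChromosomeTable(map=marker_map, records=tuple(records))


def read_linkage_ped(path: str | Path, marker_map: MarkerMap) -> ChromosomeTable:
    """Import pre-phased LINKAGE/PED-style rows (two columns per marker).

    Only the first allele column per marker is used — the rows are assumed
    pre-phased hemizygous — and the second is ignored with a warning.
    Affection status 2 maps to ``disease``, anything else to ``control``.
    """
    warnings.warn(
        "PED import ignores the second allele column per marker (hemizygous input)",
        stacklevel=2,
    )
    records: list[ChromosomeRecord] = []
    m = len(marker_map)
    for lineno, row in _rows(path):
        if len(row) != 6 + 2 * m:
            raise CohortFormatError(
                f"{path}:{lineno}: expected {6 + 2 * m} columns, got {len(row)}"
            )
        fam, ind, _pat, _mat, _sex, pheno = row[:6]
        alleles = tuple(
            _parse_allele(row[6 + 2 * i], path, lineno) for i in range(m)
        )
        group = "disease" if pheno == "2" else "control"
        records.append(
            ChromosomeRecord(sample_id=ind, family_id=fam, group=group, alleles=alleles)
        )
    return ChromosomeTable(map=marker_map, records=tuple(records))


# ---------------------------------------------------------------------------
# writers


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "name\txq_band\tposition_mb\trepeat_unit\tallele_min_bp\tallele_max_bp\trole\n"
        )
        rows = [
            (
                m.name,
                m.xq_band or MISSING,
                f"{m.position_mb:g}",
                m.repeat_unit or MISSING,
                str(m.allele_range_bp[0]) if m.allele_range_bp else MISSING,
                str(m.allele_range_bp[1]) if m.allele_range_bp else MISSING,
                "marker",
            )
            for m in marker_map.markers
        ]
        rows.append(
            (
                "mutation",
                MISSING,
                f"{marker_map.mutation_position_mb:g}",
                MISSING,
                MISSING,
                MISSING,
                "mutation",
            )
        )
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path


def write_chromosomes(table: ChromosomeTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["sample_id", "family_id", "group", *table.map.names]) + "\n")
        for rec in table.records:
            cells = [rec.sample_id, rec.family_id, rec.group]
            cells += [MISSING if a is None else str(a) for a in rec.alleles]
            fh.write("\t".join(cells) + "\n")
    return path


def write_report_tables(results, path: str | Path, kind: str | None = None) -> list[Path]:
    """Write stage outputs as tab-separated report tables under ``path``.

    Dispatches on result type: haplotype summaries, association rows,
    linkage results and age estimates each get their own TSV mirroring the
    familiar table layouts (3 decimals for proportions and delta, 2 decimals
    for LOD and generations).  Returns the list of written files.  For an
    empty result list the type is ambiguous, so ``kind`` must name the stage
    ("association", "linkage" or "ages") and header-only files are written.
    """
    # imported here to keep io free of analysis-module dependencies at import
    from .haplotypes import HaplotypeSummary
    from .association import AlleleAssociation, write_association_table
    from .linkage import LinkageResult, write_linkage_table
    from .age import AgeEstimate, write_age_table
    from .haplotypes import write_haplotype_table

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    items = results if isinstance(results, (list, tuple)) else [results]

    def all_are(cls) -> bool:
        return bool(items) and all(isinstance(x, cls) for x in items)

    if not items and kind is None:
        raise TypeError("empty results: pass kind= to choose the table layout")
    if kind is not None and not items:
        if kind == "association":
            written.append(write_association_table([], outdir / "association.tsv"))
        elif kind == "linkage":
            written += write_linkage_table([], outdir)
        elif kind == "ages":
            written.append(write_age_table([], outdir / "ages.tsv"))
        else:
            raise ValueError(f"unknown report kind {kind!r}")
        return written
    if isinstance(results, HaplotypeSummary):
        written.append(write_haplotype_table(results, outdir / "haplotypes.tsv"))
    elif all_are(AlleleAssociation):
        written.append(write_association_table(items, outdir / "association.tsv"))
    elif all_are(LinkageResult):
        written += write_linkage_table(items, outdir)
    elif all_are(AgeEstimate):
        written.append(write_age_table(items, outdir / "ages.tsv"))
    else:
        raise TypeError(f"cannot write report for {type(results).__name__}")
    return written
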