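"""End-to-end orchestration: haplotypes -> association -> LOD -> age.

``run_all`` executes the full founder-effect analysis on a chromosome table
and marker map, writes one report TSV per stage plus a run manifest
(input digests, package version, parameters, seed), and aborts with the
failing stage named if any stage errors.  Re-running on identical inputs
reproduces every output byte except the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

from . import __version__
from .age import DemographicModel, age_table, write_age_table
from .association import association_table, fisher_exact, write_association_table
from .haplotypes import (
    carriage_contingency,
    group_haplotypes,
    infer_ancestral,
    write_haplotype_table,
)
from .io import read_chromosomes, read_marker_map
from .linkage import linkage_table, write_linkage_table

logger = logging.getLogger(__name__)

DEFAULT_CLUSTERS: tuple[tuple[str, ...], ...] = (("STR24", "STR22", "STR13"),)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(
    chrom_paths: Sequence[str | Path] | str | Path,
    map_path: str | Path,
    out_dir: str | Path,
    demo: DemographicModel | None = None,
    clusters: Sequence[Sequence[str]] = DEFAULT_CLUSTERS,
    seed: int = 0,
) -> dict:
    """Run every stage on the cohort and write report tables + manifest.

    ``chrom_paths`` may be a single chromosome TSV or several (e.g. disease
    and control files split); they are concatenated onto the shared map.
    Returns a dict of stage results and written paths.
    """
    if isinstance(chrom_paths, (str, Path)):
        chrom_paths = [chrom_paths]
    demo = demo or DemographicModel(r=0.03)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    marker_map = stage("read_map", read_marker_map, map_path)
    tables = [
        stage("read_chromosomes", read_chromosomes, p, marker_map)
        for p in chrom_paths
    ]
    from .io import ChromosomeTable

    records = tuple(r for t in tables for r in t.records)
    table = ChromosomeTable(map=marker_map, records=records)
    logger.info(
        "cohort: %d disease, %d control chromosomes", table.n_disease, table.n_control
    )
    if table.n_disease == 0:
        raise StageError("stage 'haplotypes' failed: no disease chromosomes")
    if table.n_control == 0:
        raise StageError("stage 'association' failed: no control chromosomes")

    ancestral = stage("haplotypes", infer_ancestral, table)
    summary = stage("haplotypes", group_haplotypes, table, ancestral)
    labels = {h.label for h, _, _ in summary.haplotypes}
    contingency = carriage_contingency(summary, table, labels)
    fisher_p = fisher_exact(contingency)

    assoc = stage("association", association_table, table, ancestral, seed=seed)
    linkage = stage("linkage", linkage_table, table, ancestral, clusters)
    ages = stage("age", age_table, assoc, marker_map, demo)

    written = [write_haplotype_table(summary, out_dir / "haplotypes.tsv")]
    written.append(write_association_table(assoc, out_dir / "association.tsv"))
    written += write_linkage_table(linkage, out_dir)
    written.append(write_age_table(ages, out_dir / "ages.tsv"))

    manifest = {
        "package": "founderage",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": {str(p): _digest(p) for p in [*chrom_paths, map_path]},
        "seed": seed,
        "demography": dataclasses.asdict(demo),
        "clusters": [list(c) for c in clusters],
        "n_disease": table.n_disease,
        "n_control": table.n_control,
        "carriage_fisher_p": fisher_p,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    written.append(manifest_path)

    return {
        "table": table,
        "ancestral": ancestral,
        "haplotypes": summary,
        "carriage": contingency,
        "carriage_fisher_p": fisher_p,
        "association": assoc,
        "linkage": linkage,
        "ages": ages,
        "paths": written,
    }
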