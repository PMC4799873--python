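"""Packaged cohort fixture: the Xq28 founder-region marker map, 24 disease
chromosomes (one per unrelated hemophilia A family carrying F8 c.6046C>T)
and 96 control chromosomes.

The disease table expands the study's haplotype frequency table into
per-chromosome records.  The control table is SYNTHETIC: full control
haplotypes were never published, so the packaged rows are a deterministic
expansion consistent with the reported per-marker control allele counts and
with zero carriage of any disease-associated haplotype; see the file header.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import ChromosomeTable, MarkerMap, read_chromosomes, read_marker_map

_DATA = resources.files("founderage") / "data"


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(_DATA / name))


def load_marker_map() -> MarkerMap:
    """The six-marker Xq28 map with the mutation at 154.13 Mb."""
    return read_marker_map(fixture_path("marker_map.tsv"))


def load_cohort() -> ChromosomeTable:
    """Disease (24) plus control (96) chromosomes on the packaged map."""
    marker_map = load_marker_map()
    disease = read_chromosomes(fixture_path("disease_chromosomes.tsv"), marker_map)
    control = read_chromosomes(fixture_path("control_chromosomes.tsv"), marker_map)
    return ChromosomeTable(
        map=marker_map, records=disease.records + control.records
    )
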