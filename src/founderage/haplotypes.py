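"""Ancestral-haplotype inference and haplotype grouping on disease chromosomes.

In a founder population the disease chromosomes descend from a single founder
and still share most of the founder's marker alleles.  The ancestral (core)
haplotype is estimated as the marker-wise modal allele over the unrelated
disease chromosomes; chromosomes are then grouped into distinct haplotypes,
labelled H1, H2, ... by descending carrier count, and classified by how many
markers they mismatch against the ancestral estimate.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ChromosomeTable, unrelated_disease

logger = logging.getLogger(__name__)


class NoCompleteDiseaseChromosomes(ValueError):
    """No disease chromosome has a complete genotype."""


@dataclass(frozen=True)
class Haplotype:
    """An allele vector over the map's markers, optionally labelled."""

    alleles: tuple[int, ...]
    label: str | None = None

    def mismatches(self, other: "Haplotype") -> int:
        if len(self.alleles) != len(other.alleles):
            raise ValueError("haplotypes defined over different maps")
        return sum(a != b for a, b in zip(self.alleles, other.alleles))


@dataclass(frozen=True)
class HaplotypeSummary:
    """Grouped disease haplotypes with counts and ancestral classification.

    ``haplotypes`` holds (haplotype, count, frequency) triples in label order;
    ``mismatch_counts`` gives, per haplotype, the number of markers differing
    from the ancestral estimate.  Frequencies are over complete, unrelated
    disease chromosomes and sum to 1.
    """

    haplotypes: tuple[tuple[Haplotype, int, float], ...]
    ancestral: Haplotype
    mismatch_counts: tuple[int, ...]

    @property
    def n_chromosomes(self) -> int:
        return sum(c for _, c, _ in self.haplotypes)

    def by_label(self, label: str) -> Haplotype:
        for h, _, _ in self.haplotypes:
            if h.label == label:
                return h
        raise KeyError(f"unknown haplotype label {label!r}")


def _complete_disease(table: ChromosomeTable):
    recs = [r for r in unrelated_disease(table) if r.complete]
    dropped = len(unrelated_disease(table)) - len(recs)
    if dropped:
        logger.warning("excluded %d disease chromosomes with missing alleles", dropped)
    return recs


def infer_ancestral(table: ChromosomeTable) -> Haplotype:
    """Marker-wise modal allele over complete, unrelated disease chromosomes.

    Ties at a marker are broken toward the smallest fragment length, a
    deterministic and reportable rule.
    """
    recs = _complete_disease(table)
    if not recs:
        raise NoCompleteDiseaseChromosomes(
            "ancestral inference needs at least one complete disease chromosome"
        )
    alleles = []
    for i in range(len(table.map)):
        counts = Counter(r.alleles[i] for r in recs)
        top = max(counts.values())
        alleles.append(min(a for a, c in counts.items() if c == top))
    return Haplotype(alleles=tuple(alleles))


def group_haplotypes(table: ChromosomeTable, ancestral: Haplotype) -> HaplotypeSummary:
    """Group identical disease haplotypes and label them by descending count.

    Label order is descending count then lexicographic allele vector, so
    labels are invariant to record order.  Chromosomes with any missing
    allele cannot be assigned a haplotype and are excluded (logged).
    """
    if len(ancestral.alleles) != len(table.map):
        raise ValueError("ancestral haplotype does not match the table's map")
    recs = _complete_disease(table)
    counts = Counter(r.alleles for r in recs)
    n = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    haplotypes = []
    mismatches = []
    for rank, (alleles, count) in enumerate(ordered, start=1):
        h = Haplotype(alleles=alleles, label=f"H{rank}")
        haplotypes.append((h, count, count / n))
        mismatches.append(h.mismatches(ancestral))
    return HaplotypeSummary(
        haplotypes=tuple(haplotypes),
        ancestral=ancestral,
        mismatch_counts=tuple(mismatches),
    )


def carriage_contingency(
    summary: HaplotypeSummary,
    controls: ChromosomeTable,
    which: set[str] | frozenset[str],
) -> np.ndarray:
    """2x2 carriage table for a set of haplotype labels.

    Rows: disease / control chromosomes; columns: carries / does-not-carry
    any haplotype in ``which``.  A control with missing alleles cannot match
    a complete haplotype and counts as a non-carrier.  (Fisher's exact test
    is invariant to transposing this table.)
    """
    known = {h.label for h, _, _ in summary.haplotypes}
    unknown = set(which) - known
    if unknown:
        raise KeyError(f"unknown haplotype labels: {sorted(unknown)}")
    target = {
        h.alleles for h, _, _ in summary.haplotypes if h.label in which
    }
    d_carry = sum(c for h, c, _ in summary.haplotypes if h.label in which)
    d_total = summary.n_chromosomes
    c_recs = controls.subset("control")
    c_carry = sum(1 for r in c_recs if r.complete and r.alleles in target)
    return np.array(
        [[d_carry, d_total - d_carry], [c_carry, len(c_recs) - c_carry]], dtype=int
    )


def write_haplotype_table(summary: HaplotypeSummary, path: str | Path) -> Path:
    """Write the grouped haplotypes as a TSV (one row per haplotype)."""
    path = Path(path)
    n = summary.n_chromosomes
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("haplotype\talleles\tcount\tn\tfrequency\tmismatches_vs_ancestral\n")
        for (h, count, freq), mm in zip(summary.haplotypes, summary.mismatch_counts):
            alleles = ",".join(str(a) for a in h.alleles)
            fh.write(f"{h.label}\t{alleles}\t{count}\t{n}\t{freq:.3f}\t{mm}\n")
    return path
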