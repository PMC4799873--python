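"""Two-point LOD linkage between the mutation and each marker or cluster.

Unrelated disease chromosomes are treated as meioses from the founder:
a chromosome carrying the ancestral allele at a marker is scored
nonrecombinant (NR), any other allele recombinant (R).  The two-point LOD is

    LOD(theta) = NR*log10(1-theta) + R*log10(theta) + (NR+R)*log10(2),

the log10 likelihood ratio against free recombination (theta = 0.5).  This
founder-chromosome scoring is a deliberate simplification of a pedigree
likelihood: it ignores allele sharing by state and within-lineage genealogy,
but is the standard desk calculation for founder cohorts of unrelated
hemizygotes.  LOD > 3 is conventional evidence for linkage, LOD < -2
evidence against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .haplotypes import Haplotype
from .io import ChromosomeTable, unrelated_disease

#: conventional significance thresholds for two-point linkage
LOD_LINKAGE_THRESHOLD = 3.0
LOD_EXCLUSION_THRESHOLD = -2.0

#: reporting grid for LOD curves
THETA_GRID = tuple(np.round(np.arange(0.01, 0.501, 0.01), 2))


@dataclass(frozen=True)
class LinkageResult:
    locus: str
    NR: int
    R: int
    theta_max: float
    lod_max: float
    lod_curve: tuple[tuple[float, float], ...]


def count_recombinants(
    table: ChromosomeTable, ancestral: Haplotype, marker: str
) -> tuple[int, int]:
    """(NR, R) over unrelated disease chromosomes non-missing at ``marker``."""
    idx = table.map.index_of(marker)
    alleles = [
        r.alleles[idx] for r in unrelated_disease(table) if r.alleles[idx] is not None
    ]
    nr = sum(a == ancestral.alleles[idx] for a in alleles)
    return nr, len(alleles) - nr


def lod(NR: int, R: int, theta: float) -> float:
    """Two-point LOD at recombination fraction ``theta``.

    Exactly 0 at theta = 0.5; -inf at theta = 0 with observed recombinants
    (an impossible observation under complete linkage); NR*log10(2) at
    theta = 0 with none.
    """
    if NR < 0 or R < 0:
        raise ValueError("NR and R must be non-negative")
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    if theta == 0.5:
        return 0.0
    if theta == 0.0:
        return -math.inf if R > 0 else NR * math.log10(2.0)
    return (
        NR * math.log10(1.0 - theta)
        + R * math.log10(theta)
        + (NR + R) * math.log10(2.0)
    )


def maximize_lod(NR: int, R: int, locus: str = "") -> LinkageResult:
    """Maximum-likelihood theta and peak LOD for one locus.

    The MLE is analytic: theta_max = R/(NR+R) (the binomial recombination
    proportion), clamped to [0, 0.5]; the LOD is strictly concave in theta on
    (0, 0.5) so the clamp is exact.  The curve is reported on a 0.01 grid.
    """
    n = NR + R
    if n <= 0:
        raise ValueError("need at least one informative chromosome")
    theta_max = min(R / n, 0.5) if R > 0 else 0.0
    curve = tuple((float(t), lod(NR, R, float(t))) for t in THETA_GRID)
    return LinkageResult(
        locus=locus,
        NR=NR,
        R=R,
        theta_max=theta_max,
        lod_max=lod(NR, R, theta_max),
        lod_curve=curve,
    )


def cluster_lod(results: Sequence[LinkageResult], label: str | None = None) -> LinkageResult:
    """Joint LOD for a marker cluster treated as one locus.

    The cluster score is the sum of member LOD curves maximised at a shared
    theta.  Summing the curves is algebraically identical to pooling counts:
    sum_i LOD_i(theta) = LOD(sum NR_i, sum R_i, theta), so the shared optimum
    is theta* = sum(R)/sum(NR+R) and, for identical members, the cluster
    maximum is members x the single-marker maximum.
    """
    if not results:
        raise ValueError("empty cluster")
    if len(results) == 1 and label is None:
        return results[0]
    nr = sum(r.NR for r in results)
    r_ = sum(r.R for r in results)
    name = label or "/".join(r.locus for r in results)
    return maximize_lod(nr, r_, locus=name)


def linkage_table(
    table: ChromosomeTable,
    ancestral: Haplotype,
    clusters: Sequence[Sequence[str]] = (),
) -> list[LinkageResult]:
    """Per-marker linkage results, with optional marker clusters appended.

    Markers absorbed into a cluster are reported only as the cluster row,
    mirroring the convention of treating tightly linked intragenic markers
    as a single locus.
    """
    clustered = {m for c in clusters for m in c}
    out = [
        maximize_lod(*count_recombinants(table, ancestral, m), locus=m)
        for m in table.map.names
        if m not in clustered
    ]
    for members in clusters:
        parts = [
            maximize_lod(*count_recombinants(table, ancestral, m), locus=m)
            for m in members
        ]
        out.append(cluster_lod(parts))
    return out


def write_linkage_table(results: Sequence[LinkageResult], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    summary = outdir / "linkage.tsv"
    curves = outdir / "lod_curves.tsv"
    with open(summary, "w", encoding="utf-8") as fh:
        fh.write("locus\tNR\tR\ttheta_max\tlod_max\n")
        for r in results:
            fh.write(f"{r.locus}\t{r.NR}\t{r.R}\t{r.theta_max:.2f}\t{r.lod_max:.2f}\n")
    with open(curves, "w", encoding="utf-8") as fh:
        fh.write("locus\ttheta\tlod\n")
        for r in results:
            for t, z in r.lod_curve:
                fh.write(f"{r.locus}\t{t:.2f}\t{z:.2f}\n")
    return [summary, curves]
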