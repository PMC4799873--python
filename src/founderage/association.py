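"""Per-marker allelic association between the mutation and marker alleles.

For each marker the allele contributed by the ancestral haplotype is compared
between disease (mutation-bearing) and normal chromosomes: a two-sided Z-test
on the difference in proportions with a Wald 95% confidence interval, a
Fisher exact test, and the Bengtsson–Thomson linkage-disequilibrium statistic

    delta = (p_D - p_N) / (1 - p_N),

the excess of the associated allele on disease chromosomes normalised by its
room to increase; delta = 1 under complete association (p_D = 1) and can be
negative when the allele is rarer on disease chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .haplotypes import Haplotype
from .io import ChromosomeTable, unrelated_disease

Z_95 = 1.96  # Wald interval critical value


class DeltaUndefinedError(ZeroDivisionError):
    """delta is undefined when the allele is fixed on normal chromosomes."""


@dataclass(frozen=True)
class AlleleAssociation:
    """Association statistics for one marker allele.

    ``k_D``/``n_D`` and ``k_N``/``n_N`` are carrier counts over disease and
    normal chromosomes (pairwise deletion of missing genotypes); ``delta`` is
    the Bengtsson–Thomson statistic; ``delta_ci`` is a bootstrap percentile
    interval (the analytic Wald interval applies to ``delta_p`` only).
    """

    marker: str
    allele: int
    k_D: int
    n_D: int
    k_N: int
    n_N: int
    delta_p: float
    ci_low: float
    ci_high: float
    p_value: float
    delta: float
    delta_ci_low: float | None = None
    delta_ci_high: float | None = None

    @property
    def p_D(self) -> float:
        return self.k_D / self.n_D

    @property
    def p_N(self) -> float:
        return self.k_N / self.n_N


def allele_proportions(
    table: ChromosomeTable, marker: str, allele: int
) -> tuple[int, int, int, int]:
    """Carrier counts (k_D, n_D, k_N, n_N) for one marker allele.

    Denominators count chromosomes with a non-missing genotype at the marker;
    disease chromosomes are restricted to one per family.
    """
    idx = table.map.index_of(marker)
    disease = [
        r.alleles[idx] for r in unrelated_disease(table) if r.alleles[idx] is not None
    ]
    control = table.alleles_at(marker, "control")
    return (
        sum(a == allele for a in disease),
        len(disease),
        sum(a == allele for a in control),
        len(control),
    )


def diff_proportions_test(
    k_D: int, n_D: int, k_N: int, n_N: int
) -> tuple[float, float, float, float]:
    """Two-sided Z-test on p_D - p_N with a Wald 95% CI.

    Returns (delta_p, ci_low, ci_high, p_value).  The standard error is the
    unpooled Wald form sqrt(p_D(1-p_D)/n_D + p_N(1-p_N)/n_N) with z = 1.96
    and no continuity correction.
    """
    if n_D <= 0 or n_N <= 0:
        raise ZeroDivisionError("both groups need at least one chromosome")
    p_D, p_N = k_D / n_D, k_N / n_N
    delta_p = p_D - p_N
    se = np.sqrt(p_D * (1 - p_D) / n_D + p_N * (1 - p_N) / n_N)
    if se == 0.0:
        p_value = 1.0 if delta_p == 0.0 else 0.0
    else:
        p_value = float(2.0 * stats.norm.sf(abs(delta_p) / se))
    return delta_p, delta_p - Z_95 * se, delta_p + Z_95 * se, p_value


def bt_delta(k_D: int, n_D: int, k_N: int, n_N: int) -> float:
    """Bengtsson–Thomson delta = (p_D - p_N)/(1 - p_N) from exact counts."""
    if n_D <= 0 or n_N <= 0:
        raise ZeroDivisionError("both groups need at least one chromosome")
    p_D, p_N = k_D / n_D, k_N / n_N
    if p_N == 1.0:
        raise DeltaUndefinedError(
            "delta undefined: allele fixed on normal chromosomes (p_N = 1)"
        )
    return (p_D - p_N) / (1.0 - p_N)


def fisher_exact(table2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Uses the minimum-likelihood convention: the sum over all tables with the
    observed margins whose hypergeometric point probability does not exceed
    that of the observed table.  Alternative two-sided conventions (doubling
    the smaller tail) give different values and are not used here.
    """
    arr = np.asarray(table2x2, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("negative cell counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins (zero row or column total)")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def bootstrap_delta_ci(
    k_D: int,
    n_D: int,
    k_N: int,
    n_N: int,
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Nonparametric bootstrap percentile CI for delta.

    Chromosomes are resampled with replacement within each group, which for a
    single marker is a binomial resample of the carrier count.  Resamples
    with p_N = 1 (delta undefined) are dropped.
    """
    rng = np.random.default_rng(seed)
    kd = rng.binomial(n_D, k_D / n_D, size=n_boot)
    kn = rng.binomial(n_N, k_N / n_N, size=n_boot)
    ok = kn < n_N
    pd_, pn = kd[ok] / n_D, kn[ok] / n_N
    deltas = (pd_ - pn) / (1.0 - pn)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(deltas, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def association_table(
    table: ChromosomeTable,
    ancestral: Haplotype,
    n_boot: int = 10_000,
    seed: int = 0,
) -> list[AlleleAssociation]:
    """One association row per marker, using the ancestral allele at each.

    No multiple-testing correction is applied across markers; the six tests
    are reported marker-wise as-is.
    """
    if len(ancestral.alleles) != len(table.map):
        raise ValueError("ancestral haplotype does not match the table's map")
    out: list[AlleleAssociation] = []
    for i, marker in enumerate(table.map.names):
        allele = ancestral.alleles[i]
        k_D, n_D, k_N, n_N = allele_proportions(table, marker, allele)
        delta_p, lo, hi, p = diff_proportions_test(k_D, n_D, k_N, n_N)
        delta = bt_delta(k_D, n_D, k_N, n_N)
        d_lo, d_hi = bootstrap_delta_ci(
            k_D, n_D, k_N, n_N, n_boot=n_boot, seed=seed + i
        )
        out.append(
            AlleleAssociation(
                marker=marker,
                allele=allele,
                k_D=k_D,
                n_D=n_D,
                k_N=k_N,
                n_N=n_N,
                delta_p=delta_p,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
                delta=delta,
                delta_ci_low=d_lo,
                delta_ci_high=d_hi,
            )
        )
    return out


def write_association_table(
    rows: Sequence[AlleleAssociation], path: str | Path
) -> Path:
    path = Path(path)
    cols = (
        "marker\tallele\tk_D\tn_D\tp_D\tk_N\tn_N\tp_N\t"
        "delta_p\tci_low\tci_high\tp_value\tdelta\tdelta_ci_low\tdelta_ci_high\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(cols)
        for r in rows:
            dlo = "NA" if r.delta_ci_low is None else f"{r.delta_ci_low:.3f}"
            dhi = "NA" if r.delta_ci_high is None else f"{r.delta_ci_high:.3f}"
            fh.write(
                f"{r.marker}\t{r.allele}\t{r.k_D}\t{r.n_D}\t{r.p_D:.3f}\t"
                f"{r.k_N}\t{r.n_N}\t{r.p_N:.3f}\t{r.delta_p:.3f}\t"
                f"{r.ci_low:.3f}\t{r.ci_high:.3f}\t{r.p_value:.3g}\t"
                f"{r.delta:.3f}\t{dlo}\t{dhi}\n"
            )
    return path
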