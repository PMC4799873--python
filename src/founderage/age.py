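"""Moment-based allele-age estimation with demographic calibration.

Under single-founder decay the expected linkage disequilibrium after g
generations of recombination at fraction theta per generation is
delta = (1 - theta)^g, giving the moment estimator

    g_hat = log(delta) / log(1 - theta).

Because the mutation-bearing lineage grew exponentially, most extant copies
are recent and g_hat underestimates the true age.  The Luria–Delbrück-style
growth correction adds

    g_corr = -(1/r) * ln(theta * f * r),   with the product f*r taken as 1/r,

i.e. g_corr = -(1/r) * ln(theta/r), where r is the per-generation exponential
growth rate of the population.  The corrected age is the sum of the two
terms; both are reported separately so the correction can be audited.

Demographic calibrators: r = ln(T1/T0)/g from two census sizes g generations
apart, and the sampled fraction f of mutation-bearing chromosomes from the
male population size, disease incidence and the share of disease due to the
mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .association import AlleleAssociation
from .io import MarkerMap


class AgeUndefinedError(ValueError):
    """The moment estimator is undefined for delta <= 0."""


@dataclass(frozen=True)
class DemographicModel:
    """Exponential population growth between two census points.

    Either supply (T0, T1, g_demo) — sizes at the two ends of a span of
    g_demo generations — and r is derived as ln(T1/T0)/g_demo, or supply r
    directly.  Supplying both is accepted only when consistent.
    """

    T0: float | None = None
    T1: float | None = None
    g_demo: float | None = None
    r: float | None = None
    years_per_generation: float = 25.0

    def __post_init__(self) -> None:
        if self.years_per_generation <= 0:
            raise ValueError("years_per_generation must be > 0")
        census = (self.T0, self.T1, self.g_demo)
        if all(v is not None for v in census):
            derived = growth_rate(self.T0, self.T1, self.g_demo)
            if self.r is None:
                object.__setattr__(self, "r", derived)
            elif not math.isclose(self.r, derived, rel_tol=1e-6, abs_tol=1e-9):
                raise ValueError(
                    f"r={self.r} inconsistent with ln(T1/T0)/g_demo={derived:.6g}"
                )
        elif self.r is None:
            raise ValueError("supply either r or all of (T0, T1, g_demo)")


@dataclass(frozen=True)
class SamplingModel:
    """Ascertainment model for the fraction of mutant chromosomes sampled."""

    male_population: float
    disease_incidence: float
    mutation_fraction: float
    sampled_chromosomes: int

    def __post_init__(self) -> None:
        if min(self.male_population, self.disease_incidence, self.mutation_fraction) <= 0:
            raise ValueError("population, incidence and mutation fraction must be > 0")
        if self.sampled_chromosomes < 0:
            raise ValueError("sampled_chromosomes must be >= 0")

    @property
    def f(self) -> float:
        return sampled_fraction(self)


@dataclass(frozen=True)
class AgeEstimate:
    """Age decomposition for one marker: g_total = g_uncorrected + correction."""

    marker: str
    theta: float
    delta: float
    g_uncorrected: float
    correction: float
    years_per_generation: float = 25.0

    @property
    def g_total(self) -> float:
        return self.g_uncorrected + self.correction

    @property
    def years(self) -> float:
        return generations_to_years(self.g_total, self.years_per_generation)


def growth_rate(T0: float, T1: float, g_demo: float) -> float:
    """Per-generation exponential growth rate r from T1 = T0 * e^(g*r)."""
    if T0 <= 0 or T1 <= 0 or g_demo <= 0:
        raise ValueError("T0, T1 and g_demo must be > 0")
    return math.log(T1 / T0) / g_demo


def sampled_fraction(model: SamplingModel) -> float:
    """Fraction f of existing mutation-bearing chromosomes in the sample."""
    total = model.male_population * model.disease_incidence * model.mutation_fraction
    f = model.sampled_chromosomes / total
    if f > 1.0:
        raise ValueError(
            f"sampled fraction {f:.3g} > 1: more chromosomes sampled than estimated to exist"
        )
    return f


def moment_age(delta: float, theta: float) -> float:
    """Uncorrected moment age g_hat = log(delta)/log(1 - theta) in generations.

    Base-invariant (a ratio of logarithms); 0 at delta = 1.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    if delta <= 0.0:
        raise AgeUndefinedError(f"moment age undefined for delta={delta} <= 0")
    if delta > 1.0:
        raise ValueError("delta must be <= 1")
    return math.log(delta) / math.log(1.0 - theta)


def luria_delbruck_correction(theta: float, r: float) -> float:
    """Growth correction -(1/r)*ln(theta/r) in generations."""
    if theta <= 0 or r <= 0:
        raise ValueError("theta and r must be > 0")
    return -math.log(theta / r) / r


def generations_to_years(g: float, years_per_generation: float = 25.0) -> float:
    if years_per_generation <= 0:
        raise ValueError("years_per_generation must be > 0")
    return g * years_per_generation


def corrected_age(
    assoc: AlleleAssociation, marker_map: MarkerMap, demo: DemographicModel
) -> AgeEstimate:
    """Corrected age at one marker from its exact-count delta and map theta.

    delta is taken as the exact count ratio carried by ``assoc``, not a
    rounded rendition.
    """
    theta = marker_map.theta_of(assoc.marker)
    g_unc = moment_age(assoc.delta, theta)
    corr = luria_delbruck_correction(theta, demo.r)
    return AgeEstimate(
        marker=assoc.marker,
        theta=theta,
        delta=assoc.delta,
        g_uncorrected=g_unc,
        correction=corr,
        years_per_generation=demo.years_per_generation,
    )


def age_table(
    assocs: Sequence[AlleleAssociation],
    marker_map: MarkerMap,
    demo: DemographicModel,
) -> list[AgeEstimate]:
    """Corrected age at every marker with a defined (positive) delta.

    No marker-exclusion rule is applied: estimates are produced for all
    markers, including tightly linked ones where the correction term
    dominates; interpretation is left to the report reader.
    """
    out = []
    for a in assocs:
        if a.delta <= 0:
            continue
        out.append(corrected_age(a, marker_map, demo))
    return out


def write_age_table(rows: Sequence[AgeEstimate], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "marker\ttheta\tdelta\tg_uncorrected\tld_correction\tg_total\tyears\n"
        )
        for r in rows:
            fh.write(
                f"{r.marker}\t{r.theta:.4f}\t{r.delta:.3f}\t{r.g_uncorrected:.2f}\t"
                f"{r.correction:.2f}\t{r.g_total:.2f}\t{r.years:.0f}\n"
            )
    return path
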