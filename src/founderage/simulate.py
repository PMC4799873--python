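"""Forward-time simulation of a founder haplotype and validation experiments.

The generator emulates the data-generating process the age estimators assume:
a single founder chromosome carrying the mutation, a supercritical branching
process in which each mutation-bearing chromosome leaves Poisson(e^r) copies
per generation (conditioned on survival to the present by restarting extinct
runs), and per-meiosis recombination against a background allele pool.

Two recombination models are available:

``per_marker_independent``
    each transmitted marker allele is independently replaced with
    probability theta_m by a draw from the background spectrum — exactly the
    per-generation decay the moment estimator inverts, so the expected
    founder-allele retention after g generations is (1 - theta_m)^g;
``haldane_map``
    crossover points are placed by a Poisson process on a genetic map scaled
    so the marginal probability of an odd crossover count between the
    mutation and marker m is exactly theta_m (inverse Haldane distance
    d_m = -ln(1 - 2*theta_m)/2 Morgans); alleles distal to an odd number of
    crossovers are replaced from a background chromosome, so replacement is
    correlated along each flank.

Control chromosomes are drawn i.i.d. from the background spectra
(linkage equilibrium).  On top of the simulator sit a parameter-recovery
experiment for the moment estimators and a rejection-ABC posterior over the
mutation age, a likelihood-free analogue of MCMC-based allele-age inference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from . import age as age_mod
from .association import allele_proportions, bt_delta
from .haplotypes import Haplotype, infer_ancestral
from .io import ChromosomeRecord, ChromosomeTable, MarkerMap

logger = logging.getLogger(__name__)

RecombModel = Literal["per_marker_independent", "haldane_map"]


class LineageExtinctError(RuntimeError):
    """The mutation-bearing lineage died out in every restart attempt."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic founder cohort.

    ``background_freqs`` is one allele->probability mapping per marker (map
    order), each summing to 1.  ``g`` is the true age in generations and
    ``r`` the per-generation exponential growth rate of the lineage.
    ``max_population`` is a carrying capacity: once the lineage exceeds it,
    a uniform random subset of that size is kept.  Subsampling chromosomes
    does not alter any per-lineage recombination probability, so founder-
    allele retention stays (1-theta)^g; it only bounds memory and time for
    large g.  ``mutation_rate`` adds optional stepwise slippage (one repeat
    unit up or down per event) per marker per meiosis, default off.
    """

    map: MarkerMap
    founder_haplotype: Haplotype
    background_freqs: tuple[dict[int, float], ...]
    g: int
    r: float
    n_disease_sample: int
    n_control_sample: int
    seed: int
    recomb_model: RecombModel = "per_marker_independent"
    max_population: int = 10_000
    max_restarts: int = 1000
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if self.n_disease_sample < 1 or self.n_control_sample < 1:
            raise ValueError("sample sizes must be >= 1")
        if len(self.background_freqs) != len(self.map):
            raise ValueError("one background spectrum per marker required")
        if len(self.founder_haplotype.alleles) != len(self.map):
            raise ValueError("founder haplotype does not match the map")
        for i, spectrum in enumerate(self.background_freqs):
            total = sum(spectrum.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"background spectrum for marker {self.map.names[i]} sums to {total}"
                )


@dataclass(frozen=True)
class SimResult:
    table: ChromosomeTable
    true_g: int
    lineage_count_trajectory: tuple[int, ...]
    seed: int
    restarts: int = 0


def background_freqs_from_table(table: ChromosomeTable) -> tuple[dict[int, float], ...]:
    """Empirical per-marker allele spectra from the control chromosomes."""
    out = []
    for marker in table.map.names:
        alleles = table.alleles_at(marker, "control")
        if not alleles:
            raise ValueError(f"no control genotypes at {marker}")
        n = len(alleles)
        spectrum = {}
        for a in sorted(set(alleles)):
            spectrum[a] = alleles.count(a) / n
        out.append(spectrum)
    return tuple(out)


def _spectrum_arrays(config: SimConfig):
    alleles = [np.array(sorted(s)) for s in config.background_freqs]
    probs = [
        np.array([s[a] for a in sorted(s)]) for s in config.background_freqs
    ]
    return alleles, probs


def _draw_background(
    rng: np.random.Generator, alleles, probs, n: int, m: int
) -> np.ndarray:
    pool = np.empty((n, m), dtype=np.int64)
    for j in range(m):
        pool[:, j] = rng.choice(alleles[j], size=n, p=probs[j])
    return pool


def _recombine_independent(
    rng: np.random.Generator, pop: np.ndarray, theta: np.ndarray, alleles, probs
) -> np.ndarray:
    mask = rng.random(pop.shape) < theta
    for j in range(pop.shape[1]):
        k = int(mask[:, j].sum())
        if k:
            pop[mask[:, j], j] = rng.choice(alleles[j], size=k, p=probs[j])
    return pop


def _recombine_haldane(
    rng: np.random.Generator,
    pop: np.ndarray,
    theta: np.ndarray,
    positions: np.ndarray,
    mutation_pos: float,
    alleles,
    probs,
) -> np.ndarray:
    """Crossover-process recombination with P(odd count to marker m) = theta_m.

    Genetic distances use the inverse Haldane transform of theta, so marker
    intervals on each flank receive independent Poisson crossover counts and
    the parity to each marker is the parity of the partial sums.
    """
    n, m = pop.shape
    with np.errstate(divide="ignore"):
        d = -0.5 * np.log1p(-2.0 * theta)  # Morgans; inf at theta=0.5
    d = np.minimum(d, 50.0)  # parity is a fair coin far beyond ~10 Morgans
    background = _draw_background(rng, alleles, probs, n, m)
    for side in (positions < mutation_pos, positions > mutation_pos):
        idx = np.nonzero(side)[0]
        if idx.size == 0:
            continue
        order = idx[np.argsort(d[idx])]  # proximal to distal on this flank
        seg = np.diff(np.concatenate([[0.0], d[order]]))
        counts = rng.poisson(seg, size=(n, order.size))
        odd = (np.cumsum(counts, axis=1) % 2).astype(bool)
        for k, j in enumerate(order):
            pop[odd[:, k], j] = background[odd[:, k], j]
    return pop


def _slippage(
    rng: np.random.Generator, pop: np.ndarray, config: SimConfig
) -> np.ndarray:
    if config.mutation_rate <= 0:
        return pop
    steps = np.array(
        [
            len(m.repeat_unit) if m.repeat_unit else 2
            for m in config.map.markers
        ]
    )
    mask = rng.random(pop.shape) < config.mutation_rate
    direction = rng.choice([-1, 1], size=pop.shape)
    pop[mask] += (direction * steps)[mask]
    return pop


def simulate_cohort(config: SimConfig) -> SimResult:
    """Simulate one synthetic cohort; bit-identical for identical configs.

    The founder lineage is grown for ``g`` generations; runs that go extinct
    are restarted (the observed mutation is ascertained as extant today) up
    to ``max_restarts`` times, all from the same seeded stream so the result
    remains a deterministic function of the config.
    """
    rng = np.random.default_rng(config.seed)
    theta = config.map.theta
    positions = np.array([m.position_mb for m in config.map.markers])
    alleles, probs = _spectrum_arrays(config)
    m = len(config.map)
    founder = np.array(config.founder_haplotype.alleles, dtype=np.int64)
    mean_offspring = math.exp(config.r)

    too_small = 0
    for restart in range(config.max_restarts + 1):
        pop = founder[None, :].copy()
        trajectory = [1]
        extinct = False
        for _ in range(config.g):
            counts = rng.poisson(mean_offspring, size=pop.shape[0])
            total = int(counts.sum())
            if total == 0:
                extinct = True
                break
            pop = np.repeat(pop, counts, axis=0)
            if total > config.max_population:
                keep = rng.choice(total, size=config.max_population, replace=False)
                pop = pop[keep]
            if config.recomb_model == "per_marker_independent":
                pop = _recombine_independent(rng, pop, theta, alleles, probs)
            elif config.recomb_model == "haldane_map":
                pop = _recombine_haldane(
                    rng, pop, theta, positions, config.map.mutation_position_mb,
                    alleles, probs,
                )
            else:
                raise ValueError(f"unknown recomb_model {config.recomb_model!r}")
            pop = _slippage(rng, pop, config)
            trajectory.append(total)
        if not extinct:
            if pop.shape[0] >= config.n_disease_sample:
                break
            # survived but smaller than the sample: the real cohort was
            # ascertained as having at least n sampled carriers, so this
            # outcome is conditioned away like extinction
            too_small += 1
    else:
        if too_small and too_small >= config.max_restarts // 2:
            raise ValueError(
                f"disease sample ({config.n_disease_sample}) exceeds the "
                f"present-day lineage size in {too_small} of "
                f"{config.max_restarts + 1} attempts; increase g or r, or "
                f"shrink the sample"
            )
        raise LineageExtinctError(
            f"lineage extinct in all {config.max_restarts + 1} attempts"
        )
    if restart:
        logger.debug("lineage survived after %d restarts", restart)
    pick = rng.choice(pop.shape[0], size=config.n_disease_sample, replace=False)
    disease = pop[np.sort(pick)]
    controls = _draw_background(rng, alleles, probs, config.n_control_sample, m)

    records = [
        ChromosomeRecord(
            sample_id=f"simD{i:04d}",
            family_id=f"simDF{i:04d}",
            group="disease",
            alleles=tuple(int(a) for a in row),
        )
        for i, row in enumerate(disease, 1)
    ]
    records += [
        ChromosomeRecord(
            sample_id=f"simC{i:04d}",
            family_id=f"simCF{i:04d}",
            group="control",
            alleles=tuple(int(a) for a in row),
        )
        for i, row in enumerate(controls, 1)
    ]
    return SimResult(
        table=ChromosomeTable(map=config.map, records=tuple(records)),
        true_g=config.g,
        lineage_count_trajectory=tuple(trajectory),
        seed=config.seed,
        restarts=restart,
    )


def substream_seed(seed: int, k: int) -> int:
    """Derived seed for replicate k: SeedSequence([seed, k]), 31-bit."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def delta_hat(table: ChromosomeTable, reference: Haplotype) -> np.ndarray:
    """Per-marker Bengtsson–Thomson delta of the reference allele; NaN if p_N=1."""
    out = np.empty(len(table.map))
    for i, marker in enumerate(table.map.names):
        k_D, n_D, k_N, n_N = allele_proportions(table, marker, reference.alleles[i])
        if k_N == n_N:
            out[i] = np.nan
        else:
            out[i] = bt_delta(k_D, n_D, k_N, n_N)
    return out


@dataclass(frozen=True)
class RecoveryResult:
    """Replicate-level age estimates against the known simulated age."""

    true_g: int
    estimator: str
    estimates: tuple[float, ...]
    n_excluded: int

    @property
    def bias(self) -> float:
        return float(np.mean(self.estimates)) - self.true_g

    @property
    def rmse(self) -> float:
        e = np.asarray(self.estimates)
        return float(np.sqrt(np.mean((e - self.true_g) ** 2)))

    @property
    def median(self) -> float:
        return float(np.median(self.estimates))

    @property
    def empirical_interval(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.estimates, [0.025, 0.975])
        return float(lo), float(hi)


def recovery_experiment(
    config: SimConfig,
    n_reps: int,
    estimator: Literal["moment", "corrected"] = "moment",
) -> RecoveryResult:
    """Repeatedly simulate, re-estimate the age end-to-end, and summarise.

    Each replicate runs the full analysis path: ancestral haplotype inferred
    from the simulated disease sample, per-marker delta from the simulated
    case/control counts, then the moment (optionally growth-corrected)
    estimator averaged over markers with a defined positive delta.
    Replicates in which no marker yields a usable delta are excluded and
    counted.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    theta = config.map.theta
    estimates: list[float] = []
    excluded = 0
    for k in range(n_reps):
        sim = simulate_cohort(replace(config, seed=substream_seed(config.seed, k)))
        ancestral = infer_ancestral(sim.table)
        deltas = delta_hat(sim.table, ancestral)
        per_marker = []
        for d, t in zip(deltas, theta):
            if not np.isfinite(d) or d <= 0:
                continue
            if d >= 1.0:
                g_hat = 0.0  # complete LD: no decay observed at any theta
            elif t <= 0:
                continue
            else:
                g_hat = age_mod.moment_age(d, t)
            if estimator == "corrected" and t > 0:
                g_hat += age_mod.luria_delbruck_correction(t, config.r)
            per_marker.append(g_hat)
        if not per_marker:
            excluded += 1
            continue
        estimates.append(float(np.mean(per_marker)))
    if excluded:
        logger.warning("%d/%d replicates excluded (no defined delta)", excluded, n_reps)
    return RecoveryResult(
        true_g=config.g,
        estimator=estimator,
        estimates=tuple(estimates),
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class ABCResult:
    """Rejection-ABC posterior over a grid of candidate ages."""

    g_grid: tuple[int, ...]
    weights: tuple[float, ...]
    n_accepted: int
    ci_low: float
    ci_high: float

    @property
    def posterior_mean(self) -> float:
        return float(np.dot(self.g_grid, self.weights))

    @property
    def posterior_mode(self) -> int:
        return self.g_grid[int(np.argmax(self.weights))]


def abc_posterior(
    observed: ChromosomeTable,
    config_template: SimConfig,
    g_grid: Sequence[int],
    n_sims_per_g: int,
    tolerance: float,
    credible_level: float = 0.95,
) -> ABCResult:
    """Likelihood-free posterior over the mutation age.

    Uniform prior over ``g_grid``; a simulation at candidate age g is
    accepted when the Euclidean distance between its per-marker delta vector
    and the observed one is at most ``tolerance``.  The summary statistic
    uses the template's founder haplotype as the reference allele in both
    the observed and the simulated cohorts, keeping the comparison symmetric
    and deterministic.  Markers with undefined delta (allele fixed in
    controls) contribute delta = 1 to the distance in both vectors.
    """
    if not g_grid:
        raise ValueError("empty age grid")
    obs = np.nan_to_num(delta_hat(observed, config_template.founder_haplotype), nan=1.0)
    accepted = np.zeros(len(g_grid), dtype=int)
    for gi, g in enumerate(g_grid):
        for k in range(n_sims_per_g):
            seed = substream_seed(config_template.seed, gi * n_sims_per_g + k)
            sim = simulate_cohort(replace(config_template, g=int(g), seed=seed))
            sim_delta = np.nan_to_num(
                delta_hat(sim.table, config_template.founder_haplotype), nan=1.0
            )
            if np.linalg.norm(sim_delta - obs) <= tolerance:
                accepted[gi] += 1
    total = int(accepted.sum())
    if total == 0:
        raise RuntimeError(
            "no simulations accepted: increase the tolerance, the number of "
            "simulations per grid point, or widen the grid"
        )
    weights = accepted / total
    alpha = (1.0 - credible_level) / 2.0
    cum = np.cumsum(weights)
    grid = np.asarray(g_grid, dtype=float)
    ci_low = float(grid[np.searchsorted(cum, alpha)])
    ci_high = float(grid[np.searchsorted(cum, 1.0 - alpha)])
    return ABCResult(
        g_grid=tuple(int(g) for g in g_grid),
        weights=tuple(float(w) for w in weights),
        n_accepted=total,
        ci_low=ci_low,
        ci_high=ci_high,
    )
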