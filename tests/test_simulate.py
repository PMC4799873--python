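"""Forward-time founder simulator: determinism, retention, recovery, ABC."""

import numpy as np
import pytest

from founderage.haplotypes import Haplotype
from founderage.io import Marker, MarkerMap
from founderage.simulate import (
    LineageExtinctError,
    SimConfig,
    abc_posterior,
    background_freqs_from_table,
    delta_hat,
    recovery_experiment,
    simulate_cohort,
    substream_seed,
)


def make_map(offsets_mb):
    """Markers at given Mb offsets from a mutation at 100 Mb."""
    markers = tuple(
        Marker(f"M{i}", 100.0 + off) for i, off in enumerate(offsets_mb)
    )
    return MarkerMap(markers=markers, mutation_position_mb=100.0)


def make_config(offsets_mb, g, r, n_d=24, n_c=48, seed=0, background=None, **kw):
    m = make_map(offsets_mb)
    n = len(offsets_mb)
    founder = Haplotype(alleles=tuple([100] * n))
    # founder allele at 20% in the background, rest spread over two others
    freqs = tuple(background or {100: 0.2, 102: 0.5, 104: 0.3} for _ in range(n))
    return SimConfig(
        map=m,
        founder_haplotype=founder,
        background_freqs=freqs,
        g=g,
        r=r,
        n_disease_sample=n_d,
        n_control_sample=n_c,
        seed=seed,
        **kw,
    )


class TestSimulateCohort:
    def test_bit_identical_for_identical_config(self):
        cfg = make_config([0.5, 2.0], g=30, r=0.2, seed=11)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.table.records == b.table.records
        assert a.lineage_count_trajectory == b.lineage_count_trajectory

    def test_no_recombination_preserves_founder(self):
        cfg = make_config([0.0, 0.0], g=40, r=0.2, seed=3)
        res = simulate_cohort(cfg)
        for rec in res.table.subset("disease"):
            assert rec.alleles == cfg.founder_haplotype.alleles
        d = delta_hat(res.table, cfg.founder_haplotype)
        assert np.allclose(d, 1.0)

    def test_age_zero_yields_founder_copies(self):
        cfg = make_config([1.0], g=0, r=0.2, n_d=1, seed=5)
        res = simulate_cohort(cfg)
        assert all(
            rec.alleles == cfg.founder_haplotype.alleles
            for rec in res.table.subset("disease")
        )
        assert res.lineage_count_trajectory == (1,)

    def test_trajectory_starts_at_single_founder(self):
        res = simulate_cohort(make_config([1.0], g=25, r=0.2, seed=1))
        assert res.lineage_count_trajectory[0] == 1
        assert len(res.lineage_count_trajectory) == 26

    def test_sample_larger_than_lineage_rejected(self):
        cfg = make_config([1.0], g=1, r=0.05, n_d=10_000, seed=2, max_restarts=10)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_cohort(cfg)

    def test_extinction_reported_after_max_restarts(self):
        cfg = make_config([1.0], g=60, r=-3.0, seed=4, max_restarts=3)
        with pytest.raises(LineageExtinctError, match="4 attempts"):
            simulate_cohort(cfg)

    def test_retention_matches_closed_form(self):
        """Mean founder-allele retention across replicates sits within 3 MC
        standard errors of (1-theta)^g under per-marker recombination.
        The background excludes the founder allele so allele identity means
        identity-by-descent."""
        theta, g, reps, n = 0.02, 25, 60, 100
        expected = (1 - theta) ** g
        fractions = []
        for k in range(reps):
            cfg = make_config(
                [theta * 100], g=g, r=0.25, n_d=n,
                seed=substream_seed(123, k), max_population=2000,
                background={102: 0.6, 104: 0.4},
            )
            res = simulate_cohort(cfg)
            vals = [rec.alleles[0] for rec in res.table.subset("disease")]
            fractions.append(np.mean([v == 100 for v in vals]))
        se = np.std(fractions, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(fractions) - expected) < 3 * se + 1e-9

    def test_haldane_and_independent_single_marker_agree(self):
        """The crossover-process model is calibrated so the marginal odd-
        crossover probability equals theta; single-marker retention must
        match the per-marker model within Monte Carlo error."""
        means = {}
        for model in ("per_marker_independent", "haldane_map"):
            fractions = []
            for k in range(40):
                cfg = make_config(
                    [3.0], g=15, r=0.3, n_d=100,
                    seed=substream_seed(9, k), recomb_model=model,
                    max_population=2000,
                )
                res = simulate_cohort(cfg)
                vals = [r.alleles[0] for r in res.table.subset("disease")]
                fractions.append(np.mean([v == 100 for v in vals]))
            means[model] = (np.mean(fractions), np.std(fractions, ddof=1) / np.sqrt(40))
        (m1, s1), (m2, s2) = means.values()
        assert abs(m1 - m2) < 3 * np.hypot(s1, s2)

    def test_controls_reproduce_background_spectrum(self):
        cfg = make_config([1.0], g=12, r=0.3, n_c=3000, seed=8)
        res = simulate_cohort(cfg)
        vals = np.array([r.alleles[0] for r in res.table.subset("control")])
        for allele, p in cfg.background_freqs[0].items():
            phat = np.mean(vals == allele)
            se = np.sqrt(p * (1 - p) / len(vals))
            assert abs(phat - p) < 4 * se

    def test_background_spectra_fitted_from_controls(self, cohort):
        freqs = background_freqs_from_table(cohort)
        assert len(freqs) == 6
        assert freqs[5][171] == pytest.approx(29 / 96)
        for spectrum in freqs:
            assert sum(spectrum.values()) == pytest.approx(1.0, abs=1e-9)


class TestRecoveryExperiment:
    def test_zero_theta_markers_estimate_zero(self):
        cfg = make_config([0.0], g=30, r=0.2, seed=21)
        res = recovery_experiment(cfg, n_reps=5)
        assert res.estimates == (0.0,) * 5
        assert res.n_excluded == 0

    def test_median_recovers_true_age(self):
        """Moment estimator recovers g=25 within 20% in the median over
        replicates when the founder allele is absent from the background."""
        m = make_map([2.0])
        cfg = SimConfig(
            map=m,
            founder_haplotype=Haplotype(alleles=(100,)),
            background_freqs=({102: 0.6, 104: 0.4},),
            g=25,
            r=0.3,
            n_disease_sample=100,
            n_control_sample=100,
            seed=42,
            max_population=2000,
        )
        res = recovery_experiment(cfg, n_reps=40)
        assert abs(res.median - 25) / 25 < 0.2

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            recovery_experiment(make_config([1.0], g=5, r=0.3), n_reps=1)


class TestAbcPosterior:
    def test_point_grid_gives_unit_weight(self):
        cfg = make_config([1.5], g=20, r=0.3, seed=31, max_population=500)
        observed = simulate_cohort(cfg).table
        res = abc_posterior(observed, cfg, [20], n_sims_per_g=20, tolerance=np.inf)
        assert res.weights == (1.0,)
        assert res.ci_low == res.ci_high == 20

    def test_infinite_tolerance_is_uniform(self):
        cfg = make_config([1.5], g=20, r=0.3, seed=32, max_population=500)
        observed = simulate_cohort(cfg).table
        grid = [10, 20, 30, 40]
        res = abc_posterior(observed, cfg, grid, n_sims_per_g=25, tolerance=np.inf)
        assert res.n_accepted == 100
        assert res.weights == (0.25,) * 4

    def test_zero_acceptance_raises_with_advice(self):
        cfg = make_config([1.5], g=20, r=0.3, seed=33, max_population=500)
        observed = simulate_cohort(cfg).table
        # delta-hat is a coarse discrete statistic, so exact ties can occur
        # even at tolerance 0; an unsatisfiable tolerance guarantees rejection
        with pytest.raises(RuntimeError, match="tolerance"):
            abc_posterior(observed, cfg, [20], n_sims_per_g=5, tolerance=-1.0)

    def test_self_consistency_interval_contains_truth(self):
        cfg = make_config(
            [1.0, 3.0], g=40, r=0.25, n_d=24, n_c=48, seed=34, max_population=400
        )
        observed = simulate_cohort(cfg).table
        res = abc_posterior(
            observed, cfg, list(range(10, 101, 10)), n_sims_per_g=60, tolerance=0.2
        )
        assert res.ci_low <= 40 <= res.ci_high


class TestSubstreams:
    def test_derived_seeds_distinct_and_stable(self):
        seeds = [substream_seed(7, k) for k in range(100)]
        assert len(set(seeds)) == 100
        assert seeds == [substream_seed(7, k) for k in range(100)]
        assert all(0 <= s < 2**31 for s in seeds)
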