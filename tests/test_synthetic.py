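import dataclasses
import math

import numpy as np
import pytest

from atabridge.assay_data import Competitor
from atabridge.synthetic import (
    SimulationConfig,
    Species,
    SpeciesLevels,
    analytic_titer_log5,
    default_competition_spec,
    free_fraction,
    simulate_animal,
    simulate_signal,
    simulate_study,
)
from atabridge.titration import DilutionScheme, build_dilution_series, interpolate_titer


class TestFreeFraction:
    def test_full_length_cannot_block_anti_hinge(self):
        assert free_fraction(Species.HINGE, Competitor.FULL_LENGTH, 50.0) == 1.0

    def test_control_fab2_cannot_block_anti_cdr(self):
        assert free_fraction(Species.CDR, Competitor.CONTROL_FAB2, 50.0) == 1.0

    def test_half_inhibition_at_ic50(self):
        spec = default_competition_spec(ic50_ug_ml=2.0)
        assert free_fraction(Species.CDR, Competitor.DRUG_FAB2, 2.0, spec) == pytest.approx(0.5)

    def test_framework_blocked_by_all_three_with_asymptote(self):
        for comp in (Competitor.DRUG_FAB2, Competitor.CONTROL_FAB2, Competitor.FULL_LENGTH):
            assert free_fraction(Species.FRAMEWORK, comp, 1e7) < 1e-5

    def test_no_competitor_leaves_everything_free(self):
        assert free_fraction(Species.HINGE, Competitor.NONE, 0.0) == 1.0

    def test_monotone_non_increasing_in_concentration(self):
        concs = [0, 1, 10, 50, 500]
        fractions = [free_fraction(Species.HINGE, Competitor.DRUG_FAB2, c) for c in concs]
        assert fractions[0] == 1.0
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_negative_concentration_raises(self):
        with pytest.raises(ValueError):
            free_fraction(Species.HINGE, Competitor.DRUG_FAB2, -1.0)


class TestSimulateSignal:
    def test_background_only_when_no_ata(self):
        cfg = SimulationConfig()
        assert simulate_signal(SpeciesLevels(), 1.0, Competitor.NONE, 0.0, cfg) == pytest.approx(
            cfg.background_au
        )

    def test_half_saturation_identity(self):
        cfg = SimulationConfig()
        levels = SpeciesLevels(anti_hinge=cfg.half_sat * 20.0)
        expected = cfg.background_au + cfg.s_max_au / 2
        assert simulate_signal(levels, 20.0, Competitor.NONE, 0.0, cfg) == pytest.approx(expected)

    def test_saturation_concavity(self):
        """Doubling the level less than doubles the above-background signal."""
        cfg = SimulationConfig()
        s1 = simulate_signal(SpeciesLevels(anti_hinge=10.0), 20.0, Competitor.NONE, 0.0, cfg)
        s2 = simulate_signal(SpeciesLevels(anti_hinge=20.0), 20.0, Competitor.NONE, 0.0, cfg)
        assert s2 > s1
        assert (s2 - cfg.background_au) < 2 * (s1 - cfg.background_au)

    def test_decreasing_in_dilution(self):
        cfg = SimulationConfig()
        levels = SpeciesLevels(anti_hinge=30.0)
        signals = [
            simulate_signal(levels, d, Competitor.NONE, 0.0, cfg) for d in (20, 100, 500)
        ]
        assert signals[0] > signals[1] > signals[2]

    def test_noise_is_mean_preserving(self):
        cfg = SimulationConfig(noise_cv=0.2)
        rng = np.random.default_rng(3)
        levels = SpeciesLevels(anti_hinge=30.0)
        clean = simulate_signal(levels, 20.0, Competitor.NONE, 0.0, cfg)
        noisy = np.mean(
            [simulate_signal(levels, 20.0, Competitor.NONE, 0.0, cfg, rng) for _ in range(4000)]
        )
        assert noisy == pytest.approx(clean, rel=0.02)


class TestSimulateAnimal:
    def test_zero_within_sd_freezes_pretreatment_levels(self, config):
        sim = dataclasses.replace(config.simulation, hinge_within_log_sd=0.0)
        rng = np.random.default_rng(0)
        by_day = simulate_animal("a", "control", config.design, sim, rng)
        pre = [by_day[d].anti_hinge for d in config.design.pretreatment_days]
        assert pre[0] == pytest.approx(pre[1])

    def test_control_animals_never_develop_anti_cdr(self, config):
        rng = np.random.default_rng(1)
        for _ in range(20):
            by_day = simulate_animal("a", "control", config.design, config.simulation, rng)
            assert all(levels.anti_cdr == 0 for levels in by_day.values())

    def test_anti_cdr_absent_before_onset(self, config):
        sim = dataclasses.replace(config.simulation)
        rng = np.random.default_rng(2)
        for _ in range(50):
            by_day = simulate_animal("a", "5mg/kg", config.design, sim, rng)
            assert all(by_day[d].anti_cdr == 0 for d in config.design.pretreatment_days)

    def test_between_animal_spread_matches_configuration(self, config):
        rng = np.random.default_rng(9)
        day1 = config.design.pretreatment_days[0]
        logs = [
            math.log(
                simulate_animal(str(i), "control", config.design, config.simulation, rng)[
                    day1
                ].anti_hinge
            )
            for i in range(200)
        ]
        observed = np.std(logs, ddof=1)
        expected = math.hypot(
            config.simulation.hinge_between_log_sd, config.simulation.hinge_within_log_sd
        )
        assert observed == pytest.approx(expected, rel=0.10)


class TestSimulateStudy:
    def test_same_seed_reproduces_identically(self, small_design, config):
        a = simulate_study(small_design, config.simulation, seed=7)
        b = simulate_study(small_design, config.simulation, seed=7)
        assert a == b

    def test_different_seed_differs(self, small_design, config):
        a = simulate_study(small_design, config.simulation, seed=7)
        b = simulate_study(small_design, config.simulation, seed=8)
        assert a != b

    def test_row_count_formula(self, small_design, config):
        sim = config.simulation
        records = simulate_study(small_design, sim, seed=0)
        per_day = sim.scheme.n_points + sim.n_blanks + 2
        n_animals = len(small_design.groups) * small_design.animals_per_group
        assert len(records) == n_animals * len(small_design.all_days) * per_day

    def test_competition_signal_ordering_with_spiked_anti_cdr(self, config):
        """Hinge-dominant serum plus an anti-CDR spike: drug competition takes
        the signal near background, control competition leaves the CDR
        component, no competition is highest."""
        sim = dataclasses.replace(config.simulation, noise_cv=0.0)
        levels = SpeciesLevels(anti_hinge=30.0, anti_cdr=6.0)
        uncompeted = simulate_signal(levels, 20.0, Competitor.NONE, 0.0, sim)
        H = simulate_signal(levels, 20.0, Competitor.CONTROL_FAB2, 50.0, sim)
        D = simulate_signal(levels, 20.0, Competitor.DRUG_FAB2, 50.0, sim)
        assert D < H < uncompeted

    def test_full_length_competes_less_than_drug_fab2_with_anti_hinge_present(self, config):
        sim = dataclasses.replace(config.simulation, noise_cv=0.0)
        levels = SpeciesLevels(anti_hinge=30.0, anti_cdr=6.0)
        full = simulate_signal(levels, 20.0, Competitor.FULL_LENGTH, 50.0, sim)
        drug = simulate_signal(levels, 20.0, Competitor.DRUG_FAB2, 50.0, sim)
        assert full > drug


class TestTiterRecovery:
    def test_fivefold_level_increase_shifts_titer_by_one_step(self, config):
        sim = dataclasses.replace(config.simulation, noise_cv=0.0)
        scheme = sim.scheme
        dilutions = build_dilution_series(scheme)
        cutpoint = 2 * sim.background_au

        def measure(level):
            levels = SpeciesLevels(anti_hinge=level)
            series = [
                (float(d), simulate_signal(levels, float(d), Competitor.NONE, 0.0, sim))
                for d in dilutions
            ]
            return interpolate_titer(series, cutpoint, step=scheme.step)

        base = measure(30.0)
        boosted = measure(150.0)
        assert boosted.titer_log5 - base.titer_log5 == pytest.approx(1.0, abs=0.05)

    def test_interpolated_titer_tracks_analytic_crossing(self, config):
        """Linear interpolation of an exponentially decaying curve across a
        5-fold step overshoots the true crossing by at most
        max_u [(1-u)/0.8 + ln(u)/ln(5)] ~= 0.194 log5 steps (chord above a
        convex curve); the measured titer must sit within that band."""
        sim = dataclasses.replace(config.simulation, noise_cv=0.0)
        scheme = sim.scheme
        dilutions = build_dilution_series(scheme)
        cutpoint = 2 * sim.background_au
        for level in (5.0, 30.0, 200.0, 1500.0):
            levels = SpeciesLevels(anti_hinge=level)
            series = [
                (float(d), simulate_signal(levels, float(d), Competitor.NONE, 0.0, sim))
                for d in dilutions
            ]
            measured = interpolate_titer(series, cutpoint, step=scheme.step)
            expected = analytic_titer_log5(level, cutpoint, sim)
            assert -1e-9 <= measured.titer_log5 - expected <= 0.20
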