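"""Steered-Langevin generator: analytic limits, determinism, toy structures."""

import numpy as np
import pytest

import fibmech as fm
from fibmech.errors import ConfigurationError, ValidationError
from fibmech.synthetic import (
    LangevinConfig,
    PotentialSpec,
    SteeringProtocol,
    SyntheticCohortSpec,
    generate_mutation_cohort,
    largest_remainder_counts,
    simulate_length_series,
)


class TestPotentialSpec:
    def test_harmonic_energy_is_half_kappa_z_squared(self):
        pot = PotentialSpec(kind="harmonic", stiffness=1.0)
        assert pot.energy(3.0) == pytest.approx(4.5)
        assert pot.force(3.0) == pytest.approx(-3.0)

    def test_flat_potential_is_zero_everywhere(self):
        pot = PotentialSpec(kind="flat")
        x = np.linspace(-5, 5, 11)
        assert np.all(pot.energy(x) == 0)
        assert np.all(pot.force(x) == 0)

    def test_double_well_barrier_height_at_midpoint(self):
        pot = PotentialSpec(kind="double_well", barrier_height=5.0, well_separation=4.0)
        grid = np.linspace(0.0, 4.0, 4001)
        energy = pot.energy(grid)
        assert energy.max() == pytest.approx(5.0, abs=1e-6)
        assert grid[np.argmax(energy)] == pytest.approx(2.0, abs=1e-3)
        assert pot.energy(0.0) == pytest.approx(0.0)
        assert pot.energy(4.0) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "spline"},
            {"kind": "harmonic", "stiffness": -1.0},
            {"kind": "double_well", "barrier_height": -1.0},
            {"kind": "double_well", "well_separation": 0.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            PotentialSpec(**kwargs)


class TestSteeringProtocol:
    def test_grid_spacing_is_speed_times_interval(self):
        steer = SteeringProtocol(pull_speed=0.1, total_distance=30.0, output_interval=10.0)
        assert steer.grid_spacing == pytest.approx(1.0)
        assert steer.n_outputs == 30
        grid = steer.extension_grid
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(30.0)
        assert np.allclose(np.diff(grid), 1.0)

    def test_non_integer_grid_rejected(self):
        with pytest.raises(ValidationError):
            SteeringProtocol(pull_speed=0.1, total_distance=30.5, output_interval=10.0)

    def test_non_positive_distance_rejected(self):
        with pytest.raises(ValidationError):
            SteeringProtocol(total_distance=-5.0)


class TestSteeredTrajectory:
    def test_unstable_timestep_is_a_configuration_error(self):
        pot = PotentialSpec(kind="harmonic", stiffness=1.0)
        steer = SteeringProtocol(
            spring_constant=100.0, pull_speed=1.0, total_distance=2.0, output_interval=1.0
        )
        cfg = LangevinConfig(friction=1.0, timestep=0.01, seed=0)  # bound is 0.002
        with pytest.raises(ConfigurationError):
            fm.simulate_steered_trajectory(pot, steer, cfg)

    def test_flat_potential_zero_temperature_work_is_negligible(self):
        # In the stiff-spring limit only viscous drag opposes pulling, so the
        # work is bounded by gamma*v*d, made tiny here.
        pot = PotentialSpec(kind="flat")
        steer = SteeringProtocol(
            spring_constant=10.0, pull_speed=0.1, total_distance=1.0, output_interval=2.0
        )
        cfg = LangevinConfig(temperature=0.0, friction=0.01, timestep=2e-4, seed=0)
        _, work = fm.simulate_steered_trajectory(pot, steer, cfg)
        assert work.work[0] == 0.0
        assert np.all(work.work >= 0.0)
        assert work.work[-1] <= 2.0 * cfg.friction * steer.pull_speed * steer.total_distance

    def test_quasistatic_zero_temperature_work_recovers_harmonic_pmf(self):
        pot = PotentialSpec(kind="harmonic", stiffness=1.0)
        steer = SteeringProtocol(
            spring_constant=50.0, pull_speed=0.01, total_distance=1.0, output_interval=25.0
        )
        cfg = LangevinConfig(temperature=0.0, friction=0.1, timestep=2e-4, seed=0)
        _, work = fm.simulate_steered_trajectory(pot, steer, cfg)
        expected = 0.5 * work.extension**2
        assert np.max(np.abs(work.work - expected)) < 0.03

    def test_fixed_seed_reproducible_bit_for_bit(self):
        pot = PotentialSpec(kind="harmonic", stiffness=1.0)
        steer = SteeringProtocol(
            spring_constant=10.0, pull_speed=1.0, total_distance=2.0, output_interval=0.5
        )
        cfg = LangevinConfig(friction=1.0, timestep=0.002, seed=42, n_replicates=3)
        _, w1 = fm.simulate_steered_trajectory(pot, steer, cfg)
        _, w2 = fm.simulate_steered_trajectory(pot, steer, cfg)
        assert np.array_equal(w1.work, w2.work)

    def test_single_replicate_ensemble_equals_single_trajectory(self):
        pot = PotentialSpec(kind="harmonic", stiffness=1.0)
        steer = SteeringProtocol(
            spring_constant=10.0, pull_speed=1.0, total_distance=2.0, output_interval=0.5
        )
        cfg = LangevinConfig(friction=1.0, timestep=0.002, seed=7, n_replicates=1)
        _, single = fm.simulate_steered_trajectory(pot, steer, cfg)
        ensemble = fm.generate_work_ensemble(pot, steer, cfg)
        assert np.array_equal(ensemble.works[0], single.work)

    def test_different_master_seeds_share_the_grid_but_not_the_works(self):
        pot = PotentialSpec(kind="harmonic", stiffness=1.0)
        steer = SteeringProtocol(
            spring_constant=10.0, pull_speed=1.0, total_distance=2.0, output_interval=0.5
        )
        cfg_a = LangevinConfig(friction=1.0, timestep=0.002, seed=1, n_replicates=4)
        cfg_b = LangevinConfig(friction=1.0, timestep=0.002, seed=2, n_replicates=4)
        ens_a = fm.generate_work_ensemble(pot, steer, cfg_a)
        ens_b = fm.generate_work_ensemble(pot, steer, cfg_b)
        assert np.array_equal(ens_a.extension, ens_b.extension)
        assert not np.array_equal(ens_a.works, ens_b.works)

    def test_mean_ensemble_work_dominates_analytic_free_energy(self):
        # second-law direction: dissipation is non-negative in expectation
        potential, steer, cfg = fm.synthetic.harmonic_benchmark(
            seed=3, n_replicates=30, pull_speed=0.5
        )
        ensemble = fm.generate_work_ensemble(potential, steer, cfg)
        reference = fm.analytic_pmf(potential, steer)
        assert np.all(ensemble.mean_work() >= reference.delta_g - 0.05)


class TestAnalyticPMF:
    def test_values_and_normalisation(self):
        pot = PotentialSpec(kind="harmonic", stiffness=1.0)
        steer = SteeringProtocol(pull_speed=1.0, total_distance=3.0, output_interval=1.0)
        profile = fm.analytic_pmf(pot, steer)
        assert profile.delta_g[0] == 0.0
        assert profile.delta_g[-1] == pytest.approx(4.5)
        flat = fm.analytic_pmf(PotentialSpec(kind="flat"), steer)
        assert np.all(flat.delta_g == 0.0)


class TestToyConformations:
    def test_configured_contacts_at_zero_strain(self, all_hairpin_toy):
        frame = all_hairpin_toy.at_strain(0.0)
        assert fm.count_contacts(frame, all_hairpin_toy.ligand_index) == 8

    def test_all_contacts_released_at_large_strain(self, all_hairpin_toy):
        frame = all_hairpin_toy.at_strain(2.0)
        assert fm.count_contacts(frame, all_hairpin_toy.ligand_index) == 0

    def test_contacts_non_increasing_against_bruteforce(self, all_hairpin_toy):
        grid = np.linspace(0.0, 1.5, 16)
        frames = fm.generate_toy_conformations(all_hairpin_toy, grid, noise=0.0)
        ligand = all_hairpin_toy.ligand_index
        counts = []
        for frame in frames:  # independent O(n) distance scan
            d = np.linalg.norm(frame.positions - frame.positions[ligand], axis=1)
            counts.append(int(np.sum((frame.elements == "O") & (d < 4.0))))
        assert counts == sorted(counts, reverse=True)
        series = [fm.count_contacts(f, ligand) for f in frames]
        assert series == counts

    def test_strain_strictly_increases_domain_separation(self, all_hairpin_toy):
        seps = [all_hairpin_toy.com_separation(s) for s in (0.0, 0.2, 0.5, 1.0)]
        assert np.all(np.diff(seps) > 0)

    def test_negative_strain_rejected(self, all_hairpin_toy):
        with pytest.raises(ValidationError):
            fm.generate_toy_conformations(all_hairpin_toy, [0.0, -0.1])

    def test_noise_is_deterministic_under_seed(self, all_hairpin_toy):
        grid = [0.0, 0.5]
        a = fm.generate_toy_conformations(all_hairpin_toy, grid, noise=0.1, seed=5)
        b = fm.generate_toy_conformations(all_hairpin_toy, grid, noise=0.1, seed=5)
        c = fm.generate_toy_conformations(all_hairpin_toy, grid, noise=0.1, seed=6)
        assert np.array_equal(a[1].positions, b[1].positions)
        assert not np.array_equal(a[1].positions, c[1].positions)


class TestLengthSeries:
    def test_ou_series_reaches_boltzmann_variance(self):
        cfg = LangevinConfig(temperature=300.0, friction=1.0, timestep=0.01, seed=11)
        series = simulate_length_series(60.0, 1.0, cfg, n_frames=400_000)
        expected = fm.kt(300.0) / 1.0
        assert series.var() == pytest.approx(expected, rel=0.1)
        assert series.mean() == pytest.approx(60.0, abs=0.05)


class TestMutationCohortGeneration:
    def test_half_and_half_counts_are_exact(self, default_map):
        spec = SyntheticCohortSpec(
            counts={"MFS": 100},
            proportions={"MFS": {"calcium_binding": 0.5, "other": 0.5}},
            seed=0,
        )
        records = generate_mutation_cohort(spec, default_map)
        labels = [
            fm.classify_residue(r, default_map).label
            for r in fm.mutations.records_from_frame(records)
        ]
        assert labels.count("calcium_binding") == 50
        assert labels.count("other") == 50

    def test_roundtrip_classification_matches_generating_class(self, default_map):
        mix = {
            "calcium_binding": 0.3,
            "cysteine_bond1": 0.2,
            "cysteine_bond2": 0.2,
            "cysteine_bond3": 0.1,
            "other": 0.2,
        }
        spec = SyntheticCohortSpec(
            counts={"MFS": 60}, proportions={"MFS": mix}, seed=9
        )
        records = generate_mutation_cohort(spec, default_map)
        labels = [
            fm.classify_residue(r, default_map).label
            for r in fm.mutations.records_from_frame(records)
        ]
        expected = largest_remainder_counts(60, mix)
        for cls, n in expected.items():
            assert labels.count(cls) == n

    def test_largest_remainder_sums_exactly(self):
        counts = largest_remainder_counts(
            93, {"calcium_binding": 1 / 3, "cysteine_bond1": 1 / 3, "other": 1 / 3}
        )
        assert sum(counts.values()) == 93

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticCohortSpec(
                counts={"MFS": 10}, proportions={"MFS": {"other": 0.7}}, seed=0
            )
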