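import numpy as np
import pytest

from nanobreak.npgeom import Phantom, build_phantom
from nanobreak.tracks import (
    EV_TO_J,
    PROCESSES,
    PhaseSpace,
    TrackConfig,
    dose_in_region,
    process_census,
    read_phase_space,
    region_masses,
    sample_events,
    write_phase_space,
)


def _manual_ps(positions, energies, processes):
    n = len(energies)
    return PhaseSpace(
        positions=np.asarray(positions, dtype=float).reshape(n, 3),
        energies=np.asarray(energies, dtype=float),
        processes=np.asarray(processes, dtype=object),
        track_ids=np.arange(n),
        seed=0,
        config_digest="manual",
        target_dose=1.0,
    )


class TestSampleEvents:
    def test_realized_dose_matches_target(self, empty_phantom, water_phase_space):
        """In a particle-free phantom the realized water dose hits the target."""
        rd = dose_in_region(water_phase_space, empty_phantom, "water_sphere")
        assert rd.dose == pytest.approx(1.0, rel=1e-2)
        # all deposits in water => conservation is exact up to float rounding
        assert rd.dose * rd.mass == pytest.approx(
            water_phase_space.total_energy * EV_TO_J, rel=1e-9
        )

    def test_all_deposits_inside_sphere(self, small_phantom):
        ps = sample_events(small_phantom, 1e5, seed=4)
        assert np.all(
            np.linalg.norm(ps.positions, axis=1) <= small_phantom.sphere_radius_nm
        )

    def test_seed_determinism(self, small_phantom):
        a = sample_events(small_phantom, 1e5, seed=9)
        b = sample_events(small_phantom, 1e5, seed=9)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.energies, b.energies)
        assert np.array_equal(a.processes, b.processes)

    def test_label_frequencies_match_weights(self):
        """Empirical process frequencies follow configured weights (χ², 2%)."""
        weights = {
            "elastic": 2.0e5,
            "electronic_excitation": 2.4e4,
            "vibrational_excitation": 1.61e5,
            "ionization": 5.37e4,
            "attachment": 467.0,
        }
        # give elastic a nonzero mean so event count, not energy, dominates
        cfg = TrackConfig(process_frequencies=weights)
        phantom = Phantom(sphere_volume=50.0)
        # dose chosen to land ~1e5 events at the default mean energies
        ps = sample_events(phantom, 1.3, cfg, seed=12)
        assert len(ps) > 5e4
        census = process_census(ps)
        total_w = sum(weights.values())
        observed = np.array([census[p] for p in PROCESSES], dtype=float)
        expected = np.array([weights[p] / total_w for p in PROCESSES]) * len(ps)
        for obs, exp in zip(observed, expected):
            if exp > 500:
                assert obs == pytest.approx(exp, rel=0.02)
        from scipy import stats

        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(PROCESSES) - 1)
        assert p > 0.001

    def test_enhancement_monotonic_in_factor(self, small_phantom):
        """Near-particle event counts are non-decreasing in the enhancement."""
        centers = small_phantom.centers_nm()
        radius = 25.0 + small_phantom.particles[0].outer_radius
        mean_near = []
        for factor in (0.0, 1.0, 5.0):
            counts = []
            for seed in (1, 2, 3):
                cfg = TrackConfig(
                    enhancement_factor={"Pt": factor}, enhancement_radius=25.0
                )
                ps = sample_events(small_phantom, 4e4, cfg, seed=seed)
                d = np.linalg.norm(
                    ps.positions[:, None, :] - centers[None, :, :], axis=2
                ).min(axis=1)
                counts.append(np.sum(d < radius) / len(ps))
            mean_near.append(np.mean(counts))
        assert mean_near[0] < mean_near[1] < mean_near[2]

    def test_zero_enhancement_matches_background_density(self, small_phantom):
        cfg = TrackConfig(enhancement_factor={"Pt": 0.0, "Au": 0.0})
        ps = sample_events(small_phantom, 4e4, cfg, seed=5)
        # fraction of events within the inner half-radius sphere ~ (1/2)³
        frac = np.mean(
            np.linalg.norm(ps.positions, axis=1) < small_phantom.sphere_radius_nm / 2
        )
        assert frac == pytest.approx(1 / 8, abs=0.02)

    def test_elastic_deposits_zero_energy(self, water_phase_space):
        elastic = water_phase_space.processes == "elastic"
        assert np.all(water_phase_space.energies[elastic] == 0.0)

    def test_invalid_inputs(self, empty_phantom):
        with pytest.raises(ValueError):
            sample_events(empty_phantom, 0.0, seed=1)
        with pytest.raises(ValueError, match="weight"):
            sample_events(
                empty_phantom,
                1.0,
                TrackConfig(process_frequencies={p: 0.0 for p in PROCESSES}),
                seed=1,
            )
        with pytest.raises(ValueError, match="no energy"):
            sample_events(
                empty_phantom,
                1.0,
                TrackConfig(process_frequencies={"elastic": 1.0}),
                seed=1,
            )


class TestDoseAccounting:
    def test_unit_conversion_single_deposit(self):
        """1 eV in 1 kg of water is 1.602176634e-19 Gy."""
        phantom = Phantom(sphere_volume=1e9)  # 1 mm³ = 1e-6 kg... use mass directly
        ps = _manual_ps([[0.0, 0.0, 0.0]], [1.0], ["ionization"])
        rd = dose_in_region(ps, phantom, "water_sphere")
        assert rd.dose * rd.mass == pytest.approx(1.602176634e-19)

    def test_empty_phase_space_zero_dose(self, small_phantom):
        ps = _manual_ps(np.empty((0, 3)), [], [])
        for region in ("water_sphere", "shells", "cores"):
            assert dose_in_region(ps, small_phantom, region).dose == 0.0

    def test_region_energy_conservation(self, small_phantom):
        """Σ over disjoint regions of dose×mass equals the total energy in J."""
        ps = sample_events(small_phantom, 1e5, seed=21)
        total_j = sum(
            dose_in_region(ps, small_phantom, r).deposited_energy * EV_TO_J
            for r in ("water_sphere", "shells", "cores")
        )
        assert total_j == pytest.approx(ps.total_energy * EV_TO_J, rel=1e-9)

    def test_deposit_in_core_and_shell_classified(self, small_phantom):
        p = small_phantom.particles[0]
        core_point = p.center + np.array([p.core_radius * 0.5, 0, 0])
        shell_point = p.center + np.array([(p.core_radius + p.outer_radius) / 2, 0, 0])
        ps = _manual_ps([core_point, shell_point], [5.0, 7.0], ["ionization"] * 2)
        assert dose_in_region(ps, small_phantom, "cores").deposited_energy == 5.0
        assert dose_in_region(ps, small_phantom, "shells").deposited_energy == 7.0

    def test_unknown_region_rejected(self, small_phantom):
        ps = _manual_ps(np.empty((0, 3)), [], [])
        with pytest.raises(ValueError, match="unknown region"):
            dose_in_region(ps, small_phantom, "vacuum")

    def test_region_masses_use_material_densities(self, small_phantom):
        masses = region_masses(small_phantom)
        p = small_phantom.particles[0]
        core_vol_m3 = 4 / 3 * np.pi * p.core_radius**3 * 1e-27
        assert masses["cores"] == pytest.approx(12 * core_vol_m3 * 19300.0)
        shell_vol_m3 = 4 / 3 * np.pi * (p.outer_radius**3 - p.core_radius**3) * 1e-27
        assert masses["shells"] == pytest.approx(12 * shell_vol_m3 * 21450.0)


class TestCensus:
    def test_counts_exact(self):
        ps = _manual_ps(
            np.zeros((5, 3)),
            [1, 2, 3, 0, 0],
            ["ionization", "ionization", "ionization", "elastic", "elastic"],
        )
        census = process_census(ps)
        assert census["ionization"] == 3
        assert census["elastic"] == 2
        assert sum(census.values()) == len(ps)

    def test_empty_is_all_zero(self):
        ps = _manual_ps(np.empty((0, 3)), [], [])
        assert set(process_census(ps).values()) == {0}


class TestPhaseSpaceIO:
    def test_round_trip_deposit_by_deposit(self, tmp_path, water_phase_space):
        path = tmp_path / "ps.tsv"
        write_phase_space(water_phase_space, path)
        back = read_phase_space(path)
        assert np.array_equal(back.positions, water_phase_space.positions)
        assert np.array_equal(back.energies, water_phase_space.energies)
        assert np.array_equal(back.processes, water_phase_space.processes)
        assert np.array_equal(back.track_ids, water_phase_space.track_ids)
        assert back.seed == water_phase_space.seed
        assert back.config_digest == water_phase_space.config_digest
        assert back.target_dose == water_phase_space.target_dose

    def test_negative_energy_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "# seed=0\n# config_digest=x\n# target_dose_gy=1.0\n"
            "0\t0\t0\t-5.0\tionization\t0\n"
        )
        with pytest.raises(ValueError, match=":4"):
            read_phase_space(path)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "# seed=0\n# config_digest=x\n# target_dose_gy=1.0\n0\t0\t0\n"
        )
        with pytest.raises(ValueError, match=":4"):
            read_phase_space(path)

    def test_missing_header_field(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# seed=0\n0\t0\t0\t1.0\tionization\t0\n")
        with pytest.raises(ValueError, match="config_digest"):
            read_phase_space(path)

    def test_empty_body_valid_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("# seed=5\n# config_digest=abc\n# target_dose_gy=2.5\n")
        ps = read_phase_space(path)
        assert len(ps) == 0
        assert ps.seed == 5 and ps.target_dose == 2.5
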