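"""Forward model: equilibrium partition, injection, rendering, full runs."""

import numpy as np
import pytest
from scipy.special import expit

import redoxeq as rq
from redoxeq.errors import ValidationError
from redoxeq.simulate import FARADAY, GAS_CONSTANT


def grid_search_potential(e_total, species, temperature_K, resolution=0.001):
    """Independent oracle: dense scan over E for the electron balance."""
    beta = FARADAY / (1000.0 * GAS_CONSTANT * temperature_K)
    E_ms = np.array([s.E_m_mV for s in species])
    grid = np.arange(E_ms.min() - 450.0, E_ms.max() + 450.0, resolution)
    total = np.zeros_like(grid)
    for s in species:
        total += s.n * s.concentration_uM * expit(
            -s.n * beta * (grid - s.E_m_mV)
        )
    return float(grid[np.argmin(np.abs(total - e_total))])


def species(E_m, n=1, C=4.0, name="s"):
    return rq.RedoxSpecies(name=name, E_m_mV=E_m, n=n, concentration_uM=C)


class TestEquilibriumPartition:
    def test_half_capacity_single_species_sits_at_midpoint(self):
        pair = [species(47.0, n=1, C=4.0), species(34.0, n=2, C=0.0)]
        E, f = rq.equilibrium_partition(2.0, pair)
        assert E == pytest.approx(47.0, abs=1e-6)
        assert f[0] == pytest.approx(0.5, abs=1e-9)

    def test_indistinguishable_couples_share_fractions(self):
        pair = [species(-10.0, n=2, C=3.0), species(-10.0, n=2, C=5.0)]
        for e in (1.0, 6.0, 12.0):
            _, f = rq.equilibrium_partition(e, pair)
            assert f[0] == pytest.approx(f[1], abs=1e-12)

    def test_example_pair_matches_grid_oracle(self):
        pair = [species(47.0, n=1, C=4.0), species(34.0, n=2, C=3.0)]
        E, f = rq.equilibrium_partition(5.0, pair)
        assert E == pytest.approx(
            grid_search_potential(5.0, pair, 298.15), abs=0.002
        )
        conserved = sum(
            s.n * s.concentration_uM * fi for s, fi in zip(pair, f)
        )
        assert conserved == pytest.approx(5.0, abs=1e-9)

    def test_random_configurations_match_grid_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pair = [
                species(rng.uniform(-300, 300), int(rng.integers(1, 3)),
                        rng.uniform(1, 10)),
                species(rng.uniform(-300, 300), int(rng.integers(1, 3)),
                        rng.uniform(1, 10)),
            ]
            capacity = sum(s.capacity_uM_electrons for s in pair)
            e = rng.uniform(0.05, 0.95) * capacity
            E, _ = rq.equilibrium_partition(e, pair)
            assert abs(E - grid_search_potential(e, pair, 298.15)) <= 0.002

    def test_fractions_monotone_and_potential_antitone_in_e_total(self):
        pair = [species(47.0, n=1, C=4.0), species(34.0, n=2, C=3.0)]
        capacity = sum(s.capacity_uM_electrons for s in pair)
        es = np.linspace(0.0, capacity, 40)
        results = [rq.equilibrium_partition(e, pair) for e in es]
        potentials = np.array([r[0] for r in results])
        fracs = np.array([r[1] for r in results])
        assert np.all(np.diff(potentials) <= 0)
        assert np.all(np.diff(fracs, axis=0) >= -1e-12)

    def test_boundary_electron_pools(self):
        pair = [species(0.0, n=1, C=2.0)]
        E0, f0 = rq.equilibrium_partition(0.0, pair)
        Ef, ff = rq.equilibrium_partition(2.0, pair)
        assert E0 == np.inf and f0[0] == 0.0
        assert Ef == -np.inf and ff[0] == 1.0

    def test_overfilled_pool_rejected(self):
        with pytest.raises(ValidationError, match="capacity"):
            rq.equilibrium_partition(5.0, [species(0.0, n=1, C=2.0)])

    def test_empty_cuvette_rejected(self):
        with pytest.raises(ValidationError, match="C > 0"):
            rq.equilibrium_partition(0.0, [species(0.0, C=0.0)])


class TestInjectedElectrons:
    def _config(self, **kw):
        return rq.SimulationConfig(
            protein=rq.heme_protein("p", 0.0),
            dye=rq.get_dye("toluidine blue O"),
            noise_sd_AU=0.0,
            **kw,
        ).resolved()

    def test_zero_at_time_zero(self):
        assert rq.injected_electrons(0.0, self._config()) == 0.0

    def test_constant_profile_is_rate_times_time(self):
        cfg = self._config(injection_rate_uM_per_min=0.5)
        assert rq.injected_electrons(3.0, cfg) == pytest.approx(1.5)

    def test_capped_at_budget_and_capacity(self):
        cfg = self._config(injection_rate_uM_per_min=100.0)
        capacity = (
            cfg.protein.capacity_uM_electrons + cfg.dye.capacity_uM_electrons
        )
        assert rq.injected_electrons(1e6, cfg) == pytest.approx(
            min(capacity, cfg.electron_budget_uM)
        )

    def test_exponential_profile_approaches_budget(self):
        cfg = self._config(
            injection_profile="exponential_approach",
            injection_rate_uM_per_min=1.0,
        )
        assert rq.injected_electrons(1e9, cfg) == pytest.approx(
            cfg.electron_budget_uM, abs=1e-6
        )

    def test_non_decreasing_in_time(self):
        cfg = self._config(injection_profile="exponential_approach")
        ts = np.linspace(0, 120, 200)
        vals = [rq.injected_electrons(t, cfg) for t in ts]
        assert np.all(np.diff(vals) >= 0)


class TestRenderSpectrum:
    def test_endmembers_and_linearity(self):
        grid = np.arange(350.0, 751.0)
        pair = [
            rq.heme_protein("p", 0.0),
            rq.get_dye("toluidine blue O").with_concentration(5.0),
        ]
        a_ox = rq.render_spectrum([0.0, 0.0], pair, grid)
        a_red = rq.render_spectrum([1.0, 1.0], pair, grid)
        a_mid = rq.render_spectrum([0.5, 0.5], pair, grid)
        np.testing.assert_allclose(a_mid, 0.5 * (a_ox + a_red), atol=1e-12)
        exp_ox = sum(
            s.concentration_uM * s.spectrum_ox(grid) for s in pair
        )
        np.testing.assert_allclose(a_ox, exp_ox, atol=1e-12)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            rq.render_spectrum(
                [1.5, 0.0],
                [rq.heme_protein("p", 0.0), rq.get_dye("Nile blue")],
                np.arange(350.0, 751.0),
            )


class TestHemeSpectra:
    def test_band_maxima_and_positivity(self):
        grid = np.arange(350.0, 751.0)
        eps_ox, eps_red = rq.default_heme_spectra(grid)
        assert grid[np.argmax(eps_ox)] == 413.0
        assert grid[np.argmax(eps_red)] == 430.0
        assert np.all(eps_ox >= 0) and np.all(eps_red >= 0)
        assert eps_red.max() > eps_ox.max()  # reduced Soret gains amplitude

    def test_narrow_grid_rejected(self):
        with pytest.raises(ValidationError, match="380-600"):
            rq.default_heme_spectra(np.arange(400.0, 500.0))


class TestSimulateRun:
    def test_same_seed_reproduces_exactly(self, myoglobin, tbo):
        cfg = rq.SimulationConfig(protein=myoglobin, dye=tbo, seed=11)
        ts1, _ = rq.simulate_run(cfg)
        ts2, _ = rq.simulate_run(cfg)
        np.testing.assert_array_equal(ts1.absorbance, ts2.absorbance)

    def test_electron_conservation_recomputed_from_ground_truth(
        self, myoglobin, tbo
    ):
        cfg = rq.SimulationConfig(protein=myoglobin, dye=tbo, seed=3)
        _, truth = rq.simulate_run(cfg)
        rcfg = truth.config
        titr = truth.phase_labels == "titration"
        pool = (
            rcfg.protein.capacity_uM_electrons * truth.f_red_protein[titr]
            + rcfg.dye.capacity_uM_electrons * truth.f_red_dye[titr]
        )
        np.testing.assert_allclose(pool, truth.injected_uM[titr], atol=1e-9)

    def test_noiseless_exhausted_titration_equals_dithionite_block(self):
        protein = rq.heme_protein("p", 47.0)
        dye = rq.get_dye("toluidine blue O").with_concentration(1e-12)
        cfg = rq.SimulationConfig(protein=protein, dye=dye, noise_sd_AU=0.0)
        ts, _ = rq.simulate_run(cfg)
        last_titr = np.flatnonzero(ts.titration_mask)[-1]
        first_dith = np.flatnonzero(ts.dithionite_mask)[0]
        np.testing.assert_allclose(
            ts.absorbance[:, last_titr], ts.absorbance[:, first_dith], atol=1e-9
        )

    def test_default_run_shape_and_phases(self, myoglobin, tbo):
        cfg = rq.SimulationConfig(protein=myoglobin, dye=tbo, seed=1)
        ts, truth = rq.simulate_run(cfg)
        assert ts.times.size == 50  # 40 titration + 10 dithionite
        assert np.count_nonzero(ts.dithionite_mask) == 10
        titr = truth.phase_labels == "titration"
        assert np.all(np.diff(truth.f_red_protein[titr]) >= -1e-12)
        assert np.all(np.diff(truth.f_red_dye[titr]) >= -1e-12)

    def test_dye_autotitration_matches_protein_band(self, myoglobin, tbo):
        cfg = rq.SimulationConfig(
            protein=myoglobin, dye=tbo, noise_sd_AU=0.0
        ).resolved()
        grid = cfg.wavelengths
        protein_max = (
            cfg.protein.concentration_uM * cfg.protein.spectrum_ox(grid).max()
        )
        dye_max = cfg.dye.concentration_uM * cfg.dye.spectrum_ox(grid).max()
        assert dye_max == pytest.approx(protein_max, rel=1e-9)

    def test_seed_required_for_noisy_runs(self, myoglobin, tbo):
        with pytest.raises(ValidationError, match="seed"):
            rq.SimulationConfig(protein=myoglobin, dye=tbo, noise_sd_AU=0.002)

    def test_ground_truth_file_never_mixes_with_spectra(
        self, tmp_path, myoglobin, tbo
    ):
        from redoxeq.simulate import write_ground_truth

        cfg = rq.SimulationConfig(protein=myoglobin, dye=tbo, seed=5)
        ts, truth = rq.simulate_run(cfg)
        gt_path = tmp_path / "ground_truth.csv"
        write_ground_truth(truth, gt_path)
        text = gt_path.read_text()
        assert "# protein_E_m_mV: 47" in text
        assert "f_red_protein" in text
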