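"""Partition-function titration: closed forms, oracles, invariances."""

import numpy as np
import pytest

import kvpore as kp
from kvpore.errors import CapabilityError
from kvpore.titration import LN10, TitrationModel, TitrationSite, rt_kcal


def single_site_model(model_pka=6.0, e_prot=0.0, sd_prot=0.0, t=310.0):
    return TitrationModel(
        sites=[TitrationSite("S1", model_pka)],
        microstates=np.array([[0], [1]]),
        energy_mean=np.array([0.0, e_prot]),
        energy_sd=np.array([0.0, sd_prot]),
        temperature_K=t,
    )


def random_model(n_sites, rng, energy_scale=1.5, coupling_scale=0.8):
    """A random coupled multi-site model over all 2^n microstates."""
    micro = kp.enumerate_microstates(n_sites)
    shifts = rng.normal(0, energy_scale, n_sites)
    w = rng.normal(0, coupling_scale, (n_sites, n_sites))
    w = np.triu(w, 1)
    w = w + w.T
    x = micro.astype(float)
    e0 = x @ shifts + 0.5 * np.einsum("mi,ij,mj->m", x, w, x)
    sites = [
        TitrationSite(f"S{i}", float(rng.uniform(3.5, 7.5))) for i in range(n_sites)
    ]
    return TitrationModel(
        sites=sites,
        microstates=micro,
        energy_mean=e0,
        energy_sd=np.zeros(len(e0)),
        temperature_K=310.0,
    )


def direct_sum_theta(model, site_idx, ph):
    """Independent oracle: plain Boltzmann sums (no log-domain machinery)."""
    rt = rt_kcal(model.temperature_K)
    pkas = model.model_pkas
    num = den = 0.0
    for i, x in enumerate(model.microstates):
        g = model.energy_mean[i] + LN10 * rt * float(
            ph * x.sum() - x.astype(float) @ pkas
        )
        w = np.exp(-(g - model.energy_mean.min()) / rt)
        den += w
        if x[site_idx]:
            num += w
    return num / den


class TestFreeEnergy:
    def test_fully_deprotonated_state_has_bare_energy(self):
        m = single_site_model(e_prot=3.0)
        g = kp.microstate_free_energy(m, ph=7.3)
        assert g[0] == 0.0  # x = 0: pH terms vanish

    def test_equal_energies_cancel_at_model_pka(self):
        m = single_site_model(model_pka=6.54)
        g = kp.microstate_free_energy(m, ph=6.54)
        assert g[0] == pytest.approx(g[1], abs=1e-12)

    def test_three_site_hand_summed_terms(self):
        rng = np.random.default_rng(31)
        m = random_model(3, rng)
        g = kp.microstate_free_energy(m, ph=7.0)
        rt = rt_kcal(310.0)
        for i, x in enumerate(m.microstates):
            expected = m.energy_mean[i]
            for s in range(3):
                if x[s]:
                    expected += LN10 * rt * (7.0 - m.sites[s].model_pka)
            assert g[i] == pytest.approx(expected, abs=1e-12)


class TestProtonationFraction:
    def test_half_protonated_at_model_pka(self):
        m = single_site_model(model_pka=6.2)
        assert kp.protonation_fraction(m, "S1", 6.2) == pytest.approx(0.5, abs=1e-15)

    def test_henderson_hasselbalch_one_unit_below(self):
        m = single_site_model(model_pka=6.2)
        theta = kp.protonation_fraction(m, "S1", 5.2)
        assert theta == pytest.approx(10 / 11, abs=1e-12)

    def test_eight_coupled_sites_match_direct_sum_oracle(self):
        rng = np.random.default_rng(88)
        m = random_model(8, rng)
        for ph in (3.0, 5.5, 8.0):
            for si in (0, 3, 7):
                mine = kp.protonation_fraction(m, f"S{si}", ph)
                oracle = direct_sum_theta(m, si, ph)
                assert abs(mine - oracle) < 1e-10

    def test_gauge_invariance_under_constant_energy_offset(self):
        rng = np.random.default_rng(4)
        m = random_model(5, rng)
        base = [kp.protonation_fraction(m, "S2", ph) for ph in (4.0, 6.0)]
        for shift in (250.0, -500.0):
            m2 = TitrationModel(
                sites=m.sites,
                microstates=m.microstates,
                energy_mean=m.energy_mean + shift,
                energy_sd=m.energy_sd,
                temperature_K=m.temperature_K,
            )
            moved = [kp.protonation_fraction(m2, "S2", ph) for ph in (4.0, 6.0)]
            assert np.allclose(base, moved, atol=1e-10)

    def test_theta_decreasing_and_total_protons_non_increasing(self):
        rng = np.random.default_rng(9)
        grid = np.linspace(3, 8, 26)
        uncoupled = random_model(4, rng, coupling_scale=0.0)
        for si in range(4):
            theta = [kp.protonation_fraction(uncoupled, f"S{si}", p) for p in grid]
            assert np.all(np.diff(theta) < 0)
        coupled = random_model(4, rng)
        total = np.array(
            [
                sum(kp.protonation_fraction(coupled, f"S{si}", p) for si in range(4))
                for p in grid
            ]
        )
        assert np.all(np.diff(total) <= 1e-12)


class TestDominantStates:
    def test_threshold_zero_selects_all(self):
        rng = np.random.default_rng(10)
        m = random_model(4, rng)
        subset = kp.select_dominant_states(m, np.linspace(3, 8, 11), 0.0)
        assert len(subset) == 16

    def test_single_site_grid_straddling_pka(self):
        m = single_site_model(model_pka=6.0)
        subset = kp.select_dominant_states(m, np.array([4.0, 6.0, 8.0]), 0.4)
        assert set(subset) == {0, 1}

    def test_truncation_error_bounded(self):
        rng = np.random.default_rng(55)
        grid = np.linspace(3, 8, 51)
        m = random_model(6, rng)
        subset = kp.select_dominant_states(m, grid, 1e-4)
        assert len(subset) < 64
        for ph in grid[::10]:
            for si in (0, 5):
                full = kp.protonation_fraction(m, f"S{si}", ph)
                trunc = kp.protonation_fraction(m, f"S{si}", ph, subset)
                assert abs(full - trunc) < 1e-3

    def test_too_many_sites_capability_error(self):
        sites = [TitrationSite(f"S{i}", 5.0) for i in range(21)]
        micro = np.zeros((2, 21), dtype=np.int8)
        micro[1, 0] = 1
        m = TitrationModel(
            sites=sites,
            microstates=micro,
            energy_mean=np.zeros(2),
            energy_sd=np.zeros(2),
        )
        with pytest.raises(CapabilityError):
            kp.select_dominant_states(m, np.array([7.0]), 0.1)


class TestEstimatePka:
    def test_exact_grid_hit(self):
        pka, multi = kp.estimate_pka(np.array([0.8, 0.5, 0.2]), np.array([5.0, 6.0, 7.0]))
        assert pka == 6.0 and not multi

    def test_linear_interpolation(self):
        pka, _ = kp.estimate_pka(np.array([0.7, 0.3]), np.array([5.0, 6.0]))
        assert pka == pytest.approx(5.5)

    def test_closed_form_recovery_on_fine_grid(self):
        m = single_site_model(model_pka=6.2)
        grid = np.arange(3.0, 8.0001, 0.01)
        theta = np.array([kp.protonation_fraction(m, "S1", p) for p in grid])
        pka, _ = kp.estimate_pka(theta, grid)
        assert pka == pytest.approx(6.2, abs=0.005)

    def test_no_crossing_is_absent(self):
        pka, multi = kp.estimate_pka(np.array([0.9, 0.8, 0.7]), np.array([5.0, 6.0, 7.0]))
        assert pka is None and not multi

    def test_multiple_crossings_flagged_smallest_reported(self):
        theta = np.array([0.8, 0.4, 0.6, 0.2])
        grid = np.array([4.0, 5.0, 6.0, 7.0])
        pka, multi = kp.estimate_pka(theta, grid)
        assert multi
        assert pka == pytest.approx(4.75)


class TestUncertainty:
    grid = np.arange(3.0, 8.0001, 0.01)

    def test_zero_sd_bands_equal_point(self):
        m = single_site_model(model_pka=6.0)
        bands = kp.pka_uncertainty(m, "S1", self.grid)
        theta = np.array([kp.protonation_fraction(m, "S1", p) for p in self.grid])
        point, _ = kp.estimate_pka(theta, self.grid)
        for lo, hi in bands.values():
            assert lo == pytest.approx(point, abs=1e-9)
            assert hi == pytest.approx(point, abs=1e-9)

    def test_closed_form_half_width(self):
        sigma0 = 1.0
        m = single_site_model(model_pka=6.0, sd_prot=sigma0)
        bands = kp.pka_uncertainty(m, "S1", self.grid)
        lo, hi = bands[1.0]
        expected = sigma0 / (LN10 * rt_kcal(310.0))
        assert (hi - lo) / 2 == pytest.approx(expected, abs=1e-6)

    def test_band_widths_monotone_in_k(self):
        rng = np.random.default_rng(66)
        m = random_model(3, rng)
        m.energy_sd = np.abs(rng.normal(0, 0.5, len(m.energy_mean)))
        bands = kp.pka_uncertainty(m, "S1", self.grid)
        widths = [bands[k][1] - bands[k][0] for k in sorted(bands)]
        assert all(w2 >= w1 - 1e-12 for w1, w2 in zip(widths, widths[1:]))
        # single-site case: nesting is exact, width grows linearly in k
        single = single_site_model(model_pka=6.0, sd_prot=0.8)
        sb = kp.pka_uncertainty(single, "S1", self.grid)
        for k, (lo, hi) in sb.items():
            k2 = round(k + 0.1, 1)
            if k2 in sb:
                assert sb[k2][0] <= lo + 1e-9 and sb[k2][1] >= hi - 1e-9


class TestRunTitration:
    def test_parameter_recovery_without_couplings(self):
        spec = kp.ToyEnergySpec(
            sites=[("D1", 3.71, 0.0), ("E1", 4.25, 0.0), ("H1", 6.54, 0.0)],
            n_structures=1,
            noise_sd=0.0,
        )
        table, _ = kp.generate_energy_table(spec)
        curves = kp.run_titration(table, [kp.TitrationSite(s, p) for s, p, _ in spec.sites])
        for sid, pka_true in (("D1", 3.71), ("E1", 4.25), ("H1", 6.54)):
            assert curves[sid].pka_point == pytest.approx(pka_true, abs=0.01)

    def test_paper_style_output_shape(self):
        table, _ = kp.generate_energy_table(
            kp.ToyEnergySpec(sites=[("E1", 4.25, -1.0)], n_structures=5, noise_sd=0.1)
        )
        curves = kp.run_titration(table)
        curve = curves["E1"]
        assert len(curve.ph_grid) == 501
        assert curve.ph_grid[0] == 3.0 and curve.ph_grid[-1] == pytest.approx(8.0)
        assert set(curve.pka_band) == {0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0}
        assert np.all((curve.fraction >= 0) & (curve.fraction <= 1))

    def test_single_structure_degenerate_bands(self):
        table, _ = kp.generate_energy_table(
            kp.ToyEnergySpec(sites=[("E1", 4.25, 0.0)], n_structures=1, noise_sd=0.0)
        )
        curves = kp.run_titration(table)
        lo, hi = curves["E1"].pka_band[1.0]
        assert lo == pytest.approx(hi)

    def test_log_domain_stable_under_huge_offsets(self):
        spec = kp.ToyEnergySpec(
            sites=[("E1", 4.25, 0.5), ("H1", 6.54, -0.5)], n_structures=1, noise_sd=0.0
        )
        table, _ = kp.generate_energy_table(spec)
        base = kp.run_titration(table)
        for offset in (500.0, -500.0):
            shifted = kp.EnergyTable(
                sites=table.sites,
                microstates=table.microstates,
                structures=table.structures,
                energies=table.energies + offset,
            )
            moved = kp.run_titration(shifted)
            for sid in base:
                assert np.allclose(
                    base[sid].fraction, moved[sid].fraction, atol=1e-10
                )
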