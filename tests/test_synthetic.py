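"""Generator tests: determinism, stated oracles, and invariants."""

import numpy as np
import pytest
from scipy.integrate import quad

from bilayerlab import nmr, saxd
from bilayerlab.errors import InvalidGridError, InvalidInputError
from bilayerlab.synthetic import (
    R_KCAL,
    default_saxd_grid,
    gaussian_overlap,
    gen_31p_spectrum,
    gen_hexagonal_pattern,
    gen_noesy_table,
    gen_saxs_pattern,
    gen_thermogram,
    gen_trajectory,
    vant_hoff_excess_cp,
)
from bilayerlab.types import DepthDistribution, DepthGroup, LamellarModelParams, ThermogramParams


class TestGenThermogram:
    def test_peak_at_tm_depe_like(self):
        # gel-to-fluid transition at 35 C
        p = ThermogramParams(transitions=[(35.0, 7.0, 600.0)], t_range=(20.0, 50.0),
                             t_step=0.05)
        tg = gen_thermogram(p)
        t_peak = tg.temperature[np.argmax(tg.cp)]
        assert abs(t_peak - 35.0) <= p.t_step

    def test_zero_everything_gives_zero_trace(self):
        p = ThermogramParams(transitions=[], t_range=(10.0, 40.0), t_step=0.1)
        tg = gen_thermogram(p)
        assert np.all(tg.cp == 0.0)

    def test_integral_matches_quadrature_oracle(self):
        # independent oracle: adaptive quadrature of the closed-form peak
        dh, dhvh, tm = 6.0, 600.0, 30.0
        oracle, _ = quad(lambda t: vant_hoff_excess_cp(np.array([t]), tm, dh, dhvh)[0],
                         10.0, 50.0)
        assert oracle == pytest.approx(dh, rel=0.01)
        p = ThermogramParams(transitions=[(tm, dh, dhvh)], t_range=(10.0, 50.0),
                             t_step=0.02)
        tg = gen_thermogram(p)
        assert np.trapezoid(tg.cp, tg.temperature) == pytest.approx(6.0, abs=0.06)

    def test_total_heat_sums_over_transitions(self):
        p = ThermogramParams(transitions=[(30.0, 4.0, 500.0), (55.0, 2.0, 500.0)],
                             t_range=(15.0, 70.0), t_step=0.02)
        tg = gen_thermogram(p)
        assert np.trapezoid(tg.cp, tg.temperature) == pytest.approx(6.0, rel=0.01)

    def test_deterministic(self):
        p = ThermogramParams(transitions=[(30.0, 6.0, 600.0)], noise_sd=0.05,
                             t_range=(20.0, 40.0), t_step=0.05, seed=42)
        a, b = gen_thermogram(p), gen_thermogram(p)
        assert np.array_equal(a.cp, b.cp)

    def test_too_few_points_raises(self):
        p = ThermogramParams(transitions=[], t_range=(10.0, 11.0), t_step=0.5)
        with pytest.raises(InvalidGridError):
            gen_thermogram(p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ThermogramParams(transitions=[(30.0, -1.0, 100.0)]).validate()
        with pytest.raises(ValueError):
            # van't Hoff enthalpy below calorimetric
            ThermogramParams(transitions=[(30.0, 6.0, 1.0)]).validate()


class TestGenSaxsPattern:
    def test_bragg_maxima_at_h_over_d(self, dmpc_gel_params, saxd_grid):
        pat = gen_saxs_pattern(dmpc_gel_params, saxd_grid)
        step = saxd_grid[1] - saxd_grid[0]
        for h in (1, 2, 3):
            target = h / 64.0
            window = (saxd_grid > target - 5 * step) & (saxd_grid < target + 5 * step)
            i_local = np.argmax(pat.intensity[window])
            assert abs(saxd_grid[window][i_local] - target) <= step

    def test_nonnegative_intensity(self, dmpc_gel_params, saxd_grid):
        pat = gen_saxs_pattern(dmpc_gel_params, saxd_grid, noise_sd=1e5, seed=1)
        assert np.all(pat.intensity >= 0)

    def test_deterministic(self, dmpc_gel_params, saxd_grid):
        a = gen_saxs_pattern(dmpc_gel_params, saxd_grid, noise_sd=10.0, seed=5)
        b = gen_saxs_pattern(dmpc_gel_params, saxd_grid, noise_sd=10.0, seed=5)
        assert np.array_equal(a.intensity, b.intensity)

    def test_no_bragg_order_in_window_warns(self, dmpc_gel_params):
        narrow = np.linspace(0.020, 0.025, 60)  # between orders 1 and 2
        pat = gen_saxs_pattern(dmpc_gel_params, narrow)
        assert pat.warnings

    def test_roundtrip_refit_recovers_parameters(self, dmpc_gel_params, saxd_grid):
        pat = gen_saxs_pattern(dmpc_gel_params, saxd_grid)
        init = LamellarModelParams(d=62.0, zH=18.5, sigmaH=3.4, sigmaC=6.0,
                                   rho_ratio=-0.8, n_lamellae=25, eta=0.0)
        fit = saxd.fit_saxs(pat, init)
        assert fit.d == pytest.approx(64.0, rel=0.02)
        assert fit.zH == pytest.approx(19.5, rel=0.02)
        assert fit.sigmaH == pytest.approx(3.0, rel=0.02)
        assert fit.sigmaC == pytest.approx(5.4, rel=0.02)


class TestGenHexagonalPattern:
    def test_maxima_at_hexagonal_positions(self, saxd_grid):
        # closed-form law sqrt(h^2+hk+k^2)/d10
        d10 = 60.0
        pat = gen_hexagonal_pattern(d10, saxd_grid)
        step = saxd_grid[1] - saxd_grid[0]
        for r in (1.0, np.sqrt(3.0), 2.0, np.sqrt(7.0)):
            target = r / d10
            window = (saxd_grid > target - 5 * step) & (saxd_grid < target + 5 * step)
            i_local = np.argmax(pat.intensity[window])
            assert abs(saxd_grid[window][i_local] - target) <= step

    def test_single_peak_window_warns(self):
        grid = np.linspace(0.015, 0.018, 40)
        pat = gen_hexagonal_pattern(60.0, grid)
        assert pat.warnings

    def test_classified_hexagonal(self, saxd_grid):
        pat = gen_hexagonal_pattern(60.0, saxd_grid)
        peaks = saxd.pick_peaks(pat)
        assert saxd.classify_phase_saxd(peaks).phase == "hexagonal_II"


class TestGenNoesyTable:
    def test_c2c3_ligand_gives_largest_c2c3_cross_peaks(self, depth_c2c3):
        tab = gen_noesy_table(depth_c2c3, ["III"], tm=0.3, seed=0)
        per_proton_vol = {
            lip: tab.cross[("III", lip)] / tab.diagonal[lip]
            for lip in tab.lipid_groups
        }
        top2 = sorted(per_proton_vol, key=per_proton_vol.get, reverse=True)[:2]
        assert set(top2) == {"C2", "C3"}

    def test_disjoint_distributions_give_near_zero_volume(self):
        depth = DepthDistribution([
            DepthGroup("far", 10.0, 0.1, 4, 14.0),
            DepthGroup("lig", 0.0, 0.1, 4, 13.0),
        ])
        tab = gen_noesy_table(depth, ["lig"], tm=0.3)
        assert tab.cross[("lig", "far")] < 1e-12 * max(tab.diagonal.values())

    def test_roundtrip_modal_location(self, depth_c2c3):
        for seed in range(20):
            tab = gen_noesy_table(depth_c2c3, ["III", "IV"], tm=0.3, seed=seed,
                                  noise_frac=0.05)
            loc = nmr.location_profile(nmr.cross_relaxation_rates(tab))
            assert loc.modal["III"] in ("C2", "C3")
            assert loc.modal["IV"] in ("C2", "C3")

    def test_scale_invariance_of_downstream_rates(self, depth_c2c3):
        t1 = gen_noesy_table(depth_c2c3, ["III"], tm=0.3, scale=100.0, seed=1)
        t2 = gen_noesy_table(depth_c2c3, ["III"], tm=0.3, scale=700.0, seed=1)
        r1 = nmr.cross_relaxation_rates(t1).rates
        r2 = nmr.cross_relaxation_rates(t2).rates
        for pair in r1:
            assert r1[pair] == pytest.approx(r2[pair], rel=1e-12)

    def test_empty_ligand_list_rejected(self, depth_c2c3):
        with pytest.raises(InvalidInputError):
            gen_noesy_table(depth_c2c3, [], tm=0.3)


class TestGenTrajectory:
    def test_single_atom_single_frame(self):
        depth = DepthDistribution([DepthGroup("a", 0.5, 0.2, 1, 12.0)])
        traj = gen_trajectory(depth, n_frames=1, box=(4.0, 4.0, 8.0), seed=0)
        assert traj.n_frames == 1
        assert traj.frames[0]["a"].shape == (1, 3)

    def test_sampled_z_sd_matches_oracle(self):
        # sampling oracle: empirical sd over 1e4 draws within 5%
        depth = DepthDistribution([DepthGroup("a", 1.0, 0.4, 100, 12.0)])
        traj = gen_trajectory(depth, n_frames=100, box=(4.0, 4.0, 10.0), seed=3)
        z = np.concatenate([fr["a"][:, 2] for fr in traj.frames]) - 5.0
        assert np.std(z) == pytest.approx(0.4, rel=0.05)
        assert np.mean(z) == pytest.approx(1.0, abs=3 * 0.4 / np.sqrt(z.size))

    def test_zero_atom_group_omitted_with_warning(self):
        depth = DepthDistribution([DepthGroup("a", 0.0, 0.2, 2, 12.0),
                                   DepthGroup("b", 0.0, 0.2, 0, 12.0)])
        with pytest.warns(UserWarning):
            traj = gen_trajectory(depth, n_frames=2, box=(3.0, 3.0, 6.0), seed=0)
        assert "b" not in traj.group_labels

    def test_atom_counts_conserved_and_coords_in_box(self):
        depth = DepthDistribution([DepthGroup("a", 0.0, 3.0, 7, 12.0)])
        traj = gen_trajectory(depth, n_frames=5, box=(3.0, 3.0, 6.0), seed=1)
        for fr in traj.frames:
            assert fr["a"].shape == (7, 3)
            assert np.all(fr["a"] >= 0) and np.all(fr["a"] < [3.0, 3.0, 6.0])


class TestGen31pSpectrum:
    def test_lamellar_edge_span_matches_powder_oracle(self):
        # powder-average oracle: span of shift(theta) over a dense grid
        ds = -40.0
        theta = np.deg2rad(np.linspace(0.0, 90.0, 20001))
        shifts = -(ds / 3.0) * (3.0 * np.cos(theta) ** 2 - 1.0)
        oracle_span = shifts.max() - shifts.min()
        sp = nmr.simulate_31p_lineshape(ds, "lamellar", lb=0.0)
        support = sp.ppm[sp.intensity > 0]
        assert support.max() - support.min() == pytest.approx(oracle_span, abs=1.0)
        assert oracle_span == pytest.approx(40.0, abs=1e-9)

    def test_hexagonal_is_lamellar_at_minus_half_delta(self):
        window = (-50.0, 50.0)
        hx = gen_31p_spectrum(-40.0, "hexagonal", lb=50.0, noise_sd=0.0,
                              ppm_window=window)
        lam_eq = nmr.simulate_31p_lineshape(20.0, "lamellar", lb=50.0,
                                            ppm_window=window)
        assert np.allclose(hx.intensity, lam_eq.intensity)

    def test_isotropic_symmetric(self):
        sp = gen_31p_spectrum(0.0, "isotropic", lb=100.0)
        c = nmr.classify_31p(sp)
        assert abs(c.skewness) < 0.05

    def test_lorentzian_broadening_width(self):
        # an isotropic line broadened by lb Hz has FWHM lb/field ppm
        lb, field = 100.0, 242.9
        sp = gen_31p_spectrum(0.0, "isotropic", lb=lb, field_MHz=field)
        y = sp.intensity
        half = 0.5 * y.max()
        above = sp.ppm[y >= half]
        fwhm = above.max() - above.min()
        assert fwhm == pytest.approx(lb / field, rel=0.15)

    def test_deterministic(self):
        a = gen_31p_spectrum(-40.0, "lamellar", seed=2, noise_sd=0.05)
        b = gen_31p_spectrum(-40.0, "lamellar", seed=2, noise_sd=0.05)
        assert np.array_equal(a.intensity, b.intensity)


def test_gaussian_overlap_closed_form():
    # overlap of two identical unit Gaussians equals 1/(2 sqrt(pi) sd)
    sd = 0.3
    assert gaussian_overlap(0.0, sd, 0.0, sd) == pytest.approx(
        1.0 / (2.0 * np.sqrt(np.pi) * sd))
    # numeric oracle on a grid
    z = np.linspace(-5, 5, 20001)
    p1 = np.exp(-0.5 * ((z - 0.4) / 0.3) ** 2) / (0.3 * np.sqrt(2 * np.pi))
    p2 = np.exp(-0.5 * ((z + 0.2) / 0.5) ** 2) / (0.5 * np.sqrt(2 * np.pi))
    assert gaussian_overlap(0.4, 0.3, -0.2, 0.5) == pytest.approx(
        np.trapezoid(p1 * p2, z), rel=1e-6)
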