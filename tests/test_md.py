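import numpy as np
import pytest

from bilayerlab import md, nmr
from bilayerlab.errors import InvalidInputError, MissingGroupError
from bilayerlab.synthetic import gen_noesy_table, gen_trajectory
from bilayerlab.types import DepthDistribution, DepthGroup, GroupTrajectory


def make_traj(frames, masses, box):
    return GroupTrajectory(frames=frames, masses=masses, box=box)


class TestCenterFrames:
    def test_reference_com_zeroed(self):
        fr = {"ref": np.array([[1.0, 1.0, 1.3], [2.0, 2.0, 1.3]]),
              "x": np.array([[0.5, 0.5, 2.0]])}
        t = make_traj([fr], {"ref": np.ones(2), "x": np.ones(1)}, (4.0, 4.0, 8.0))
        out = md.center_frames(t, "ref")
        com = np.average(out.frames[0]["ref"][:, 2], weights=out.masses["ref"])
        assert abs(com) < 1e-9
        assert np.allclose(out.frames[0]["x"][:, :2], fr["x"][:, :2])

    def test_already_centered_unchanged(self):
        fr = {"ref": np.array([[1.0, 1.0, -0.5], [2.0, 2.0, 0.5]])}
        t = make_traj([fr], {"ref": np.ones(2)}, (4.0, 4.0, 8.0))
        out = md.center_frames(t, "ref")
        assert np.allclose(out.frames[0]["ref"], fr["ref"])

    def test_missing_reference_names_frame(self):
        fr = {"x": np.zeros((1, 3))}
        t = make_traj([fr], {"x": np.ones(1)}, (4.0, 4.0, 8.0))
        with pytest.raises(MissingGroupError) as exc:
            md.center_frames(t, "ref")
        assert exc.value.frame == 0

    def test_symmetric_bilayer_profiles_symmetric(self):
        depth = DepthDistribution([
            DepthGroup("CH3", 0.0, 0.25, 40, 15.0),
            DepthGroup("head+", 1.5, 0.2, 20, 14.0),
            DepthGroup("head-", -1.5, 0.2, 20, 14.0),
        ])
        traj = gen_trajectory(depth, n_frames=300, box=(4.0, 4.0, 8.0), seed=2)
        dp = md.mass_density_profile(md.center_frames(traj, "CH3"), bin_width=0.25)
        combined = dp.density["head+"] + dp.density["head-"]
        assert np.allclose(combined, combined[::-1], atol=0.25 * combined.max())


class TestMassDensityProfile:
    def test_single_fixed_atom_closed_form(self):
        fr = {"a": np.array([[1.0, 1.0, 0.0]])}
        t = make_traj([fr], {"a": np.array([10.0])}, (4.0, 4.0, 2.0))
        dp = md.mass_density_profile(t, bin_width=0.1)
        nonzero = np.nonzero(dp.density["a"])[0]
        assert nonzero.size == 1
        expected = 10.0 / (4.0 * 4.0 * 0.1) * md.DA_PER_NM3_TO_KG_M3
        assert dp.density["a"][nonzero[0]] == pytest.approx(expected)

    def test_mass_conserved_exactly(self):
        depth = DepthDistribution([DepthGroup("a", 0.3, 0.5, 17, 13.5)])
        traj = gen_trajectory(depth, n_frames=7, box=(3.0, 3.0, 6.0), seed=4)
        dp = md.mass_density_profile(md.center_frames(traj, "a"), bin_width=0.13)
        total = dp.density["a"].sum() * 3.0 * 3.0 * dp.bin_width
        assert total == pytest.approx(17 * 13.5 * md.DA_PER_NM3_TO_KG_M3, rel=1e-12)

    def test_profile_mean_tracks_generator_mean(self):
        depth = DepthDistribution([DepthGroup("ref", 0.0, 0.2, 50, 15.0),
                                   DepthGroup("a", 1.2, 0.3, 50, 14.0)])
        traj = gen_trajectory(depth, n_frames=200, box=(4.0, 4.0, 10.0), seed=5)
        dp = md.mass_density_profile(md.center_frames(traj, "ref"), bin_width=0.1)
        w = dp.density["a"] / dp.density["a"].sum()
        mean_z = float(np.dot(w, dp.z_bins))
        se = 0.3 / np.sqrt(50 * 200) + 0.2 / np.sqrt(50 * 200)
        assert abs(mean_z - 1.2) < 3 * (se + 0.1)

    def test_overlap_maximal_for_colocated_groups(self, depth_c2c3):
        traj = gen_trajectory(depth_c2c3, n_frames=200, box=(4.0, 4.0, 8.0), seed=6)
        dp = md.mass_density_profile(md.center_frames(traj, "CH3"), bin_width=0.1)
        lipids = ["CH3", "(CH2)n", "CH2C=", "C3", "C2", "G1", "gamma"]
        overlaps = {g: md._profile_overlap(dp.density["III"], dp.density[g],
                                           dp.bin_width) for g in lipids}
        top2 = sorted(overlaps, key=overlaps.get, reverse=True)[:2]
        assert set(top2) <= {"C2", "C3", "G1"}

    def test_zero_box_area_rejected(self):
        fr = {"a": np.zeros((1, 3))}
        t = make_traj([fr], {"a": np.ones(1)}, (4.0, 4.0, 2.0))
        with pytest.raises(ValueError):
            md.mass_density_profile(t, bin_width=-0.1)


def brute_force_contacts(a, b, box, cutoff):
    """O(N^2) triple-loop minimum-image oracle."""
    n = 0
    for pa in a:
        for pb in b:
            d2 = 0.0
            for dim in range(3):
                delta = pa[dim] - pb[dim]
                delta -= box[dim] * round(delta / box[dim])
                d2 += delta * delta
            if d2 < cutoff * cutoff:
                n += 1
    return n


class TestCountContacts:
    def test_pair_inside_cutoff(self):
        fr = {"a": np.array([[1.0, 1.0, 1.0]]), "b": np.array([[1.0, 1.0, 1.4]])}
        t = make_traj([fr], {"a": np.ones(1), "b": np.ones(1)}, (4.0, 4.0, 4.0))
        assert md.count_contacts(t, "a", "b", 0.5).get("a", "b") == 1.0

    def test_pair_outside_cutoff(self):
        fr = {"a": np.array([[1.0, 1.0, 1.0]]), "b": np.array([[1.0, 1.0, 1.6]])}
        t = make_traj([fr], {"a": np.ones(1), "b": np.ones(1)}, (4.0, 4.0, 4.0))
        assert md.count_contacts(t, "a", "b", 0.5).get("a", "b") == 0.0

    def test_wraparound_pair_counted(self):
        # 0.1 + 0.2 across the periodic boundary -> distance 0.3
        fr = {"a": np.array([[0.1, 1.0, 1.0]]), "b": np.array([[3.8, 1.0, 1.0]])}
        t = make_traj([fr], {"a": np.ones(1), "b": np.ones(1)}, (4.0, 4.0, 4.0))
        assert md.count_contacts(t, "a", "b", 0.5).get("a", "b") == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        box = (2.0, 2.0, 3.0)
        frames = [{"a": rng.uniform(0, [2, 2, 3], (30, 3)),
                   "b": rng.uniform(0, [2, 2, 3], (30, 3))} for _ in range(10)]
        t = make_traj(frames, {"a": np.ones(30), "b": np.ones(30)}, box)
        got = md.count_contacts(t, "a", "b", 0.5)
        oracle = np.mean([brute_force_contacts(fr["a"], fr["b"], box, 0.5)
                          for fr in frames])
        assert got.get("a", "b") == oracle

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        frames = [{"a": rng.uniform(0, 3, (12, 3)), "b": rng.uniform(0, 3, (15, 3))}]
        t = make_traj(frames, {"a": np.ones(12), "b": np.ones(15)}, (3.0, 3.0, 3.0))
        assert (md.count_contacts(t, "a", "b").get("a", "b")
                == md.count_contacts(t, "b", "a").get("a", "b"))

    def test_translation_invariance_with_wrap(self):
        rng = np.random.default_rng(9)
        box = np.array([3.0, 3.0, 3.0])
        frames = [{"a": rng.uniform(0, 3, (20, 3)), "b": rng.uniform(0, 3, (20, 3))}]
        t1 = make_traj(frames, {"a": np.ones(20), "b": np.ones(20)}, tuple(box))
        shift = np.array([1.234, -0.77, 2.5])
        frames2 = [{g: (xyz + shift) % box for g, xyz in frames[0].items()}]
        t2 = make_traj(frames2, {"a": np.ones(20), "b": np.ones(20)}, tuple(box))
        assert (md.count_contacts(t1, "a", "b").get("a", "b")
                == md.count_contacts(t2, "a", "b").get("a", "b"))

    def test_same_group_rejected(self):
        fr = {"a": np.zeros((2, 3))}
        t = make_traj([fr], {"a": np.ones(2)}, (3.0, 3.0, 3.0))
        with pytest.raises(InvalidInputError):
            md.count_contacts(t, "a", "a")


class TestProfileNoesyConcordance:
    def test_identical_and_reversed_rankings(self):
        from bilayerlab.types import CrossRelaxationProfile, DensityProfile
        z = np.linspace(-2, 2, 41)
        dens = {"lig": np.exp(-0.5 * ((z - 1.0) / 0.3) ** 2)}
        for i, g in enumerate(["g1", "g2", "g3", "g4"]):
            dens[g] = np.exp(-0.5 * ((z - 1.0 + 0.4 * i) / 0.3) ** 2)
        dp = DensityProfile(z_bins=z, density=dens, bin_width=0.1)
        rates_fwd = {("lig", g): 1.0 - 0.2 * i
                     for i, g in enumerate(["g1", "g2", "g3", "g4"])}
        fwd = md.profile_noesy_concordance(
            dp, CrossRelaxationProfile(rates=rates_fwd))
        assert fwd.correlations["lig"] == pytest.approx(1.0)
        rates_rev = {("lig", g): 0.2 + 0.2 * i
                     for i, g in enumerate(["g1", "g2", "g3", "g4"])}
        rev = md.profile_noesy_concordance(
            dp, CrossRelaxationProfile(rates=rates_rev))
        assert rev.correlations["lig"] == pytest.approx(-1.0)

    def test_insufficient_shared_groups_flagged(self):
        from bilayerlab.types import CrossRelaxationProfile, DensityProfile
        z = np.linspace(-1, 1, 21)
        dp = DensityProfile(z_bins=z,
                            density={"lig": np.ones(21), "g1": np.ones(21)},
                            bin_width=0.1)
        res = md.profile_noesy_concordance(
            dp, CrossRelaxationProfile(rates={("lig", "g1"): 1.0,
                                              ("lig", "g2"): 0.5}))
        assert res.insufficient["lig"]
        assert "lig" not in res.correlations

    def test_coupled_generators_agree(self, depth_c2c3):
        # NOESY table and trajectory drawn from one depth distribution
        rhos = []
        for seed in range(20):
            tab = gen_noesy_table(depth_c2c3, ["III", "IV"], tm=0.3, seed=seed,
                                  noise_frac=0.05)
            prof = nmr.cross_relaxation_rates(tab)
            traj = gen_trajectory(depth_c2c3, n_frames=120, box=(4.0, 4.0, 8.0),
                                  seed=seed + 100)
            dp = md.mass_density_profile(md.center_frames(traj, "CH3"),
                                         bin_width=0.1)
            res = md.profile_noesy_concordance(dp, prof)
            rhos.extend(res.correlations.values())
        assert np.all(np.array(rhos) > 0.8)
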