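import numpy as np
import pytest

from calcimem import binding
from calcimem.binding import (
    AnalysisError,
    RDFResult,
    adsorption_timeline,
    contact_timeline,
    coordination_of_adsorbed,
    coordination_per_group,
    first_shell_cutoff,
    group_atom_sets,
    hydration_numbers,
    lipids_per_adsorbed_ion,
    min_image_distances,
    rdf,
    residence_times,
)
from calcimem.io import GroupTag
from calcimem.synth import SyntheticSpec, generate

from conftest import make_trajectory
from oracles import brute_count_within, brute_group_counts, brute_min_image_dist


class TestRDF:
    def test_single_pair_step(self):
        pos = np.array([[[1, 1, 1], [1, 1, 1.3]]], dtype=float)
        traj = make_trajectory(pos, [4, 4, 4])
        res = rdf(traj, np.array([0]), np.array([1]), r_max=1.0, bin_width=0.01)
        below = res.n_cum[res.r < 0.295]
        above = res.n_cum[res.r > 0.305]
        assert np.all(below == 0) and np.all(above == 1)

    def test_pair_split_across_boundary(self):
        # true separation 0.25 nm through the periodic wall
        pos = np.array([[[0.1, 2, 2], [3.85, 2, 2]]], dtype=float)
        box = np.array([4.0, 4.0, 4.0])
        traj = make_trajectory(pos, box)
        oracle = brute_min_image_dist(pos[0, :1], pos[0, 1:], box)[0, 0]
        assert oracle == pytest.approx(0.25)
        res = rdf(traj, np.array([0]), np.array([1]), r_max=1.0, bin_width=0.01)
        assert res.n_cum[np.searchsorted(res.r, 0.26)] == 1

    def test_uniform_gas_unity(self, rng):
        n, box = 600, np.array([5.0, 5.0, 5.0])
        pos = rng.uniform(0, 5, size=(8, n, 3))
        traj = make_trajectory(pos, box)
        res = rdf(traj, np.arange(n), np.arange(n), r_max=2.0, bin_width=0.1)
        # Poisson noise per bin: counts = frames * n * rho * shell * g
        shell = 4 * np.pi * res.r**2 * 0.1
        counts = traj.n_frames * n * res.reference_density * shell
        sigma = 1.0 / np.sqrt(counts)
        inner = res.r > 0.3
        assert np.all(np.abs(res.g[inner] - 1.0) < 4 * sigma[inner])

    def test_rmax_beyond_half_box_rejected(self):
        traj = make_trajectory(np.zeros((1, 2, 3)), [4, 4, 4])
        with pytest.raises(ValueError):
            rdf(traj, np.array([0]), np.array([1]), r_max=2.5)


class TestFirstShellCutoff:
    def _make(self, r, g):
        return RDFResult(r=r, g=g, n_cum=np.zeros_like(r), reference_density=1.0,
                         bin_width=r[1] - r[0])

    def test_gaussian_peak_plus_flat(self):
        r = np.arange(0.0, 1.0, 0.01)
        g = 3 * np.exp(-((r - 0.27) ** 2) / (2 * 0.03**2)) + 1.0 / (1 + np.exp(-(r - 0.4) / 0.02))
        res = first_shell_cutoff(self._make(r, g))
        assert 0.3 < res.cutoff < 0.4 and res.source == "rdf"

    def test_two_peaks_returns_first_minimum(self):
        r = np.arange(0.0, 1.2, 0.01)
        g = (3 * np.exp(-((r - 0.25) ** 2) / 0.002)
             + 5 * np.exp(-((r - 0.6) ** 2) / 0.002))
        res = first_shell_cutoff(self._make(r, g))
        assert 0.3 < res.cutoff < 0.55

    def test_monotone_falls_back_to_user_cutoff(self):
        r = np.arange(0.01, 1.0, 0.01)
        res = first_shell_cutoff(self._make(r, np.exp(r)), fallback=0.42)
        assert res.cutoff == 0.42 and res.source == "user"

    def test_featureless_without_fallback_is_error(self):
        r = np.arange(0.01, 1.0, 0.01)
        with pytest.raises(AnalysisError):
            first_shell_cutoff(self._make(r, np.exp(r)))


class TestCoordination:
    def test_two_ions_on_one_phosphate(self):
        pos = np.array([[[2, 2, 2], [2, 2, 2.2], [2, 2.2, 2]]], dtype=float)
        tags = [GroupTag.PHOS_P, GroupTag.CA, GroupTag.CA]
        traj = make_trajectory(pos, [5, 5, 5], tags=tags, resids=[1, 2, 3])
        groups = group_atom_sets(traj.topology, GroupTag.PHOS_P)
        n1, _ = coordination_per_group(traj, groups, np.array([1, 2]), 0.3)
        assert n1 == 2.0

    def test_zero_cutoff_counts_nothing(self):
        pos = np.array([[[2, 2, 2], [2, 2, 2.2]]], dtype=float)
        traj = make_trajectory(pos, [5, 5, 5],
                               tags=[GroupTag.PHOS_P, GroupTag.CA], resids=[1, 2])
        groups = group_atom_sets(traj.topology, GroupTag.PHOS_P)
        n1, _ = coordination_per_group(traj, groups, np.array([1]), 0.0)
        assert n1 == 0.0

    def test_empty_selection_rejected(self):
        traj = make_trajectory(np.zeros((1, 1, 3)), [5, 5, 5], tags=[GroupTag.CA])
        with pytest.raises(ValueError):
            coordination_per_group(traj, [], np.array([0]), 0.3)

    def test_multi_atom_group_counts_ion_once(self):
        # ion within the cutoff of both carboxylate oxygens of one group
        pos = np.array([[[2, 2, 2], [2.2, 2, 2], [2.1, 2.1, 2]]], dtype=float)
        tags = [GroupTag.COO_PS, GroupTag.COO_PS, GroupTag.CA]
        traj = make_trajectory(pos, [5, 5, 5], tags=tags, resids=[1, 1, 2])
        groups = group_atom_sets(traj.topology, GroupTag.COO_PS)
        assert len(groups) == 1
        n1, _ = coordination_per_group(traj, groups, np.array([2]), 0.3)
        assert n1 == 1.0


class TestAdsorption:
    def test_no_contacts_reports_infinity_with_warning(self):
        spec = SyntheticSpec(n_ca=5, n_frames=3, waters_per_lipid=1)  # all free
        traj, _ = generate(spec, 0)
        ions = traj.topology.indices_with_tag(GroupTag.CA)
        tl = adsorption_timeline(traj, ions)
        assert not tl.any()
        with pytest.warns(UserWarning, match="undefined"):
            assert lipids_per_adsorbed_ion(tl, 128) == np.inf

    def test_half_bound_markov_ratio(self):
        spec = SyntheticSpec(n_ca=48, p_phos=0.5, n_frames=120, waters_per_lipid=0,
                             mean_residence=0.2, sigma=0.01)
        traj, _ = generate(spec, 9)
        ions = traj.topology.indices_with_tag(GroupTag.CA)
        tl = adsorption_timeline(traj, ions)
        ratio = lipids_per_adsorbed_ion(tl, 128)
        expect = 2 * 128 / 48
        n_eff = tl.size  # frames nearly independent at residence 2*dt
        se_frac = np.sqrt(0.25 / n_eff)
        se_ratio = expect * se_frac / 0.5 * 2
        assert abs(ratio - expect) < 4 * se_ratio

    def test_coordination_of_adsorbed_bridging_construction(self):
        # one ion equidistant from exactly 3 phosphates
        p = np.array([[2, 2, 2], [2.4, 2, 2], [2.2, 2.35, 2]], dtype=float)
        ion = p.mean(axis=0)
        pos = np.vstack([p, ion[None]])[None]
        tags = [GroupTag.PHOS_P] * 3 + [GroupTag.CA]
        traj = make_trajectory(pos, [5, 5, 5], tags=tags, resids=[1, 2, 3, 4])
        groups = {GroupTag.PHOS_P: group_atom_sets(traj.topology, GroupTag.PHOS_P)}
        res = coordination_of_adsorbed(
            traj, np.array([3]), groups, {GroupTag.PHOS_P: 0.33}
        )
        assert res[GroupTag.PHOS_P][0] == 3.0

    def test_ion_bound_to_coo_and_po4_of_same_lipid(self):
        pos = np.array(
            [[[2, 2, 2], [2.2, 2, 2], [2.3, 2, 2], [2.15, 2.1, 2]]], dtype=float
        )
        tags = [GroupTag.PHOS_P, GroupTag.COO_PS, GroupTag.COO_PS, GroupTag.CA]
        traj = make_trajectory(pos, [5, 5, 5], tags=tags, resids=[1, 1, 1, 2])
        groups = {
            GroupTag.PHOS_P: group_atom_sets(traj.topology, GroupTag.PHOS_P),
            GroupTag.COO_PS: group_atom_sets(traj.topology, GroupTag.COO_PS),
        }
        res = coordination_of_adsorbed(
            traj, np.array([3]), groups,
            {GroupTag.PHOS_P: 0.33, GroupTag.COO_PS: 0.33},
        )
        assert res[GroupTag.PHOS_P][0] == 1.0
        assert res[GroupTag.COO_PS][0] == 1.0

    def test_no_adsorbed_anywhere_is_analysis_error(self):
        pos = np.array([[[1, 1, 1], [3, 3, 3]]], dtype=float)
        tags = [GroupTag.PHOS_P, GroupTag.CA]
        traj = make_trajectory(pos, [6, 6, 6], tags=tags, resids=[1, 2])
        groups = {GroupTag.PHOS_P: group_atom_sets(traj.topology, GroupTag.PHOS_P)}
        with pytest.raises(AnalysisError):
            coordination_of_adsorbed(traj, np.array([1]), groups, {GroupTag.PHOS_P: 0.33})


class TestHydration:
    def test_shell_construction_counts(self):
        spec = SyntheticSpec(
            sigma=0.0, n_frames=3, waters_per_lipid=2,
            shell_waters_carbonyl=2, shell_waters_phosphate=3,
        )
        traj, truth = generate(spec, 1)
        res = hydration_numbers(traj)
        assert res[GroupTag.CARBONYL_O_SN2][0] == pytest.approx(2.0)
        assert res[GroupTag.PHOS_P][0] == pytest.approx(3.0)
        assert res[GroupTag.CARBONYL_O_SN2][1] == pytest.approx(0.0)

    def test_boundary_water_just_outside_cutoff(self):
        pos = np.array([[[2, 2, 2], [2, 2, 2.25]]], dtype=float)
        tags = [GroupTag.CARBONYL_O_SN2, GroupTag.WATER_O]
        traj = make_trajectory(pos, [5, 5, 5], tags=tags, resids=[1, 2])
        res = hydration_numbers(traj, {GroupTag.CARBONYL_O_SN2: 0.24})
        assert res[GroupTag.CARBONYL_O_SN2][0] == 0.0

    def test_no_water_is_error(self):
        traj = make_trajectory(np.zeros((1, 1, 3)), [5, 5, 5], tags=[GroupTag.PHOS_P])
        with pytest.raises(AnalysisError):
            hydration_numbers(traj)

    def test_random_slab_matches_brute_force(self, rng):
        spec = SyntheticSpec(lipids_per_leaflet=9, sigma=0.05, n_frames=4,
                             waters_per_lipid=6, shell_waters_carbonyl=1, box_z=7.0)
        traj, _ = generate(spec, 13)
        topo = traj.topology
        waters = topo.indices_with_tag(GroupTag.WATER_O)
        groups = group_atom_sets(topo, GroupTag.CARBONYL_O_SN2)
        res = hydration_numbers(traj, {GroupTag.CARBONYL_O_SN2: 0.24})
        oracle = []
        for f in range(traj.n_frames):
            oracle.append(
                brute_group_counts(traj.positions[f], groups, waters, traj.boxes[f], 0.24)
            )
        assert res[GroupTag.CARBONYL_O_SN2][0] == pytest.approx(
            np.concatenate(oracle).mean()
        )


class TestResidence:
    def test_simple_run(self):
        res = residence_times(np.array([[1, 1, 1, 0, 0]], bool), 1.0, 0)
        np.testing.assert_allclose(res.intervals_ns, [3.0])
        assert res.first_desorption_ns[0] == 3.0

    def test_gap_bridging(self):
        tl = np.array([[1, 1, 0, 1, 1]], bool)
        res1 = residence_times(tl, 1.0, 1)
        np.testing.assert_allclose(res1.intervals_ns, [5.0])
        res0 = residence_times(tl, 1.0, 0)
        np.testing.assert_allclose(sorted(res0.intervals_ns), [2.0, 2.0])

    def test_censoring_flags(self):
        tl = np.array([[1, 1, 0, 0, 1]], bool)
        res = residence_times(tl, 1.0, 0)
        np.testing.assert_array_equal(res.censored, [True, True])

    def test_markov_mean_residence_recovery(self):
        spec = SyntheticSpec(
            n_ca=50, p_phos=0.4, n_frames=400, frame_spacing=1.0,
            mean_residence=10.0, waters_per_lipid=0, sigma=0.01,
        )
        traj, truth = generate(spec, 21)
        ions = traj.topology.indices_with_tag(GroupTag.CA)
        tl = adsorption_timeline(traj, ions)
        res = residence_times(tl, 1.0, 0)
        keep = ~res.censored
        est = res.intervals_ns[keep].mean()
        se = res.intervals_ns[keep].std(ddof=1) / np.sqrt(keep.sum())
        assert abs(est - truth.expected_residence_ns) < 3 * se


class TestInvariances:
    def test_counts_match_brute_force_on_random_frames(self, rng):
        for _ in range(5):
            n = int(rng.integers(20, 80))
            box = rng.uniform(3, 6, size=3)
            pos = rng.uniform(-2, 8, size=(n, 3))  # deliberately out of box
            traj = make_trajectory(pos[None], box,
                                   tags=[GroupTag.CA] * n, resids=np.arange(1, n + 1))
            a = rng.choice(n, size=10, replace=False)
            b = rng.choice(n, size=15, replace=False)
            cutoff = float(rng.uniform(0.3, 2.0))
            d = min_image_distances(pos[a], pos[b], box)
            oracle = brute_min_image_dist(pos[a], pos[b], box)
            np.testing.assert_allclose(d, oracle, atol=1e-10)
            assert np.array_equal(
                (d <= cutoff).sum(axis=1), brute_count_within(pos[a], pos[b], box, cutoff)
            )

    def test_translation_and_relabel_invariance(self, rng):
        spec = SyntheticSpec(n_ca=12, p_phos=0.5, n_frames=5, waters_per_lipid=0,
                             sigma=0.02)
        traj, _ = generate(spec, 31)
        topo = traj.topology
        ions = topo.indices_with_tag(GroupTag.CA)
        groups = group_atom_sets(topo, GroupTag.PHOS_P)
        n1, _ = coordination_per_group(traj, groups, ions, 0.3)
        shift = rng.uniform(-3, 3, size=3)
        traj.positions = traj.positions + shift
        n1_shift, _ = coordination_per_group(traj, groups, ions, 0.3)
        assert n1_shift == pytest.approx(n1, abs=1e-12)

    def test_rdf_cumulative_matches_direct_count_at_cutoff(self):
        spec = SyntheticSpec(n_ca=20, p_phos=0.6, n_frames=10, waters_per_lipid=0,
                             sigma=0.02)
        traj, _ = generate(spec, 37)
        topo = traj.topology
        ions = topo.indices_with_tag(GroupTag.CA)
        phos = topo.indices_with_tag(GroupTag.PHOS_P)
        cutoff = 0.3
        res = rdf(traj, phos, ions, r_max=1.0, bin_width=0.002)
        edges = res.r + res.bin_width / 2
        i = int(np.argmin(np.abs(edges - cutoff)))  # edge aligned with cutoff
        n_from_rdf = res.n_cum[i] * len(phos)
        groups = group_atom_sets(topo, GroupTag.PHOS_P)
        n1, _ = coordination_per_group(traj, groups, ions, cutoff)
        assert n_from_rdf == pytest.approx(n1 * len(groups), abs=1e-9)


def test_contact_timeline_matches_adsorption_for_full_headgroup_set():
    spec = SyntheticSpec(n_ca=10, p_phos=0.5, n_frames=20, waters_per_lipid=0,
                         mean_residence=0.3)
    traj, _ = generate(spec, 41)
    topo = traj.topology
    ions = topo.indices_with_tag(GroupTag.CA)
    heads = np.flatnonzero(
        np.array([t in binding.LIPID_TAGS for t in topo.tags])
    )
    tl_a = adsorption_timeline(traj, ions)
    tl_c = contact_timeline(traj, ions, heads, binding.DEFAULT_CONTACT_CUTOFF)
    assert np.array_equal(tl_a, tl_c)
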