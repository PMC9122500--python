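"""Clustering, precision, satisfaction, edge filtering, localization densities."""
import numpy as np
import pandas as pd
import pytest

from dcxlattice.ensemble_analysis import (cluster_models, crosslink_satisfaction,
                                          filter_models, localization_density,
                                          pairwise_rmsd, sampling_precision)
from dcxlattice.restraints import Crosslink, CrosslinkSet
from dcxlattice.sampling import Ensemble, ModelConfiguration
from dcxlattice.synthetic_data import make_toy_domain
from dcxlattice.topology import ChainSet, build_representation


def _models(coords_list, scores=None, runs=None):
    scores = scores if scores is not None else np.zeros(len(coords_list))
    runs = runs if runs is not None else np.zeros(len(coords_list), int)
    return Ensemble([ModelConfiguration(np.asarray(c, float), int(r), 0, 10 * i, s)
                     for i, (c, s, r) in enumerate(zip(coords_list, scores, runs))])


class TestRMSD:
    def test_identical_is_zero(self, rng):
        a = rng.normal(size=(7, 3))
        assert pairwise_rmsd(a, a) == 0.0

    def test_rigid_translation_gives_norm(self, rng):
        a = rng.normal(size=(9, 3))
        t = np.array([3.0, -4.0, 12.0])
        assert pairwise_rmsd(a, a + t) == pytest.approx(np.linalg.norm(t))

    def test_matches_direct_formula(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
            sel = np.array([0, 2, 5])
            want = np.sqrt(np.mean(np.sum((a[sel] - b[sel]) ** 2, axis=1)))
            assert pairwise_rmsd(a, b, sel) == pytest.approx(want)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert pairwise_rmsd(a, b) == pairwise_rmsd(b, a)


class TestClustering:
    def test_identical_models_one_cluster_zero_precision(self):
        coords = [np.ones((4, 3))] * 6
        cl = cluster_models(np.stack(coords), np.zeros(6), threshold=1.0)
        assert len(cl) == 1
        assert cl[0].precision == 0.0
        assert cl[0].population == 1.0

    def test_two_separated_groups(self, rng):
        g1 = [rng.normal(0, 1, (4, 3)) for _ in range(8)]
        g2 = [rng.normal(0, 1, (4, 3)) + np.array([100.0, 0, 0]) for _ in range(5)]
        stack = np.stack(g1 + g2)
        cl = cluster_models(stack, np.zeros(13), threshold=10.0)
        assert len(cl) == 2
        assert sorted(len(c.members) for c in cl) == [5, 8]
        assert {frozenset(c.members) for c in cl} == \
            {frozenset(range(8)), frozenset(range(8, 13))}

    def test_threshold_above_diameter_single_cluster(self, rng):
        stack = rng.normal(0, 5, size=(12, 4, 3))
        cl = cluster_models(stack, np.zeros(12), threshold=1e6)
        assert len(cl) == 1

    def test_two_member_cluster_precision_is_half_rmsd(self):
        a = np.zeros((4, 3))
        b = np.zeros((4, 3))
        b[:, 0] = 6.0  # RMSD(a, b) = 6
        cl = cluster_models(np.stack([a, b]), np.zeros(2), threshold=10.0)
        assert len(cl) == 1
        assert cl[0].precision == pytest.approx(3.0)

    def test_populations_partition_filtered_ensemble(self, rng):
        stack = rng.normal(0, 30, size=(40, 3, 3))
        cl = cluster_models(stack, rng.normal(size=40), threshold=15.0)
        members = [m for c in cl for m in c.members]
        assert sorted(members) == list(range(40))
        assert sum(c.population for c in cl) == pytest.approx(1.0)


class TestSamplingPrecision:
    def grid(self):
        return [1.0, 2.0, 5.0, 10.0, 20.0]

    def test_unimodal_passes_at_smallest_threshold(self, rng):
        stack = rng.normal(0, 0.2, size=(60, 4, 3))
        runs = np.repeat([0, 1, 2, 3], 15)
        prec, table = sampling_precision(stack, np.zeros(60), runs, self.grid())
        assert prec == 1.0
        assert table["passed"].all()

    def test_bimodal_fails_below_mode_gap(self, rng):
        # half A at the origin, half B split between origin and a mode 50 A away
        a = rng.normal(0, 0.5, size=(30, 4, 3))
        b = rng.normal(0, 0.5, size=(30, 4, 3)) + np.array([50.0, 0, 0])
        stack = np.concatenate([a, b])
        runs = np.array([0] * 30 + [1] * 30)
        prec, table = sampling_precision(stack, np.zeros(60), runs,
                                         [1.0, 5.0, 20.0, 40.0])
        failed = table[table["threshold"] < 50.0]
        assert not failed["passed"].any()
        assert prec == np.inf

    def test_single_run_errors(self, rng):
        stack = rng.normal(size=(10, 4, 3))
        with pytest.raises(ValueError, match="2 independent runs"):
            sampling_precision(stack, np.zeros(10), np.zeros(10, int), self.grid())

    def test_pass_is_monotone_on_well_mixed_data(self, rng):
        stack = rng.normal(0, 2.0, size=(80, 4, 3))
        runs = np.repeat([0, 1], 40)
        _, table = sampling_precision(stack, np.zeros(80), runs, self.grid())
        passed = table.sort_values("threshold")["passed"].to_numpy()
        first = np.argmax(passed)
        assert passed[first:].all()


@pytest.fixture(scope="module")
def sat_fixture():
    """Two 12-residue domains with 20 crosslinks of mixed chemistry."""
    rng = np.random.default_rng(5)
    a = make_toy_domain(12, 3, chain_id="A", entity="ndc")
    b = make_toy_domain(12, 4, chain_id="B", entity="cdc")
    for r in b.residues:
        r.ca_xyz = r.ca_xyz + np.array([20.0, 0, 0])
    topo = build_representation(ChainSet([a, b]),
                                {"ndc": [(1, 12)], "cdc": [(1, 12)]})
    xls = CrosslinkSet([
        Crosslink(f"x{i}", "ndc", frozenset([rng.integers(1, 13)]),
                  "cdc", frozenset([rng.integers(1, 13)]),
                  ["LCSDA", "DSS", "EDC"][i % 3])
        for i in range(20)
    ])
    return topo, xls


class TestSatisfaction:
    def test_all_close_fully_satisfied(self, sat_fixture):
        topo, xls = sat_fixture
        coords = topo.reference_coords().copy()
        # collapse everything within 10 A
        coords *= 10.0 / max(np.linalg.norm(coords, axis=1).max(), 1.0)
        ens = _models([coords])
        rep = crosslink_satisfaction(ens, xls, topo)
        assert rep.per_model[0] == 1.0

    @pytest.mark.parametrize("chem,thr", [("LCSDA", 35.0), ("DSS", 35.0),
                                          ("EDC", 30.0)])
    def test_boundary_is_strict(self, chem, thr):
        a = make_toy_domain(1, 0, chain_id="A", entity="ndc")
        b = make_toy_domain(1, 1, chain_id="B", entity="cdc")
        a.residues[0].ca_xyz = np.zeros(3)
        b.residues[0].ca_xyz = np.zeros(3)
        topo = build_representation(ChainSet([a, b]),
                                    {"ndc": [(1, 1)], "cdc": [(1, 1)]})
        xls = CrosslinkSet([Crosslink("x", "ndc", frozenset([1]), "cdc",
                                      frozenset([1]), chem)])
        at = topo.reference_coords().copy()
        at[topo.site_bead("B", 1)] = [thr, 0, 0]
        just_below = at.copy()
        just_below[topo.site_bead("B", 1)] = [thr - 0.1, 0, 0]
        rep = crosslink_satisfaction(_models([at, just_below]), xls, topo)
        assert rep.satisfied()[0, 0] == False  # noqa: E712  (exactly at threshold)
        assert rep.satisfied()[1, 0] == True  # noqa: E712

    def test_matches_bruteforce_oracle(self, sat_fixture, rng):
        topo, xls = sat_fixture
        from dcxlattice.restraints import resolve_crosslink

        coords_list = [topo.reference_coords() + rng.normal(0, 10, (topo.n_beads, 3))
                       for _ in range(5)]
        rep = crosslink_satisfaction(_models(coords_list), xls, topo)
        for m, coords in enumerate(coords_list):
            for k, xl in enumerate(xls):
                b1, b2 = resolve_crosslink(xl, topo)
                dmin = min(np.linalg.norm(coords[i] - coords[j])
                           for i in b1 for j in b2 if i != j)
                assert rep.min_distances[m, k] == pytest.approx(dmin)
                assert rep.satisfied()[m, k] == (dmin < xl.threshold)

    def test_cluster_satisfaction_any_member_and_monotone(self, sat_fixture, rng):
        topo, xls = sat_fixture
        from dcxlattice.ensemble_analysis import Cluster

        coords_list = [topo.reference_coords() + rng.normal(0, 15, (topo.n_beads, 3))
                       for _ in range(6)]
        ens = _models(coords_list)
        small = Cluster(members=[0, 1], centroid=0, population=0.5, precision=0)
        big = Cluster(members=[0, 1, 2], centroid=0, population=0.75, precision=0)
        rep = crosslink_satisfaction(ens, xls, topo, clusters=[small, big])
        assert rep.per_cluster[0] >= rep.per_model[[0, 1]].max()
        assert rep.per_cluster[1] >= rep.per_cluster[0]


class TestEdgeFilter:
    def test_interior_kept_corner_removed(self, toy_lattice, stage1_clean):
        inputs, _ = stage1_clean
        patch = inputs.patch
        sel = inputs.mobile_selection
        interior = inputs.truth_coords.copy()  # truth sits at an interior junction
        corner = inputs.truth_coords.copy()
        corner_pos = patch.junction_by_id((-1, -1)).position + np.array([0, 0, 20.0])
        corner[sel] += corner_pos - corner[sel].mean(axis=0)
        ens = _models([interior, corner])
        kept, idx = filter_models(ens, patch, sel, score_quantile=1.0)
        assert list(idx) == [0]

    def test_filter_matches_bruteforce_on_random_placements(self, stage1_clean, rng):
        inputs, _ = stage1_clean
        patch, sel = inputs.patch, inputs.mobile_selection
        juncs = [(j.position, j.interior) for j in patch.junctions]
        coords_list, want_keep = [], []
        for i in range(100):
            c = inputs.truth_coords.copy()
            target = rng.uniform([-40, -40, 10], [150, 210, 40])
            c[sel] += target - c[sel].mean(axis=0)
            coords_list.append(c)
            centroid = c[sel].mean(axis=0)
            ds = [np.linalg.norm(p - centroid) for p, _ in juncs]
            want_keep.append(juncs[int(np.argmin(ds))][1])
        ens = _models(coords_list)
        _, idx = filter_models(ens, patch, sel, score_quantile=1.0)
        assert sorted(idx) == [i for i, k in enumerate(want_keep) if k]

    def test_score_quantile_keeps_best_half(self, stage1_clean, rng):
        inputs, _ = stage1_clean
        scores = np.arange(10.0)
        ens = _models([inputs.truth_coords] * 10, scores=scores)
        _, idx = filter_models(ens, inputs.patch, inputs.mobile_selection,
                               score_quantile=0.5)
        assert list(idx) == [0, 1, 2, 3, 4]  # quantile(0..9, 0.5) = 4.5


class TestLocalizationDensity:
    def _component(self, rng, n=3):
        centers = rng.uniform(10, 40, size=(n, 3))
        radii = np.full(n, 3.0)
        masses = np.full(n, 500.0)
        return centers, radii, masses

    def test_single_model_maxima_at_beads(self, rng):
        centers, radii, masses = self._component(rng)
        ens = _models([centers])
        dm = localization_density(ens, [0], np.arange(3), radii, masses, voxel=1.0)
        for c in centers:
            ijk = np.round((c - dm.origin) / dm.voxel_size).astype(int)
            window = dm.data[max(0, ijk[0] - 4): ijk[0] + 5,
                             max(0, ijk[1] - 4): ijk[1] + 5,
                             max(0, ijk[2] - 4): ijk[2] + 5]
            assert dm.data[tuple(ijk)] >= 0.7 * window.max()

    def test_integral_matches_component_mass(self, rng):
        centers, radii, masses = self._component(rng)
        ens = _models([centers, centers + 2.0])
        dm = localization_density(ens, [0, 1], np.arange(3), radii, masses,
                                  voxel=1.0)
        assert dm.integral() == pytest.approx(masses.sum(), rel=0.01)

    def test_two_translated_models_give_bimodal_map(self, rng):
        centers = np.array([[20.0, 20, 20]])
        ens = _models([centers, centers + np.array([30.0, 0, 0])])
        dm = localization_density(ens, [0, 1], np.array([0]), np.array([2.5]),
                                  np.array([100.0]), voxel=1.0)
        profile = dm.data.max(axis=(1, 2))
        peaks = np.nonzero((profile > np.roll(profile, 1))
                           & (profile > np.roll(profile, -1))
                           & (profile > 0.3 * profile.max()))[0]
        assert len(peaks) == 2
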