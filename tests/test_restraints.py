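"""Restraint terms against closed forms and independent brute-force oracles."""
import numpy as np
import pytest

from dcxlattice.restraints import (GMM, Crosslink, CrosslinkSet, RestraintParams,
                                   ScoringSystem, beads_to_gmm, crosslink_score,
                                   em_cross_correlation, em_score,
                                   excluded_volume_score, connectivity_score,
                                   fit_map_gmm, resolve_crosslink, total_score)
from dcxlattice.synthetic_data import make_toy_domain, simulate_density
from dcxlattice.topology import Bead, ChainSet, Topology, build_representation


# ---------------------------------------------------------------------------
# hand-built fixtures

def two_point_system(d, chemistry="LCSDA"):
    """Two single-residue 'domains' separated by distance d."""
    a = make_toy_domain(1, 0, chain_id="A", entity="ndc")
    b = make_toy_domain(1, 1, chain_id="B", entity="cdc")
    a.residues[0].ca_xyz = np.zeros(3)
    b.residues[0].ca_xyz = np.array([d, 0.0, 0.0])
    topo = build_representation(ChainSet([a, b]),
                                {"ndc": [(1, 1)], "cdc": [(1, 1)]})
    xl = Crosslink("x1", "ndc", frozenset([1]), "cdc", frozenset([1]), chemistry)
    return topo, CrosslinkSet([xl])


def bare_bead_topology(centers, radii, bonds=()):
    beads = [Bead(i, "A", (i + 1, i + 1), np.asarray(c, float), r, 100.0)
             for i, (c, r) in enumerate(zip(centers, radii))]
    return Topology(beads, [], [], list(bonds), {"A": "other"})


# ---------------------------------------------------------------------------
# independent oracles (plain-python enumeration)

def oracle_crosslink(coords, xls, topo, params):
    total = 0.0
    for xl in xls:
        b1, b2 = resolve_crosslink(xl, topo)
        prod = 1.0
        beads = topo.all_beads
        for i in b1:
            for j in b2:
                if xl.inter_copy_only:
                    if beads[i].chain_id == beads[j].chain_id:
                        continue
                elif i == j:
                    continue
                d = np.linalg.norm(coords[i] - coords[j])
                p = 1.0 / (1.0 + np.exp((d - xl.d0) / params.lam))
                prod *= 1.0 - p
        P = 1.0 - prod
        total += -np.log((1 - params.psi) * P + params.psi * (1 - P))
    return total


def oracle_excluded_volume(coords, topo, k=1.0):
    total = 0.0
    sb = topo.beads
    bonds = {frozenset(p) for p in topo.bonded_pairs}
    for a in range(len(sb)):
        for b in range(a + 1, len(sb)):
            i, j = sb[a].id, sb[b].id
            if (sb[a].in_rigid_body is not None
                    and sb[a].in_rigid_body == sb[b].in_rigid_body):
                continue
            if frozenset((i, j)) in bonds:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            total += 0.5 * k * max(0.0, sb[a].radius + sb[b].radius - d) ** 2
    return total


def oracle_connectivity(coords, topo, k=1.0):
    radii = {b.id: b.radius for b in topo.all_beads}
    total = 0.0
    for i, j in topo.bonded_pairs:
        c = 2.0 * (radii[i] + radii[j])
        d = np.linalg.norm(coords[i] - coords[j])
        total += 0.5 * k * max(0.0, d - c) ** 2
    return total


def oracle_gmm_overlap_quadrature(f: GMM, g: GMM, n=80):
    """Numerical grid integration of the product density."""
    all_mu = np.vstack([f.means, g.means])
    spread = 4.0 * np.sqrt(max(np.linalg.eigvalsh(c).max()
                               for c in np.vstack([f.covariances, g.covariances])))
    lo = all_mu.min(axis=0) - spread
    hi = all_mu.max(axis=0) + spread
    axes = [np.linspace(lo[k], hi[k], n) for k in range(3)]
    dv = np.prod([(a[1] - a[0]) for a in axes])
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    def density(gmm):
        out = np.zeros(len(pts))
        for w, mu, cov in zip(gmm.weights, gmm.means, gmm.covariances):
            inv = np.linalg.inv(cov)
            det = np.linalg.det(cov)
            dx = pts - mu
            q = np.einsum("ij,jk,ik->i", dx, inv, dx)
            out += w * np.exp(-0.5 * q) / np.sqrt((2 * np.pi) ** 3 * det)
        return out

    return float(np.sum(density(f) * density(g)) * dv)


# ---------------------------------------------------------------------------

class TestCrosslinkScore:
    def test_sigmoid_midpoint_exact(self):
        """A single unambiguous crosslink at exactly d0 scores -log(0.5)."""
        params = RestraintParams()
        topo, xls = two_point_system(30.0)
        coords = topo.reference_coords()
        assert crosslink_score(coords, xls, topo, params) == pytest.approx(np.log(2.0))

    def test_psi_half_degeneracy(self):
        params = RestraintParams(psi=0.5)
        for d in (2.0, 30.0, 500.0):
            topo, xls = two_point_system(d)
            s = crosslink_score(topo.reference_coords(), xls, topo, params)
            assert s == pytest.approx(np.log(2.0))

    def test_copy_ambiguity_rescues_far_site(self):
        """One near + one far copy scores lower than the far-only case."""
        params = RestraintParams()
        a = make_toy_domain(1, 0, chain_id="A", entity="ndc")
        b1 = make_toy_domain(1, 1, chain_id="B", entity="cdc")
        b2 = make_toy_domain(1, 2, chain_id="C", entity="cdc")
        a.residues[0].ca_xyz = np.zeros(3)
        b1.residues[0].ca_xyz = np.array([5.0, 0, 0])     # d << d0
        b2.residues[0].ca_xyz = np.array([90.0, 0, 0])    # d >> d0
        topo2 = build_representation(ChainSet([a, b1, b2]),
                                     {"ndc": [(1, 1)], "cdc": [(1, 1)]})
        xl = Crosslink("x", "ndc", frozenset([1]), "cdc", frozenset([1]), "LCSDA")
        s_both = crosslink_score(topo2.reference_coords(), CrosslinkSet([xl]),
                                 topo2, params)
        topo_far, xls_far = two_point_system(90.0)
        s_far = crosslink_score(topo_far.reference_coords(), xls_far, topo_far, params)
        assert s_both < s_far
        assert s_both == pytest.approx(
            oracle_crosslink(topo2.reference_coords(), CrosslinkSet([xl]), topo2, params))

    def test_end_swap_symmetry(self):
        params = RestraintParams()
        topo, _ = two_point_system(20.0)
        fwd = Crosslink("f", "ndc", frozenset([1]), "cdc", frozenset([1]), "DSS")
        rev = Crosslink("r", "cdc", frozenset([1]), "ndc", frozenset([1]), "DSS")
        c = topo.reference_coords()
        assert crosslink_score(c, CrosslinkSet([fwd]), topo, params) == \
            pytest.approx(crosslink_score(c, CrosslinkSet([rev]), topo, params))

    def test_monotone_in_distance(self):
        params = RestraintParams()
        scores = []
        for d in np.linspace(1.0, 80.0, 25):
            topo, xls = two_point_system(d)
            scores.append(crosslink_score(topo.reference_coords(), xls, topo, params))
        assert np.all(np.diff(scores) >= -1e-12)

    def test_lower_bound_attained_near_contact(self):
        params = RestraintParams()
        topo, xls = two_point_system(0.5)
        s = crosslink_score(topo.reference_coords(), xls, topo, params)
        bound = -len(xls) * np.log(1 - params.psi)
        assert s >= bound - 1e-12
        assert s == pytest.approx(bound, abs=1e-6)

    def test_unresolvable_site_reports_id(self):
        topo, _ = two_point_system(10.0)
        bad = Crosslink("bad7", "ndc", frozenset([99]), "cdc", frozenset([1]), "EDC")
        with pytest.raises(ValueError, match="bad7"):
            crosslink_score(topo.reference_coords(), CrosslinkSet([bad]), topo,
                            RestraintParams())

    def test_psi_out_of_range(self):
        with pytest.raises(ValueError, match="psi"):
            RestraintParams(psi=0.7)


class TestPhysicalTerms:
    def test_ev_formula_full_overlap(self):
        topo = bare_bead_topology([[0, 0, 0], [0, 0, 0]], [5.0, 5.0])
        assert excluded_volume_score(topo.reference_coords(), topo) == pytest.approx(50.0)

    def test_ev_zero_without_overlap(self):
        topo = bare_bead_topology([[0, 0, 0], [20, 0, 0]], [5.0, 5.0])
        assert excluded_volume_score(topo.reference_coords(), topo) == 0.0

    def test_ev_matches_allpairs_oracle_on_random_beads(self, rng):
        centers = rng.uniform(0, 30, size=(50, 3))
        radii = rng.uniform(2, 6, size=50)
        bonds = [(i, i + 1) for i in range(0, 48, 7)]
        topo = bare_bead_topology(centers, radii, bonds)
        got = excluded_volume_score(topo.reference_coords(), topo)
        want = oracle_excluded_volume(topo.reference_coords(), topo)
        assert got == pytest.approx(want, rel=1e-10)
        assert got > 0

    def test_connectivity_boundary_and_formula(self):
        r = 3.0
        c = 2 * (r + r)
        topo = bare_bead_topology([[0, 0, 0], [c, 0, 0]], [r, r], bonds=[(0, 1)])
        assert connectivity_score(topo.reference_coords(), topo) == 0.0
        topo2 = bare_bead_topology([[0, 0, 0], [c + 2.0, 0, 0]], [r, r], bonds=[(0, 1)])
        assert connectivity_score(topo2.reference_coords(), topo2) == pytest.approx(2.0)

    def test_connected_chain_within_bounds_scores_zero(self):
        centers = [[4.0 * i, 0, 0] for i in range(5)]
        topo = bare_bead_topology(centers, [2.0] * 5,
                                  bonds=[(i, i + 1) for i in range(4)])
        assert connectivity_score(topo.reference_coords(), topo) == 0.0


class TestGMMAndEM:
    def test_beads_to_gmm_weights_are_masses(self):
        g = beads_to_gmm(np.zeros((3, 3)), [2.0, 3.0, 4.0], [10.0, 20.0, 30.0])
        assert g.n_components == 3
        assert g.weights.sum() == pytest.approx(60.0)

    def test_identical_gmms_correlate_perfectly(self, rng):
        g = beads_to_gmm(rng.normal(size=(4, 3)) * 10, rng.uniform(2, 5, 4),
                         rng.uniform(1, 9, 4))
        assert em_cross_correlation(g, g) == pytest.approx(1.0)
        assert em_score(g, g, RestraintParams()) == pytest.approx(0.0, abs=1e-9)

    def test_distant_gmms_do_not_overlap(self):
        g1 = beads_to_gmm([[0, 0, 0]], [3.0], [1.0])
        g2 = beads_to_gmm([[1000, 0, 0]], [3.0], [1.0])
        p = RestraintParams()
        assert em_score(g1, g2, p) == pytest.approx(p.w_em)

    def test_cc_matches_quadrature_oracle(self, rng):
        def random_gmm():
            means = rng.uniform(-10, 10, size=(3, 3))
            covs = []
            for _ in range(3):
                A = rng.normal(size=(3, 3))
                covs.append(A @ A.T + 4.0 * np.eye(3))
            return GMM(rng.uniform(0.5, 2.0, 3), means, np.array(covs))

        f, g = random_gmm(), random_gmm()
        from dcxlattice.restraints import gmm_overlap

        want = oracle_gmm_overlap_quadrature(f, g)
        assert gmm_overlap(f, g) == pytest.approx(want, rel=1e-3)

    def test_fit_map_gmm_recovers_two_component_mixture(self):
        centers = np.array([[0.0, 0, 0], [24.0, 0, 0]])
        dm = simulate_density(centers, [4.0, 4.0], [1.0, 1.0], resolution=6.0,
                              voxel=2.0)
        g = fit_map_gmm(dm, 2, seed=5)
        rec = g.means[np.argsort(g.means[:, 0])]
        assert np.abs(rec - centers).max() < dm.voxel_size

    def test_fit_map_gmm_invalid_inputs(self):
        dm = simulate_density(np.zeros((1, 3)), [3.0], [1.0])
        with pytest.raises(ValueError, match="n_components"):
            fit_map_gmm(dm, 0, seed=0)
        empty = simulate_density(np.zeros((1, 3)), [3.0], [1.0])
        empty.data[:] = 0.0
        with pytest.raises(ValueError, match="empty"):
            fit_map_gmm(empty, 1, seed=0, floor=1.0)

    def test_gmm_table_round_trip(self, tmp_path, rng):
        g = beads_to_gmm(rng.normal(size=(3, 3)), [2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        g.to_table(tmp_path / "g.csv")
        g2 = GMM.from_table(tmp_path / "g.csv")
        np.testing.assert_allclose(g2.means, g.means)
        np.testing.assert_allclose(g2.covariances, g.covariances)


@pytest.fixture(scope="module")
def small_system():
    a = make_toy_domain(12, 3, chain_id="A", entity="ndc")
    b = make_toy_domain(12, 4, chain_id="B", entity="cdc")
    for r in b.residues:
        r.ca_xyz = r.ca_xyz + np.array([18.0, 0, 0])
    topo = build_representation(ChainSet([a, b]),
                                {"ndc": [(1, 12)], "cdc": [(1, 12)]})
    xls = CrosslinkSet([
        Crosslink(f"x{i}", "ndc", frozenset([i + 1]), "cdc",
                  frozenset([i + 2]), chem)
        for i, chem in enumerate(["LCSDA", "DSS", "EDC", "LCSDA", "EDC"])
    ])
    return ScoringSystem(topo, xls, RestraintParams())


class TestTotalScore:
    def test_total_is_sum_of_terms(self, small_system):
        total, terms = total_score(small_system.topology.reference_coords(),
                                   small_system)
        assert total == pytest.approx(sum(terms.values()))
        assert set(terms) == {"crosslink", "excluded_volume", "connectivity"}

    def test_matches_oracles_on_random_configurations(self, small_system, rng):
        topo = small_system.topology
        params = small_system.params
        for _ in range(10):
            coords = topo.reference_coords() + rng.normal(0, 8.0,
                                                          size=(topo.n_beads, 3))
            total, terms = small_system.score(coords)
            assert terms["crosslink"] == pytest.approx(
                oracle_crosslink(coords, small_system.xls, topo, params), rel=1e-9)
            assert terms["excluded_volume"] == pytest.approx(
                oracle_excluded_volume(coords, topo), rel=1e-9)
            assert terms["connectivity"] == pytest.approx(
                oracle_connectivity(coords, topo), rel=1e-9)

    def test_rigid_motion_invariance(self, small_system, rng):
        from dcxlattice.geometry import random_rotation_uniform

        coords = small_system.topology.reference_coords()
        R = random_rotation_uniform(rng)
        t = rng.normal(0, 50, 3)
        moved = coords @ R.T + t
        s0, _ = small_system.score(coords)
        s1, _ = small_system.score(moved)
        assert s1 == pytest.approx(s0, abs=1e-8)

    def test_em_term_translation_invariance_of_cc(self, rng):
        g1 = beads_to_gmm(rng.normal(size=(3, 3)) * 5, [3.0] * 3, [1.0] * 3)
        g2 = beads_to_gmm(rng.normal(size=(3, 3)) * 5, [4.0] * 3, [2.0] * 3)
        t = np.array([30.0, -12.0, 7.0])
        g1t = GMM(g1.weights, g1.means + t, g1.covariances)
        g2t = GMM(g2.weights, g2.means + t, g2.covariances)
        assert em_cross_correlation(g1t, g2t) == pytest.approx(
            em_cross_correlation(g1, g2), rel=1e-10)


class TestCrosslinkCSV:
    def test_round_trip_bit_exact(self, tmp_path):
        from dcxlattice.synthetic_data import make_toy_lattice, simulate_crosslinks

        chains, _ = make_toy_lattice(2, 2, seed=3, monomer_n_residues=20)
        dom = ChainSet([make_toy_domain(10, 5, chain_id="X", entity="ndc")])
        for r in dom.chains[0].residues:
            r.ca_xyz = r.ca_xyz + chains.chains[0].centroid() + np.array([0, 0, 25.0])
        xls, _ = simulate_crosslinks(dom, chains, 8, decoy_fraction=0.25,
                                     seed=1, site_ambiguity=1,
                                     copy_specific=(False, True))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        xls.to_csv(p1)
        CrosslinkSet.from_csv(p1).to_csv(p2)
        assert p1.read_text() == p2.read_text()
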