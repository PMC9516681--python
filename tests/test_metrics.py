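import numpy as np
import pytest

from permeus import metrics as met
from permeus import synthetic as syn
from permeus.core import TrajectorySeries


def _frame(coords, elements, donors=(), acceptors=(), radii=None):
    return met.ConformerFrame(
        np.asarray(coords, float), list(elements), radii,
        donors=list(donors), acceptors=list(acceptors),
    )


def hbond_oracle(frame, d_max=3.5, angle_min=135.0):
    """Vectorized all-pairs H-bond count, coded independently of the
    implementation under test."""
    X = frame.coords
    count = 0
    for h, d in frame.donors:
        for a in frame.acceptors:
            if a in (d, h):
                continue
            if np.sqrt(((X[a] - X[d]) ** 2).sum()) > d_max:
                continue
            v1, v2 = X[d] - X[h], X[a] - X[h]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                count += 1
    return count


def random_frame(rng, n_units=6):
    """Random N-H / O soup in an 8 A box with valid donor bookkeeping."""
    coords, elements, donors, acceptors = [], [], [], []
    for _ in range(n_units):
        d = rng.uniform(0, 8, 3)
        h = d + rng.normal(0, 0.7, 3)
        a = rng.uniform(0, 8, 3)
        base = len(coords)
        coords += [d, h, a]
        elements += ["N", "H", "O"]
        donors.append((base + 1, base))
        acceptors.append(base + 2)
    return _frame(coords, elements, donors, acceptors)


class TestHbonds:
    def test_collinear_contact_counts(self):
        f = _frame(
            [[0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]], "NHO",
            donors=[(1, 0)], acceptors=[2],
        )
        assert met.count_hbonds(f) == 1

    def test_distant_pair_rejected_by_default_cutoff(self):
        f = _frame(
            [[0, 0, 0], [1.0, 0, 0], [5.0, 0, 0]], "NHO",
            donors=[(1, 0)], acceptors=[2],
        )
        assert met.count_hbonds(f) == 0

    def test_bent_geometry_rejected_by_angle(self):
        # acceptor at 90 degrees off the D-H axis, within distance
        f = _frame(
            [[0, 0, 0], [1.0, 0, 0], [1.0, 2.0, 0]], "NHO",
            donors=[(1, 0)], acceptors=[2],
        )
        assert met.count_hbonds(f) == 0
        assert met.count_hbonds(f, angle_min=30.0) == 1

    def test_matches_all_pairs_oracle_on_random_frames(self):
        rng = np.random.default_rng(2024)
        mismatches = 0
        for _ in range(1000):
            f = random_frame(rng)
            if met.count_hbonds(f) != hbond_oracle(f):
                mismatches += 1
        assert mismatches == 0

    def test_selection_restricts_partners(self):
        # donor unit 0-1 and acceptors 2 (own), 5 (other)
        f = _frame(
            [[0, 0, 0], [1, 0, 0], [2.9, 0, 0], [10, 0, 0], [11, 0, 0], [12.9, 0, 0]],
            "NHONHO",
            donors=[(1, 0), (4, 3)], acceptors=[2, 5],
        )
        assert met.count_hbonds(f) == 2
        assert met.count_hbonds(f, donor_atoms=[0], acceptor_atoms=[2]) == 1
        assert met.count_hbonds(f, donor_atoms=[0], acceptor_atoms=[5]) == 0

    def test_missing_roles_rejected(self):
        f = _frame([[0, 0, 0], [1, 0, 0]], "NH")
        with pytest.raises(ValueError, match="role"):
            met.count_hbonds(f)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        f = _frame([[0, 0, 0]], ["X"], radii=np.array([1.6]))
        area = met.sasa(f)[0]
        assert area == pytest.approx(4 * np.pi * 3.0**2, rel=1e-12)
        assert area == pytest.approx(113.1, abs=0.05)

    def test_distant_atoms_additive(self):
        f = _frame([[0, 0, 0], [100, 0, 0]], ["C", "C"])
        areas = met.sasa(f)
        assert areas[0] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2)
        assert areas[1] == areas[0]

    def test_two_sphere_overlap_matches_cap_formula(self):
        # analytic: a neighbor at distance d removes a spherical cap of
        # area 2 pi R1 h with h = R1 - (R1^2 + d^2 - R2^2)/(2 d)
        r1 = r2 = 1.7 + 1.4
        d = 2.0
        f = _frame([[0, 0, 0], [d, 0, 0]], ["C", "C"])
        h = r1 - (r1**2 + d**2 - r2**2) / (2 * d)
        expected = 4 * np.pi * r1**2 - 2 * np.pi * r1 * h
        areas = met.sasa(f, n_sphere_points=2000)
        assert areas[0] == pytest.approx(expected, rel=0.005)

    def test_caged_atom_nearly_buried(self):
        pts = met._sphere_points(60)
        coords = np.vstack([[0.0, 0.0, 0.0], 3.0 * pts])
        f = _frame(coords, ["C"] * len(coords))
        areas = met.sasa(f)
        assert areas[0] < 0.01 * 4 * np.pi * (1.7 + 1.4) ** 2

    def test_identical_coordinates_rejected(self):
        f = _frame([[0, 0, 0], [0, 0, 0]], ["C", "C"])
        with pytest.raises(ValueError, match="identical"):
            met.sasa(f)

    def test_matches_mdtraj_shrake_rupley(self):
        # independent implementation cross-check on a small random cluster
        mdtraj = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 6, (8, 3))
        f = _frame(coords, ["C"] * 8)
        top = mdtraj.Topology()
        chain = top.add_chain()
        res = top.add_residue("LIG", chain)
        for i in range(8):
            top.add_atom(f"C{i}", mdtraj.element.carbon, res)
        traj = mdtraj.Trajectory((coords / 10.0)[None], top)  # nm
        ref = mdtraj.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960)[0] * 100.0
        mine = met.sasa(f, n_sphere_points=960)
        assert np.allclose(mine, ref, rtol=0.03, atol=0.5)


class TestPsa:
    def test_no_polar_atoms_zero(self):
        f = _frame([[0, 0, 0]], ["C"])
        assert met.psa(f) == 0.0

    def test_single_nitrogen_closed_form(self):
        f = _frame([[0, 0, 0]], ["N"])
        assert met.psa(f) == pytest.approx(4 * np.pi * (1.55 + 1.4) ** 2, rel=1e-12)
        assert met.psa(f) == pytest.approx(109.4, abs=0.05)

    def test_open_template_exposes_more_polar_area_than_closed(self):
        rules = syn.default_conformer_rules()
        psa_closed = met.psa(rules.templates["closed"])
        psa_open = met.psa(rules.templates["open"])
        assert psa_closed < psa_open


class TestDihedralPca:
    def _series_single_angle(self, n=400):
        # variance confined to one phi; +/-15 deg keeps its cos essentially
        # constant so the variation is one-dimensional
        rng = np.random.default_rng(1)
        angles = np.full((n, 2, 3), 180.0)
        angles[:, 0, 0] = rng.uniform(-15.0, 15.0, n)
        return met.DihedralSeries(angles)

    def test_single_variable_angle_dominates_pc1(self):
        s = self._series_single_angle()
        model, proj = met.dihedral_pca(s)
        assert model.explained_variance_ratio[0] >= 0.99
        # PC1 lies in the (sin, cos) plane of the variable angle
        weights = np.abs(model.components[0])
        emb_dim = weights.size
        idx_sin, idx_cos = 0, emb_dim // 2  # angle (0,0) sin and cos slots
        assert weights[idx_sin] ** 2 + weights[idx_cos] ** 2 > 0.99

    def test_eigenvectors_orthonormal(self):
        s = self._series_single_angle()
        model, _ = met.dihedral_pca(s)
        assert np.allclose(model.components @ model.components.T, np.eye(len(model.eigenvalues)), atol=1e-10)

    def test_projection_roundtrip_and_centering(self):
        s = self._series_single_angle()
        model, proj = met.dihedral_pca(s)
        emb = met._embed(s) - model.mean
        assert np.allclose(proj @ model.components, emb, atol=1e-8)
        assert np.allclose(proj.mean(axis=0), 0.0, atol=1e-10)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_constant_series_rejected(self):
        angles = np.full((10, 2, 3), 180.0)
        with pytest.raises(ValueError, match="degenerate|zero variance"):
            met.dihedral_pca(met.DihedralSeries(angles))


class TestClosedFraction:
    def test_all_inside_region_is_one(self):
        cls = met.pc_box_classifier(0, (2.0, 3.0))
        proj = np.full((50, 4), 2.5)
        assert met.closed_fraction(proj, cls) == 1.0

    def test_recovers_generator_fraction(self):
        rules = syn.default_conformer_rules()
        rules.closed_probability = lambda z: np.full_like(np.asarray(z, float), 0.3)
        z = TrajectorySeries(1.0, np.linspace(0, 37.5, 3000))
        ens = syn.generate_conformer_series(1500, z, rules, seed=11)
        frac = met.closed_fraction(ens.frames, met.hbond_classifier())
        se = np.sqrt(0.3 * 0.7 / 1500)
        assert frac == pytest.approx(0.3, abs=4 * se)

    def test_hbond_and_pc_classifiers_agree_on_clean_templates(self):
        rules = syn.default_conformer_rules()
        z = TrajectorySeries(1.0, np.linspace(0, 37.5, 3000))
        ens = syn.generate_conformer_series(600, z, rules, seed=12)
        model, proj = met.dihedral_pca(ens.dihedrals)
        closed_proj = proj[ens.labels, 0]
        lo, hi = closed_proj.min() - 0.1, closed_proj.max() + 0.1
        pc_cls = met.pc_box_classifier(0, (lo, hi))
        hb = np.array([met.hbond_classifier()(f) for f in ens.frames])
        pc = np.array([pc_cls(p) for p in proj])
        assert (hb == pc).mean() >= 0.95

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            met.closed_fraction([], lambda x: True)


class TestOmegaAndGeometry:
    def test_cis_omega_boundary_definition(self):
        angles = np.full((5, 1, 3), 180.0)
        angles[1, 0, 2] = 0.0
        angles[2, 0, 2] = 89.9
        angles[3, 0, 2] = -89.9
        angles[4, 0, 2] = 90.0  # exactly 90 -> trans
        counts = met.count_cis_omega(met.DihedralSeries(angles))
        assert counts.tolist() == [0, 1, 1, 1, 0]

    def _ring(self, n=12, radius=5.0):
        ang = 2 * np.pi * np.arange(n) / n
        return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)], axis=1)

    def test_planar_ring_short_axis_along_normal(self):
        assert met.short_axis_angle(self._ring()) == pytest.approx(0.0, abs=1e-9)

    def test_ring_rotated_ninety_degrees(self):
        X = self._ring()
        rot = X[:, [0, 2, 1]] * np.array([1, -1, 1])  # rotate about x
        assert met.short_axis_angle(rot) == pytest.approx(90.0, abs=1e-9)

    def test_ring_tilted_thirty_degrees(self):
        X = self._ring()
        t = np.radians(30.0)
        rot = X.copy()
        rot[:, 1] = X[:, 1] * np.cos(t) - X[:, 2] * np.sin(t)
        rot[:, 2] = X[:, 1] * np.sin(t) + X[:, 2] * np.cos(t)
        assert met.short_axis_angle(rot) == pytest.approx(30.0, abs=1e-6)

    def test_collinear_points_rejected(self):
        X = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError, match="degenerate"):
            met.short_axis_angle(X)

    @pytest.mark.parametrize(
        "box, n, expected",
        [((63.3, 51.0), 51, 63.3), ((10.0, 10.0), 1, 100.0)],
    )
    def test_area_per_lipid(self, box, n, expected):
        assert met.area_per_lipid(box, n) == pytest.approx(expected)

    def test_area_per_lipid_table_row(self):
        # 102 POPC = 51 per leaflet over a 3228.3 A^2 lateral box
        assert met.area_per_lipid((np.sqrt(3228.3), np.sqrt(3228.3)), 51) == pytest.approx(63.3, abs=0.05)

    def test_area_per_lipid_scaling_and_validation(self):
        assert met.area_per_lipid((20.0, 20.0), 4) == 4 * met.area_per_lipid((10.0, 10.0), 4)
        with pytest.raises(ValueError):
            met.area_per_lipid((10.0, 10.0), 0)


class TestProfileByZ:
    def test_constant_observable(self):
        z = np.random.default_rng(0).uniform(0, 10, 200)
        p = met.profile_by_z(np.full(200, 7.0), z, np.linspace(0, 10, 6))
        assert np.allclose(p.values, 7.0)
        assert np.allclose(p.stderr, 0.0)

    def test_step_rule_recovered(self):
        rng = np.random.default_rng(3)
        z = rng.uniform(0, 20, 5000)
        vals = np.where(z < 5, 0.0, np.where(z > 15, 6.0, 3.0))
        p = met.profile_by_z(vals, z, np.arange(0.0, 21.0, 1.0))
        assert np.allclose(p.values[p.grid < 5], 0.0)
        assert np.allclose(p.values[p.grid > 15], 6.0)

    def test_empty_and_single_frame_bins_flagged(self):
        z = np.array([0.5, 0.6, 5.5])
        vals = np.array([1.0, 2.0, 3.0])
        p = met.profile_by_z(vals, z, np.array([0.0, 1.0, 2.0, 6.0]))
        assert np.isnan(p.values[1])  # empty bin undefined
        assert p.values[2] == 3.0
        assert np.isnan(p.stderr[2])  # half-split impossible for one frame

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            met.profile_by_z(np.zeros(5), np.zeros(6), 3)
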