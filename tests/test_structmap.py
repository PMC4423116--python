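"""Superposition, SASA, Delta-SASA, patches, grafting and clashes."""

import numpy as np
import pytest
import biotite.structure as struc

from paddleclamp import structmap as sm
from paddleclamp import synthdata as sd


def rotation_matrix(axis, angle_deg):
    d = np.asarray(axis, dtype=float)
    d = d / np.linalg.norm(d)
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def make_atoms(coords, chain="A", element="C"):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    atoms = struc.AtomArray(n)
    atoms.coord = coords.astype(np.float32)
    atoms.chain_id = np.full(n, chain)
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.full(n, "UNK")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, element)
    return atoms


class TestTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError, match="proper"):
            sm.Transform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_and_inverse(self, rng):
        a = sm.Transform(rotation_matrix([0, 0, 1], 30.0), rng.normal(size=3))
        b = sm.Transform(rotation_matrix([1, 1, 0], 70.0), rng.normal(size=3))
        x = rng.normal(size=(5, 3))
        assert np.allclose(a.compose(b).apply(x), a.apply(b.apply(x)), atol=1e-10)
        assert np.allclose(a.inverse().apply(a.apply(x)), x, atol=1e-10)


class TestKabsch:
    def test_identity_case(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        tf, rmsd = sm.kabsch_superpose(pts, pts)
        assert rmsd < 1e-10
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self, rng):
        pts = rng.normal(size=(6, 3))
        R = rotation_matrix([1, 2, 3], 30.0)
        moved = pts @ R.T + np.array([5.0, -2.0, 1.0])
        tf, rmsd = sm.kabsch_superpose(moved, pts)
        assert rmsd < 1e-10
        assert np.allclose(tf.rotation, R.T, atol=1e-8)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            sm.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_jittered_cystine_pairs_match_brute_force(self, rng):
        """Oracle: coarse-to-fine search over axis-angle rotations for the
        minimal RMSD on six jittered pseudo-cystine C-alphas."""
        ref = rng.normal(size=(6, 3)) * 4.0
        mobile = ref + rng.normal(scale=1.0, size=(6, 3))
        tf, rmsd = sm.kabsch_superpose(mobile, ref)

        p0 = mobile - mobile.mean(axis=0)
        q0 = ref - ref.mean(axis=0)

        def rmsd_of(R):
            return np.sqrt(np.mean(np.sum((p0 @ R.T - q0) ** 2, axis=1)))

        # coarse grid over rotation space, then local refinement
        best = (None, np.inf)
        axes = sm.fibonacci_sphere(60)
        for ax in axes:
            for ang in np.arange(0.0, 360.0, 6.0):
                r = rotation_matrix(ax, ang)
                v = rmsd_of(r)
                if v < best[1]:
                    best = ((ax, ang), v)
        (ax, ang), v = best
        for _ in range(40):  # refine by random local proposals
            scale = 3.0
            cand_ax = ax + rng.normal(scale=0.05, size=3)
            cand_ang = ang + rng.normal(scale=scale)
            r = rotation_matrix(cand_ax, cand_ang)
            val = rmsd_of(r)
            if val < v:
                ax, ang, v = cand_ax, cand_ang, val
        assert rmsd <= v + 1e-3

    def test_optimality_against_random_perturbations(self, rng):
        """No small proper-rotation perturbation of the Kabsch solution
        lowers the RMSD."""
        ref = rng.normal(size=(8, 3)) * 3.0
        mobile = ref + rng.normal(scale=0.5, size=(8, 3))
        tf, rmsd = sm.kabsch_superpose(mobile, ref)
        centered = mobile - mobile.mean(axis=0)
        target = ref - ref.mean(axis=0)
        base = tf.rotation
        for _ in range(1000):
            axis = rng.normal(size=3)
            angle = rng.uniform(0.01, 5.0)
            R = rotation_matrix(axis, angle) @ base
            perturbed = np.sqrt(np.mean(np.sum((centered @ R.T - target) ** 2, axis=1)))
            assert perturbed >= rmsd - 1e-12


class TestSasa:
    def test_single_sphere_matches_closed_form(self):
        atoms = make_atoms([[0.0, 0.0, 0.0]])
        rep = sm.shrake_rupley_sasa(atoms, probe_radius=1.4, n_points=960,
                                    radii=np.array([1.7]))
        exact = 4.0 * np.pi * 3.1**2
        assert rep.total == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_are_additive(self):
        one = sm.shrake_rupley_sasa(make_atoms([[0.0, 0.0, 0.0]]))
        two = sm.shrake_rupley_sasa(make_atoms([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]))
        assert two.total == pytest.approx(2 * one.total, rel=1e-9)

    def test_coincident_duplicates_follow_documented_convention(self):
        """An exact duplicate is fully occluded by its lower-index twin,
        so the pair's total equals one isolated atom."""
        one = sm.shrake_rupley_sasa(make_atoms([[0.0, 0.0, 0.0]]))
        dup = sm.shrake_rupley_sasa(make_atoms([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]))
        assert dup.total == pytest.approx(one.total)
        assert dup.per_atom[1] == 0.0

    def test_quadrature_converges_with_point_count(self, contact_complex):
        lo = sm.shrake_rupley_sasa(contact_complex, n_points=960)
        hi = sm.shrake_rupley_sasa(contact_complex, n_points=1920)
        assert hi.total == pytest.approx(lo.total, rel=0.01)

    def test_per_residue_sums_match_per_atom(self, toy_complex):
        rep = sm.shrake_rupley_sasa(toy_complex)
        assert rep.per_residue["sasa_A2"].sum() == pytest.approx(rep.per_atom.sum())

    def test_agrees_with_independent_implementation(self, contact_complex):
        """Cross-check against biotite's own Shrake-Rupley."""
        radii = sm.assign_vdw_radii(contact_complex)
        ours = sm.shrake_rupley_sasa(contact_complex, n_points=960, radii=radii)
        theirs = struc.sasa(contact_complex, probe_radius=1.4, point_number=1000,
                            vdw_radii=radii)
        assert ours.total == pytest.approx(float(np.nansum(theirs)), rel=0.02)

    def test_too_few_points_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="92"):
            sm.shrake_rupley_sasa(toy_complex, n_points=50)


class TestDeltaSasa:
    def test_separated_components_bury_nothing(self, far_complex):
        rep = sm.delta_sasa(far_complex, ["B"], n_points=960)
        assert np.allclose(rep.table["dsasa_A2"], 0.0, atol=1e-6)

    def test_contact_buries_interface_only(self, contact_complex):
        rep = sm.delta_sasa(contact_complex, ["B"], n_points=960)
        assert rep.total > 10.0
        assert np.all(rep.table["dsasa_A2"] >= -1e-6)

    def test_matches_independent_sasa_oracle(self, contact_complex):
        """Delta-SASA from biotite's independent quadrature agrees with
        ours to within 2% of the buried area."""
        radii = sm.assign_vdw_radii(contact_complex)
        ours = sm.delta_sasa(contact_complex, ["B"], n_points=1920)
        mask = contact_complex.chain_id == "B"
        free = struc.sasa(contact_complex[mask], probe_radius=1.4,
                          point_number=2000, vdw_radii=radii[mask])
        bound = struc.sasa(contact_complex, probe_radius=1.4,
                           point_number=2000, vdw_radii=radii)
        oracle_total = float(np.nansum(free) - np.nansum(bound[mask]))
        assert ours.total == pytest.approx(oracle_total, rel=0.02)

    def test_burial_symmetry_consistency(self, contact_complex):
        """Sum of both components' Delta-SASA equals the total area lost
        by the complex relative to the free components."""
        da = sm.delta_sasa(contact_complex, ["A"], n_points=960).total
        db = sm.delta_sasa(contact_complex, ["B"], n_points=960).total
        whole = sm.shrake_rupley_sasa(contact_complex, n_points=960).total
        free_a = sm.shrake_rupley_sasa(
            contact_complex[contact_complex.chain_id == "A"], n_points=960
        ).total
        free_b = sm.shrake_rupley_sasa(
            contact_complex[contact_complex.chain_id == "B"], n_points=960
        ).total
        assert da + db == pytest.approx(free_a + free_b - whole, abs=1e-6)

    def test_empty_chain_selection_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="empty"):
            sm.delta_sasa(toy_complex, [])
        with pytest.raises(ValueError, match="not in complex"):
            sm.delta_sasa(toy_complex, ["Z"])


class TestHydrophobicPatch:
    def test_single_residue_patch_is_its_sasa(self, toy_complex):
        rep = sm.shrake_rupley_sasa(toy_complex)
        helix = toy_complex[toy_complex.chain_id == "A"]
        area = sm.hydrophobic_patch_area(helix, [5], rep, chain_id="A")
        per_res = rep.per_residue
        expected = float(per_res[(per_res.chain_id == "A")
                                 & (per_res.res_id == 5)]["sasa_A2"].iloc[0])
        assert area == pytest.approx(expected)

    def test_largest_cluster_excludes_remote_residue(self):
        """Two adjacent residues + one remote one: only the pair counts."""
        coords = [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [50.0, 0.0, 0.0]]
        atoms = make_atoms(coords)
        rep = sm.shrake_rupley_sasa(atoms)
        area = sm.hydrophobic_patch_area(atoms, [1, 2, 3], rep)
        expected = float(rep.per_residue[rep.per_residue.res_id.isin([1, 2])]
                         ["sasa_A2"].sum())
        assert area == pytest.approx(expected)

    def test_disjoint_residue_set_rejected(self, toy_complex):
        rep = sm.shrake_rupley_sasa(toy_complex)
        with pytest.raises(ValueError, match="disjoint"):
            sm.hydrophobic_patch_area(toy_complex, [999], rep)


class TestHelixAxisAndGraft:
    @pytest.fixture
    def graft_setup(self):
        tox = sd.gen_toy_complex(sd.ToyComplexSpec())
        toxin = tox[tox.chain_id == "B"]
        template = tox[tox.chain_id == "A"]
        target = sd.ideal_helix(18, chain_id="T")
        move = sm.Transform(rotation_matrix([0, 1, 0], 40.0), np.array([20.0, 5.0, -3.0]))
        return toxin, template, move.apply_to(target)

    def test_axis_recovered_for_ideal_helix(self):
        helix = sd.ideal_helix(12)
        point, direction = sm.helix_axis(helix.coord)
        assert np.allclose(np.abs(direction), [0, 0, 1], atol=1e-6)
        assert np.allclose(point[:2], 0.0, atol=1e-5)

    def test_short_helix_rejected(self):
        with pytest.raises(sm.GeometryError, match="<4"):
            sm.helix_axis(np.zeros((3, 3)))

    def test_offset_zero_is_plain_superposition(self, graft_setup):
        toxin, template, target = graft_setup
        g = sm.graft_by_register(toxin, template, ("A", 5, 13),
                                 target, ("T", 5, 13), offset=0)
        tpl_ca = sm._helix_window_ca(template, "A", 5, 13)
        tgt_ca = sm._helix_window_ca(target, "T", 5, 13)
        base, _ = sm.kabsch_superpose(tpl_ca, tgt_ca)
        assert np.allclose(g.transform.rotation, base.rotation, atol=1e-8)
        assert np.allclose(g.transform.translation, base.translation, atol=1e-8)

    def test_register_steps_compose_as_group(self, graft_setup):
        """graft(k) equals graft(0) composed with k elementary steps,
        and +1 then -1 returns to the start."""
        toxin, template, target = graft_setup
        args = (toxin, template, ("A", 5, 13), target, ("T", 5, 13))
        g0 = sm.graft_by_register(*args, offset=0)
        point, direction = sm.helix_axis(sm._helix_window_ca(target, "T", 5, 13))
        step = sm.axis_step_transform(point, direction, 100.0, 1.5)
        for k in (-2, -1, 1, 2):
            gk = sm.graft_by_register(*args, offset=k)
            expect = g0.transform
            one = step if k > 0 else step.inverse()
            for _ in range(abs(k)):
                expect = one.compose(expect)
            assert np.allclose(gk.transform.rotation, expect.rotation, atol=1e-8)
            assert np.allclose(gk.transform.translation, expect.translation, atol=1e-8)
        g1 = sm.graft_by_register(*args, offset=1)
        back = step.inverse().compose(g1.transform)
        assert np.allclose(back.rotation, g0.transform.rotation, atol=1e-8)
        assert np.allclose(back.translation, g0.transform.translation, atol=1e-8)

    def test_offset_rotates_and_translates_centroid(self, graft_setup):
        toxin, template, target = graft_setup
        args = (toxin, template, ("A", 5, 13), target, ("T", 5, 13))
        g0 = sm.graft_by_register(*args, offset=0)
        g1 = sm.graft_by_register(*args, offset=1)
        point, direction = sm.helix_axis(sm._helix_window_ca(target, "T", 5, 13))
        # independently composed transform applied to the offset-0 centroid
        step = sm.axis_step_transform(point, direction, 100.0, 1.5)
        c0 = g0.toxin.coord.astype(float).mean(axis=0)
        c1 = g1.toxin.coord.astype(float).mean(axis=0)
        assert np.allclose(c1, step.apply(c0[None, :])[0], atol=1e-4)
        assert (c1 - c0) @ direction == pytest.approx(1.5, abs=1e-4)

    def test_out_of_frame_offset_rejected(self, graft_setup):
        toxin, template, target = graft_setup
        with pytest.raises(ValueError, match="outside configured frames"):
            sm.graft_by_register(toxin, template, ("A", 5, 13),
                                 target, ("T", 5, 13), offset=3)

    def test_engineered_collisions_flag_exact_frames(self, graft_setup):
        """Obstacle atoms placed on the offset +1/-1 toxin positions make
        exactly those frames clash."""
        toxin, template, target = graft_setup
        args = (toxin, template, ("A", 5, 13), target, ("T", 5, 13))
        placements = {k: sm.graft_by_register(*args, offset=k).toxin
                      for k in (-2, -1, 0, 1, 2)}
        obstacle = make_atoms(
            [placements[-1].coord[0], placements[1].coord[0]], chain="O"
        )
        spiked = target + obstacle
        clashing = set()
        for k in (-2, -1, 0, 1, 2):
            g = sm.graft_by_register(toxin, template, ("A", 5, 13),
                                     spiked, ("T", 5, 13), offset=k)
            if g.clash_count > 0:
                clashing.add(k)
        assert clashing == {-1, 1}


class TestContacts:
    def test_separated_chains_no_clashes(self, toy_complex):
        count, pairs = sm.detect_clashes(toy_complex, "A", "B", 2.5)
        assert count == 0 and pairs == []

    def test_single_engineered_clash(self):
        a = make_atoms([[0.0, 0.0, 0.0]], chain="A")
        b = make_atoms([[1.0, 0.0, 0.0]], chain="B")
        count, pairs = sm.detect_clashes(a + b, "A", "B", 2.5)
        assert count == 1
        assert pairs[0][2] == pytest.approx(1.0)

    def test_hydrogens_ignored(self):
        a = make_atoms([[0.0, 0.0, 0.0]], chain="A")
        b = make_atoms([[1.0, 0.0, 0.0]], chain="B", element="H")
        count, _ = sm.detect_clashes(a + b, "A", "B", 2.5)
        assert count == 0

    def test_missing_chain_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="not present"):
            sm.detect_clashes(toy_complex, "A", "Z")

    def test_interface_empty_beyond_threshold(self, toy_complex):
        far = sd.gen_toy_complex(sd.ToyComplexSpec(placement_offset=(40.0, 0.0, 0.0)))
        res = sm.interface_residues(far, "A", "B", 12.0)
        assert res["A"] == [] and res["B"] == []

    def test_known_contacts_identified(self):
        a = make_atoms([[0.0, 0.0, 0.0], [0.0, 0.0, 30.0]], chain="A")
        b = make_atoms([[5.0, 0.0, 0.0]], chain="B")
        res = sm.interface_residues(a + b, "A", "B", 12.0)
        assert res["A"] == [1] and res["B"] == [1]

    def test_interface_shrinks_with_threshold(self, contact_complex):
        sizes = []
        for thr in (16.0, 12.0, 8.0, 4.0):
            res = sm.interface_residues(contact_complex, "A", "B", thr)
            sizes.append(len(res["A"]) + len(res["B"]))
        assert sizes == sorted(sizes, reverse=True)


class TestPdbRoundTrip:
    def test_write_read_preserves_structure(self, toy_complex, tmp_path):
        path = tmp_path / "toy.pdb"
        sm.write_structure(toy_complex, path)
        back = sm.read_structure(path)
        assert len(back) == len(toy_complex)
        assert np.allclose(back.coord, toy_complex.coord, atol=1e-2)
        assert list(back.chain_id) == list(toy_complex.chain_id)
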