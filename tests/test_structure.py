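"""Structure comparison: superposition, SASA, interfaces, salt bridges,
cis peptides, hydropathy, cavity volume."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import get3atlas as g
from get3atlas.structio import Atom, Chain, Residue, StructureModel
from get3atlas.structure import PROBE_RADIUS, VDW_RADII, _dihedral


def quaternion_superpose_rmsd(fixed, mobile):
    """Independent oracle: Horn's quaternion absolute-orientation method."""
    F = fixed - fixed.mean(axis=0)
    M = mobile - mobile.mean(axis=0)
    Sxx = M.T @ F
    K = np.empty((4, 4))
    K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
    K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
    K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
    K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
    K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
    K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
    K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
    K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
    K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
    K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
    w, v = np.linalg.eigh(K)
    q = v[:, -1]
    R = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    moved = M @ R.T
    return float(np.sqrt(np.mean(np.sum((moved - F) ** 2, axis=1))))


def single_atom(element="C", xyz=(0, 0, 0)):
    return StructureModel([Chain("A", [Residue("ALA", 1, "", [
        Atom("CA", element, np.array(xyz, float))])])])


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        sup = g.kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(sup.translation, 0.0, atol=1e-9)

    def test_rigid_copy_rmsd_zero(self, rng):
        pts = rng.normal(size=(25, 3))
        R = Rotation.random(random_state=7).as_matrix()
        moved = pts @ R.T + np.array([4.0, -2.0, 9.0])
        sup = g.kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fixed = rng.normal(size=(20, 3))
        mobile = rng.normal(size=(20, 3))
        sup = g.kabsch_superpose(fixed, mobile)
        assert sup.rmsd == pytest.approx(
            quaternion_superpose_rmsd(fixed, mobile), abs=1e-8)
        assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-9)

    def test_too_few_or_collinear_rejected(self):
        with pytest.raises(ValueError):
            g.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            g.kabsch_superpose(line, line)


class TestBackboneRmsd:
    def test_self_is_zero(self):
        dim = g.make_toy_dimer(9.0)
        assert g.backbone_rmsd(dim, dim) == pytest.approx(0.0, abs=1e-9)

    def test_chain_renaming_is_irrelevant(self):
        dim = g.make_toy_dimer(9.0)
        renamed = g.read_pdb_subset(g.write_pdb(dim))
        for c, new in zip(renamed.chains, ("X", "Y")):
            c.id = new
        assert g.backbone_rmsd(dim, renamed) == pytest.approx(0.0, abs=1e-3)

    def test_rotation_invariance(self):
        dim = g.make_toy_dimer(9.0)
        rotated = g.read_pdb_subset(g.write_pdb(dim))
        R = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
        for _, _, a in rotated.atoms():
            a.xyz = R @ a.xyz + np.array([5.0, 6.0, 7.0])
        assert g.backbone_rmsd(dim, rotated) == pytest.approx(0.0, abs=1e-2)


class TestSasa:
    def test_single_atom_analytic(self):
        s = g.total_sasa(single_atom())
        exact = 4 * np.pi * (VDW_RADII["C"] + PROBE_RADIUS) ** 2
        assert abs(s - exact) / exact < 0.01

    def test_additivity_far_apart(self):
        m = StructureModel([Chain("A", [
            Residue("ALA", 1, "", [Atom("CA", "C", np.zeros(3))]),
            Residue("ALA", 2, "", [Atom("CA", "C", np.array([100.0, 0, 0]))])])])
        single = g.total_sasa(single_atom())
        assert g.total_sasa(m) == pytest.approx(2 * single, rel=0.01)

    @pytest.mark.parametrize("d", [0.5, 1.5, 2.5])
    def test_overlapping_pair_matches_dense_sampling(self, d):
        m = StructureModel([Chain("A", [
            Residue("ALA", 1, "", [Atom("CA", "C", np.zeros(3))]),
            Residue("ALA", 2, "", [Atom("CA", "C", np.array([d, 0, 0]))])])])
        coarse = g.total_sasa(m, n_points=960)
        dense = g.total_sasa(m, n_points=20000)
        assert abs(coarse - dense) / dense < 0.02

    def test_monotone_under_atom_addition(self, rng):
        base = [Atom("CA", "C", rng.normal(scale=2.0, size=3)) for _ in range(6)]
        prev = None
        for k in range(1, 7):
            m = StructureModel([Chain("A", [Residue("ALA", i + 1, "", [a])
                                            for i, a in enumerate(base[:k])])])
            areas = g.shrake_rupley_sasa(m)
            if prev is not None:
                assert areas[:k - 1].sum() <= prev.sum() + 1e-6
            prev = areas

    def test_unknown_element_warns_and_defaults(self):
        m = single_atom(element="Q")
        with pytest.warns(UserWarning, match="unknown element"):
            s = g.total_sasa(m)
        exact = 4 * np.pi * (1.70 + PROBE_RADIUS) ** 2
        assert abs(s - exact) / exact < 0.01


class TestInterface:
    def test_far_apart_zero(self):
        far = g.make_toy_dimer(100.0)
        rep = g.buried_interface_area(far, [("A", None)], [("B", None)])
        assert abs(rep.delta_sasa_total) < 1.0

    def test_contact_positive_and_half_convention(self):
        dim = g.make_toy_dimer(8.0)
        rep = g.buried_interface_area(dim, [("A", None)], [("B", None)])
        assert rep.delta_sasa_total > 100.0
        assert rep.delta_sasa_half == pytest.approx(rep.delta_sasa_total / 2)

    def test_symmetry_exact(self):
        dim = g.make_toy_dimer(9.0)
        ab = g.buried_interface_area(dim, [("A", None)], [("B", None)])
        ba = g.buried_interface_area(dim, [("B", None)], [("A", None)])
        assert ab.delta_sasa_total == ba.delta_sasa_total

    def test_overlapping_parts_rejected(self):
        dim = g.make_toy_dimer(9.0)
        with pytest.raises(ValueError, match="overlap"):
            g.buried_interface_area(dim, [("A", None)], [("A", 1), ("B", None)])

    def test_rotation_invariance(self):
        dim = g.make_toy_dimer(9.0)
        base = g.buried_interface_area(dim, [("A", None)], [("B", None)])
        R = Rotation.from_euler("zyx", [1.0, 0.3, -0.8]).as_matrix()
        rot = g.read_pdb_subset(g.write_pdb(dim))
        for _, _, a in rot.atoms():
            a.xyz = R @ a.xyz - np.array([3.0, 11.0, 2.0])
        again = g.buried_interface_area(rot, [("A", None)], [("B", None)])
        assert again.delta_sasa_total == pytest.approx(base.delta_sasa_total,
                                                       abs=1e-6 + 0.02 * base.delta_sasa_total)


class TestSaltBridges:
    def test_pair_at_3_5_detected(self):
        dim = g.make_toy_dimer(10.0, salt_bridge_distance=3.5)
        out = g.detect_salt_bridges(dim, [("A", None)], [("B", None)])
        assert ("A:ARG21", "B:ASP21") in out

    def test_pair_at_6_0_not_detected(self):
        dim = g.make_toy_dimer(10.0, salt_bridge_distance=6.0)
        assert g.detect_salt_bridges(dim, [("A", None)], [("B", None)]) == []


def dipeptide(omega_deg):
    """Two residues whose peptide bond has the requested omega dihedral."""
    ca0 = np.array([-1.5, 1.0, 0.0])
    c0 = np.array([0.0, 0.0, 0.0])
    n1 = np.array([1.33, 0.0, 0.0])
    th = np.radians(omega_deg)
    ca1 = n1 + np.array([0.5, np.cos(th), np.sin(th)]) * 1.46
    return StructureModel([Chain("A", [
        Residue("GLY", 1, "", [Atom("CA", "C", ca0), Atom("C", "C", c0),
                               Atom("N", "N", ca0 + [0, 1, 0]),
                               Atom("O", "O", c0 + [0, -1, 0])]),
        Residue("PRO", 2, "", [Atom("N", "N", n1), Atom("CA", "C", ca1)]),
    ])])


class TestCisPeptides:
    def test_omega_zero_is_cis(self):
        out = g.detect_cis_peptides(dipeptide(0.0))
        assert len(out) == 1
        chain, num, name, omega = out[0]
        assert (chain, num, name) == ("A", 2, "PRO")
        assert abs(omega) < 1.0

    def test_omega_180_is_trans(self):
        assert g.detect_cis_peptides(dipeptide(180.0)) == []

    def test_threshold_boundary(self):
        assert len(g.detect_cis_peptides(dipeptide(29.0))) == 1
        assert g.detect_cis_peptides(dipeptide(31.5)) == []

    def test_chain_break_skipped(self):
        m = dipeptide(0.0)
        m.chains[0].residues[1].atom("N").xyz += np.array([10.0, 0, 0])
        assert g.detect_cis_peptides(m) == []

    def test_dihedral_sign_convention(self):
        # right-handed rotation about the central bond, eclipsed = 0
        p = [np.array([0, 1.0, 0]), np.zeros(3), np.array([1.0, 0, 0]),
             np.array([1.0, 0, 1.0])]
        assert _dihedral(*p) == pytest.approx(90.0, abs=1e-6)
        p_cis = [np.array([0, 1.0, 0]), np.zeros(3), np.array([1.0, 0, 0]),
                 np.array([1.0, 1.0, 0])]
        assert _dihedral(*p_cis) == pytest.approx(0.0, abs=1e-6)


class TestHydropathy:
    def test_kyte_doolittle_values(self):
        m = StructureModel([Chain("A", [
            Residue("ILE", 1, "", [Atom("CA", "C", np.zeros(3))]),
            Residue("ARG", 2, "", [Atom("CA", "C", np.ones(3))]),
            Residue("GLY", 3, "", [Atom("CA", "C", 2 * np.ones(3))])])])
        h = g.hydrophobicity_map(m)
        assert h[("A", 1)] == 4.5
        assert h[("A", 2)] == -4.5
        assert h[("A", 3)] == -0.4

    def test_unknown_residue_zero_with_warning(self):
        m = StructureModel([Chain("A", [
            Residue("XYZ", 1, "", [Atom("CA", "C", np.zeros(3))])])])
        with pytest.warns(UserWarning, match="no hydropathy"):
            h = g.hydrophobicity_map(m)
        assert h[("A", 1)] == 0.0


def hollow_shell(interior_radius=6.0, n=700):
    """Atoms whose probe-inflated spheres seal a hollow ball."""
    shell_r = interior_radius + VDW_RADII["C"] + PROBE_RADIUS
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    pts = shell_r * np.stack([np.sin(phi) * np.cos(theta),
                              np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)
    residues = [Residue("ALA", k + 1, "", [Atom("CA", "C", p)])
                for k, p in enumerate(pts)]
    return StructureModel([Chain("A", residues)])


class TestCavity:
    def test_hollow_shell_volume(self):
        rep = g.cavity_volume(hollow_shell(6.0), grid=0.5)
        expect = 4 / 3 * np.pi * 6.0 ** 3
        assert abs(rep.volume - expect) / expect < 0.10
        assert rep.helix_residue_capacity == pytest.approx(rep.volume / 170.0)

    def test_solid_cluster_no_cavity(self):
        pts = [np.array([i * 1.2, j * 1.2, k * 1.2])
               for i in range(3) for j in range(3) for k in range(3)]
        m = StructureModel([Chain("A", [Residue("ALA", n + 1, "", [
            Atom("CA", "C", p)]) for n, p in enumerate(pts)])])
        assert g.cavity_volume(m, grid=0.5).volume == pytest.approx(0.0, abs=5.0)

    def test_grid_convergence(self):
        v1 = g.cavity_volume(hollow_shell(6.0), grid=0.5).volume
        v2 = g.cavity_volume(hollow_shell(6.0), grid=0.25).volume
        assert abs(v1 - v2) / v2 < 0.05
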