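import numpy as np
import pytest
from rdkit import Chem
from rdkit.Geometry import Point3D
from scipy.spatial.transform import Rotation

from fieldqsar.errors import ParameterError
from fieldqsar.interactions import (
    ComplexPose,
    DEFAULT_ECIDAL_SPEC,
    InteractionRecord,
    ReceptorAtom,
    detect_hbonds,
    detect_pi_stacking,
    ecidal_filter,
    read_receptor_pdb,
    summarize_interactions,
    write_receptor_pdb,
)
from fieldqsar.synthetic import (
    ComplexSpec,
    PlantedInteraction,
    default_receptor,
    generate_toy_complexes,
)


def _mol_from_atoms(atoms, bonds):
    """atoms: [(element, xyz)]; bonds: [(i, j, order)]."""
    rw = Chem.RWMol()
    for el, _ in atoms:
        a = Chem.Atom(el)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    kinds = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE}
    for i, j, o in bonds:
        rw.AddBond(i, j, kinds[o])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(len(atoms))
    for i, (_, xyz) in enumerate(atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol.AddConformer(conf)
    return mol


def _gln_fragment(ne2=(0.0, 0.0, 0.0)):
    """A Gln-like side-chain amide donor: CD-NE2 with one N-H along +x."""
    ne2 = np.asarray(ne2, float)
    return [
        ReceptorAtom("CD", "GLN", 1001, "A", "C", ne2 + [-1.33, 0, 0]),
        ReceptorAtom("NE2", "GLN", 1001, "A", "N", ne2),
        ReceptorAtom("HE21", "GLN", 1001, "A", "H", ne2 + [1.01, 0, 0]),
        ReceptorAtom("OE1", "GLN", 1001, "A", "O", ne2 + [-1.33, -1.23, 0]),
    ]


def _acceptor_ligand(o_pos):
    """Formaldehyde with the carbonyl O at o_pos."""
    o = np.asarray(o_pos, float)
    return _mol_from_atoms(
        [
            ("O", o),
            ("C", o + [0, 1.22, 0]),
            ("H", o + [0.9, 1.8, 0]),
            ("H", o + [-0.9, 1.8, 0]),
        ],
        [(0, 1, 2), (1, 2, 1), (1, 3, 1)],
    )


def _benzene(centroid, normal):
    centroid = np.asarray(centroid, float)
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    ref = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    atoms, bonds = [], []
    for k in range(6):
        ang = np.radians(60 * k)
        atoms.append(("C", centroid + 1.39 * (np.cos(ang) * e1 + np.sin(ang) * e2)))
    for k in range(6):
        bonds.append((k, (k + 1) % 6, 1))
    rw = Chem.RWMol()
    for el, _ in atoms:
        a = Chem.Atom(el)
        a.SetIsAromatic(True)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, _ in bonds:
        b = rw.AddBond(i, j, Chem.BondType.AROMATIC)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(6)
    for i, (_, xyz) in enumerate(atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol.AddConformer(conf)
    return mol


def _phe_ring(res_seq=1004, centroid=(0, 0, 0), normal=(0, 0, 1)):
    centroid = np.asarray(centroid, float)
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    ref = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    return [
        ReceptorAtom(
            nm, "PHE", res_seq, "A", "C",
            centroid + 1.39 * (np.cos(np.radians(60 * k)) * e1
                               + np.sin(np.radians(60 * k)) * e2),
        )
        for k, nm in enumerate(names)
    ]


class TestHBondDetection:
    def test_ideal_geometry_detected(self):
        """N-H...O at 2.9 A heavy-atom distance and 180 deg."""
        pose = ComplexPose(
            _gln_fragment(), _acceptor_ligand([2.9, 0, 0]), "p1"
        )
        records = [r for r in detect_hbonds(pose) if r.residue == "Gln1001"]
        hb = [r for r in records if r.group == "NH2"]
        assert len(hb) == 1
        assert hb[0].r == pytest.approx(2.9, abs=1e-9)
        assert hb[0].angle == pytest.approx(180.0, abs=1e-6)

    def test_beyond_cutoff_not_detected(self):
        pose = ComplexPose(
            _gln_fragment(), _acceptor_ligand([5.0, 0, 0]), "p1"
        )
        assert not [r for r in detect_hbonds(pose) if r.group == "NH2"]

    def test_bad_angle_not_detected(self):
        """Donor H pointing away: 3.0 A but D-H...A angle 60 deg."""
        # place the acceptor O so that the angle at H is exactly 60 degrees
        ne2 = np.zeros(3)
        h = np.array([1.01, 0.0, 0.0])
        direction = Rotation.from_euler("z", 120, degrees=True).apply([1.0, 0, 0])
        o_pos = h + 2.5 * direction  # vector H->O at 120deg from H->(away from N)
        # angle(D-H, A-H): D-H = -x; A-H at 120 from +x -> angle = 60
        pose = ComplexPose(_gln_fragment(ne2), _acceptor_ligand(o_pos), "p1")
        recs = [r for r in detect_hbonds(pose)
                if r.group == "NH2" and np.isclose(r.angle, 60, atol=1)]
        assert not recs

    def test_ligand_donor_to_receptor_acceptor(self):
        """The interface is scanned in both directions."""
        oe1 = np.array([-1.33, -1.23, 0.0])
        n = oe1 + [0.0, -3.0, 0.0]
        lig = _mol_from_atoms(
            [
                ("N", n),
                ("H", n + [0.0, 1.01, 0.0]),  # aimed at OE1
                ("H", n + [0.95, -0.35, 0.0]),
                ("C", n + [-0.7, -1.2, 0.0]),
                ("H", n + [-1.4, -1.2, 0.9]),
                ("H", n + [-1.4, -1.2, -0.9]),
                ("H", n + [0.0, -2.2, 0.0]),
            ],
            [(0, 1, 1), (0, 2, 1), (0, 3, 1), (3, 4, 1), (3, 5, 1), (3, 6, 1)],
        )
        pose = ComplexPose(_gln_fragment(), lig, "p1")
        recs = [r for r in detect_hbonds(pose) if r.group == "CO"]
        assert len(recs) == 1
        assert recs[0].r == pytest.approx(3.0, abs=1e-9)

    def test_cutoff_monotonicity(self):
        pose = ComplexPose(
            _gln_fragment(), _acceptor_ligand([3.8, 0, 0]), "p1"
        )
        tight = detect_hbonds(pose, distance_cutoff=3.5)
        loose = detect_hbonds(pose, distance_cutoff=4.0)
        tight_keys = {(r.residue, r.group, r.ligand_part) for r in tight}
        loose_keys = {(r.residue, r.group, r.ligand_part) for r in loose}
        assert tight_keys <= loose_keys
        assert len(loose) > len(tight)


class TestPiStacking:
    def test_parallel_stack(self):
        pose = ComplexPose(
            _phe_ring(), _benzene([0, 0, 3.5], [0, 0, 1]), "p1"
        )
        recs = detect_pi_stacking(pose)
        assert len(recs) == 1
        assert recs[0].kind == "pi_parallel"
        assert recs[0].r == pytest.approx(3.5, abs=1e-9)

    def test_boundary_distance_inclusive(self):
        """5.5 A is included ('equal to or less than'); 5.6 A is not."""
        at = ComplexPose(_phe_ring(), _benzene([0, 0, 5.5], [0, 0, 1]), "p1")
        beyond = ComplexPose(_phe_ring(), _benzene([0, 0, 5.6], [0, 0, 1]), "p1")
        assert len(detect_pi_stacking(at)) == 1
        assert len(detect_pi_stacking(beyond)) == 0

    def test_perpendicular_is_tshaped(self):
        pose = ComplexPose(
            _phe_ring(), _benzene([0, 0, 5.0], [1, 0, 0]), "p1"
        )
        recs = detect_pi_stacking(pose)
        assert len(recs) == 1
        assert recs[0].kind == "pi_tshaped"
        assert recs[0].angle == pytest.approx(90.0, abs=1e-6)

    def test_intermediate_angle_unclassified(self):
        normal = Rotation.from_euler("y", 45, degrees=True).apply([0, 0, 1.0])
        pose = ComplexPose(_phe_ring(), _benzene([0, 0, 4.0], normal), "p1")
        recs = detect_pi_stacking(pose)
        assert recs[0].kind == "pi_unclassified"
        assert recs[0].angle == pytest.approx(45.0, abs=1e-6)

    def test_rigid_transform_invariance(self):
        rot = Rotation.from_euler("xyz", [31, -54, 17], degrees=True)
        shift = np.array([4.0, -7.0, 11.0])
        ring = _phe_ring()
        lig = _benzene([0, 0, 3.5], [0, 0, 1])
        base = detect_pi_stacking(ComplexPose(ring, lig, "p"))[0]
        ring2 = [
            ReceptorAtom(a.name, a.res_name, a.res_seq, a.chain, a.element,
                         rot.apply(a.xyz) + shift)
            for a in ring
        ]
        lig2 = Chem.Mol(lig)
        conf = lig2.GetConformer()
        for i, p in enumerate(rot.apply(lig.GetConformer().GetPositions()) + shift):
            conf.SetAtomPosition(i, Point3D(*p))
        moved = detect_pi_stacking(ComplexPose(ring2, lig2, "p"))[0]
        assert moved.r == pytest.approx(base.r, abs=1e-9)
        assert moved.angle == pytest.approx(base.angle, abs=1e-9)


class TestEcidalFilter:
    def _rec(self, residue, kind="hbond", group="x", r=3.0):
        return InteractionRecord(kind, residue, group, "0", r, 180.0)

    def test_fully_compliant(self):
        records = [
            self._rec("His961"),
            self._rec("Gln1001"),
            self._rec("Phe1004", kind="pi_parallel", group="ring"),
        ]
        ok, missing, satisfied = ecidal_filter(records, DEFAULT_ECIDAL_SPEC)
        assert ok and not missing and len(satisfied) == 3

    def test_missing_requirement_named(self):
        records = [
            self._rec("Gln1001"),
            self._rec("Phe1004", kind="pi_parallel", group="ring"),
        ]
        ok, missing, _ = ecidal_filter(records, DEFAULT_ECIDAL_SPEC)
        assert not ok
        assert missing == ["His961 hbond"]

    def test_alternate_satisfies(self):
        records = [
            self._rec("His961"),
            self._rec("Thr965"),  # hydroxyl alternate for Gln1001
            self._rec("Phe1004", kind="pi_tshaped", group="ring"),
        ]
        ok, missing, _ = ecidal_filter(records, DEFAULT_ECIDAL_SPEC)
        assert ok and not missing

    def test_empty_spec_rejected(self):
        with pytest.raises(ParameterError):
            ecidal_filter([], [])

    def test_monotone_in_records(self):
        base = [self._rec("His961")]
        ok1, _, _ = ecidal_filter(base, DEFAULT_ECIDAL_SPEC)
        more = base + [
            self._rec("Gln1001"),
            self._rec("Phe1004", kind="pi_parallel", group="ring"),
        ]
        ok2, _, _ = ecidal_filter(more, DEFAULT_ECIDAL_SPEC)
        assert (not ok1) and ok2  # adding records never flips true -> false


class TestSummaries:
    def test_mean_of_three(self):
        poses = [
            ("1", [InteractionRecord("hbond", "His961", "ring", "0", r, 170)])
            for r in (3.0, 3.2, 3.4)
        ]
        df = summarize_interactions(poses)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["N"] == 3
        assert row["mean"] == pytest.approx(3.2)

    def test_single_pose_sd_zero(self):
        df = summarize_interactions(
            [("1", [InteractionRecord("hbond", "His961", "ring", "0", 2.9, 175)])]
        )
        assert df.iloc[0]["sd"] == 0.0

    def test_shortest_per_pose_kept(self):
        recs = [
            InteractionRecord("hbond", "His961", "ring", "0", 3.5, 170),
            InteractionRecord("hbond", "His961", "ring", "1", 2.8, 160),
        ]
        df = summarize_interactions([("1", recs)])
        assert df.iloc[0]["N"] == 1
        assert df.iloc[0]["mean"] == pytest.approx(2.8)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(4)
        poses = []
        for k in range(15):
            recs = []
            if rng.random() < 0.7:
                recs.append(
                    InteractionRecord("hbond", "His961", "ring", "0",
                                      float(rng.uniform(2.7, 3.9)), 170)
                )
            if rng.random() < 0.4:
                recs.append(
                    InteractionRecord("pi_parallel", "Phe1004", "ring", "(0,)",
                                      float(rng.uniform(3.3, 5.4)), 5)
                )
            poses.append(("1", recs))
        df = summarize_interactions(poses)
        brute_his = sum(
            1 for _, recs in poses if any(r.residue == "His961" for r in recs)
        )
        got = df[df["residue"] == "His961"]
        assert got.iloc[0]["N"] == brute_his


class TestToyComplexes:
    def test_planted_hbond_realized_exactly(self):
        spec = ComplexSpec(
            interactions=[PlantedInteraction("His961", "hbond", distance=2.9)]
        )
        pose = generate_toy_complexes(spec)[0]
        hbonds = detect_hbonds(pose)
        assert len(hbonds) == 1
        assert hbonds[0].residue == "His961"
        assert hbonds[0].r == pytest.approx(2.9, abs=0.01)
        assert not detect_pi_stacking(pose)

    def test_planted_absent_pi_not_detected(self):
        spec = ComplexSpec(
            interactions=[
                PlantedInteraction(
                    "Phe1004", "pi_parallel", distance=5.6, present=False
                )
            ]
        )
        pose = generate_toy_complexes(spec)[0]
        assert not detect_pi_stacking(pose)

    def test_infeasible_spec_rejected(self):
        from fieldqsar.errors import InfeasibleSpecError

        with pytest.raises(InfeasibleSpecError):
            ComplexSpec(
                interactions=[
                    PlantedInteraction("His961", "hbond", distance=6.0)
                ]
            )

    def test_sampled_distances_recover_planted_mean(self):
        spec = ComplexSpec(
            interactions=[
                PlantedInteraction(
                    "His961", "hbond", distance=3.2, distance_sd=0.2
                )
            ],
            n_poses=20,
            seed=3,
        )
        poses = generate_toy_complexes(spec)
        analyzed = [(p.set_label, detect_hbonds(p)) for p in poses]
        df = summarize_interactions(analyzed)
        assert df.iloc[0]["N"] == 20
        assert 3.1 <= df.iloc[0]["mean"] <= 3.3

    def test_full_ecidal_compliance(self):
        spec = ComplexSpec(
            interactions=[
                PlantedInteraction("His961", "hbond", distance=3.45),
                PlantedInteraction("Gln1001", "hbond", group="NH2", distance=3.21),
                PlantedInteraction("Gln1001", "hbond", group="CO", distance=2.99),
                PlantedInteraction("Phe1004", "pi_parallel", distance=4.15),
            ]
        )
        pose = generate_toy_complexes(spec)[0]
        records = detect_hbonds(pose) + detect_pi_stacking(pose)
        ok, missing, _ = ecidal_filter(records, DEFAULT_ECIDAL_SPEC)
        assert ok, missing

    def test_receptor_pdb_round_trip(self, tmp_path):
        atoms, _ = default_receptor()
        p = tmp_path / "receptor.pdb"
        write_receptor_pdb(atoms, p)
        back = read_receptor_pdb(p)
        assert len(back) == len(atoms)
        by_key = {(a.res_name, a.res_seq, a.name): a.xyz for a in back}
        for a in atoms:
            assert np.allclose(
                by_key[(a.res_name, a.res_seq, a.name)], a.xyz, atol=1e-3
            )
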