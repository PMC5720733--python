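import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from fieldqsar.alignment import align_series
from fieldqsar.dataset import LigandTable
from fieldqsar.errors import ParameterError
from fieldqsar.fields import (
    COULOMB_KCAL,
    AtomParameters,
    assemble_descriptor_matrix,
    build_grid,
    electrostatic_values,
    field_values,
    gaussian_property_values,
    steric_values,
)
from fieldqsar.synthetic import SCAFFOLD_TEMPLATE_SMARTS

from conftest import single_atom_record


@pytest.fixture(scope="module")
def params():
    return AtomParameters.default()


def _formaldehyde():
    mol = Chem.AddHs(Chem.MolFromSmiles("C=O"))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    return mol


class TestGrid:
    def test_single_atom_lattice_counts(self):
        rec = single_atom_record("a")
        grid = build_grid(rec.coords, spacing=1.0, padding=3.0, exclusion=2.0)
        assert grid.dims == (7, 7, 7)
        assert grid.n_points == 343
        # brute-force oracle: integer lattice points with |r| < 2 are excluded
        pts = grid.lattice_points()
        excluded = int((np.linalg.norm(pts, axis=1) < 2.0).sum())
        assert excluded == 27
        assert grid.n_included == 316

    def test_zero_padding_excludes_the_atom_itself(self):
        rec = single_atom_record("a")
        grid = build_grid(rec.coords, spacing=1.0, padding=0.0, exclusion=2.0)
        assert grid.n_points == 1
        assert grid.n_included == 0

    def test_box_covers_padding(self, small_series):
        table, _ = small_series
        coords = np.vstack([r.coords for r in table])
        grid = build_grid(coords)
        pts = grid.lattice_points()
        assert np.all(pts.min(0) <= coords.min(0) - 3.0 + 1e-9)
        assert np.all(pts.max(0) >= coords.max(0) + 3.0 - 1.0)  # within a cell

    def test_empty_series_rejected(self):
        with pytest.raises(ParameterError):
            build_grid(np.zeros((0, 3)))


class TestStericField:
    def test_zero_crossing_and_minimum(self, params):
        rec = single_atom_record("a", element="C")
        eps, sig = params.combined("C")
        at_sigma = steric_values(rec, np.array([[sig, 0.0, 0.0]]), params)[0]
        at_min = steric_values(
            rec, np.array([[2 ** (1 / 6) * sig, 0.0, 0.0]]), params
        )[0]
        assert at_sigma == pytest.approx(0.0, abs=1e-9)
        assert at_min == pytest.approx(-eps, abs=1e-9)

    def test_truncation_at_plus_30(self, params):
        rec = single_atom_record("a")
        val = steric_values(rec, np.array([[0.1, 0.0, 0.0]]), params)[0]
        assert val == 30.0

    def test_unparameterized_element(self, params):
        rec = single_atom_record("a", element="Br")
        with pytest.raises(ParameterError, match="Br"):
            steric_values(rec, np.zeros((1, 3)), params)


class TestElectrostaticField:
    def test_zero_charges(self):
        rec = single_atom_record("a", charge=0.0)
        pts = np.random.default_rng(0).normal(size=(10, 3)) * 5 + 8
        assert np.allclose(electrostatic_values(rec, pts), 0.0)

    def test_coulomb_closed_form(self):
        rec = single_atom_record("a", charge=0.5)
        r = COULOMB_KCAL * 0.5 / 10.0  # distance where the energy is +10
        val = electrostatic_values(rec, np.array([[r, 0.0, 0.0]]))[0]
        assert val == pytest.approx(10.0, abs=1e-9)

    def test_clamped_to_pm30(self):
        plus = single_atom_record("a", charge=1.0)
        minus = single_atom_record("b", charge=-1.0)
        pt = np.array([[3.0, 0.0, 0.0]])  # unclamped |E| = 110.7
        assert electrostatic_values(plus, pt)[0] == 30.0
        assert electrostatic_values(minus, pt)[0] == -30.0


class TestGaussianFields:
    def test_acceptor_projected_point_peak_and_decay(self):
        """One acceptor feature -> value 1 at its projected point, Gaussian decay."""
        mol = _formaldehyde()
        o_idx = next(
            a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O"
        )
        c_idx = next(
            a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"
        )
        pos = mol.GetConformer().GetPositions()
        direction = pos[o_idx] - pos[c_idx]
        direction /= np.linalg.norm(direction)
        proj = pos[o_idx] + 1.0 * direction
        at_proj = gaussian_property_values(mol, proj[None], "acceptor")[0]
        assert at_proj == pytest.approx(1.0, abs=1e-9)
        # two Angstroms out along the same axis: exp(-0.3 * 4)
        at_2A = gaussian_property_values(
            mol, (proj + 2.0 * direction)[None], "acceptor"
        )[0]
        assert at_2A == pytest.approx(math.exp(-1.2), abs=1e-9)
        far = gaussian_property_values(mol, (proj + 100 * direction)[None], "acceptor")[0]
        assert far < 1e-12

    def test_hydrophobic_matches_brute_force(self, small_series):
        from rdkit.Chem import rdMolDescriptors

        table, _ = small_series
        mol = table.records[0].mol
        pts = np.random.default_rng(1).normal(size=(20, 3)) * 4
        vals = gaussian_property_values(mol, pts, "hydrophobic", alpha=0.3)
        contribs = np.array(
            [c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol)]
        )
        pos = mol.GetConformer().GetPositions()
        expected = np.array(
            [
                sum(
                    w * math.exp(-0.3 * np.sum((p - xyz) ** 2))
                    for w, xyz in zip(contribs, pos)
                )
                for p in pts
            ]
        )
        assert np.allclose(vals, expected, atol=1e-9)

    def test_alpha_monotone_decay(self, small_series):
        table, _ = small_series
        mol = table.records[0].mol
        pts = mol.GetConformer().GetPositions().mean(0)[None] + [[5.0, 2.0, 1.0]]
        for prop in ("hydrophobic", "acceptor", "donor"):
            v1 = abs(gaussian_property_values(mol, pts, prop, alpha=0.3)[0])
            v2 = abs(gaussian_property_values(mol, pts, prop, alpha=0.6)[0])
            assert v2 <= v1 + 1e-12

    def test_unknown_property_tag(self):
        with pytest.raises(ParameterError):
            gaussian_property_values(_formaldehyde(), np.zeros((1, 3)), "polar")


class TestFieldInvariants:
    def test_truncation_bounds_everywhere(self, small_series, params):
        table, _ = small_series
        grid = build_grid(np.vstack([r.coords for r in table]))
        pts = grid.included_points()
        for rec in table.records[:4]:
            s = field_values(rec, pts, "S", params=params)
            e = field_values(rec, pts, "E", params=params)
            assert np.all(np.isfinite(s)) and np.all(np.isfinite(e))
            assert s.max() <= 30.0 + 1e-12
            assert np.abs(e).max() <= 30.0 + 1e-12

    def test_rigid_translation_invariance(self, small_series, params):
        table, _ = small_series
        rec = table.records[0]
        grid = build_grid(rec.coords)
        shift = np.array([7.0, -3.0, 2.5])
        moved = rec.copy()
        moved.set_coords(rec.coords + shift)
        for tag in "SEHAD":
            base = field_values(rec, grid.included_points(), tag, params=params)
            after = field_values(
                moved, grid.translated(shift).included_points(), tag, params=params
            )
            assert np.allclose(base, after, atol=1e-9)


class TestDescriptorMatrix:
    def test_no_variance_series_eliminates_everything(self, small_series):
        table, _ = small_series
        clones = LigandTable(
            [
                type(table.records[0])(
                    id=f"c{k}",
                    set_label="x",
                    mol=Chem.Mol(table.records[0].mol),
                    ic50=1.0,
                )
                for k in range(4)
            ]
        )
        series = align_series(clones, "ppa", SCAFFOLD_TEMPLATE_SMARTS)
        grid = build_grid(np.vstack([r.coords for r in clones]))
        with pytest.warns(UserWarning, match="eliminated"):
            dm = assemble_descriptor_matrix(series, grid, ("S",))
        assert dm.n_retained == 0

    def test_elimination_matches_brute_force(self, small_series):
        table, _ = small_series
        series = align_series(table, "ppa", SCAFFOLD_TEMPLATE_SMARTS)
        train = table.ids[:10]
        grid = build_grid(np.vstack([table[i].coords for i in train]))
        dm = assemble_descriptor_matrix(
            series, grid, ("S", "H"), train_ids=train
        )
        train_rows = [dm.ids.index(i) for i in train]
        for tag in ("S", "H"):
            sds = dm.raw[tag][train_rows].std(axis=0, ddof=1)
            assert (dm.column_fields == tag).sum() == int((sds >= 0.01).sum())

    def test_block_scaling_unit_block_sd(self, small_series):
        table, _ = small_series
        series = align_series(table, "ppa", SCAFFOLD_TEMPLATE_SMARTS)
        grid = build_grid(np.vstack([r.coords for r in table]))
        dm = assemble_descriptor_matrix(series, grid, ("S", "E"))
        for tag in ("S", "E"):
            block = dm.X[:, dm.column_fields == tag]
            assert block.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_autoscaling_unit_column_sd(self, small_series):
        table, _ = small_series
        series = align_series(table, "ppa", SCAFFOLD_TEMPLATE_SMARTS)
        grid = build_grid(np.vstack([r.coords for r in table]))
        dm = assemble_descriptor_matrix(series, grid, ("S",), scaling="auto")
        sds = dm.X.std(axis=0, ddof=1)
        assert np.allclose(sds, 1.0, atol=1e-9)

    def test_row_stacking_equals_single_evaluations(self, small_series, params):
        table, _ = small_series
        series = align_series(table, "ppa", SCAFFOLD_TEMPLATE_SMARTS)
        grid = build_grid(np.vstack([r.coords for r in table]))
        dm = assemble_descriptor_matrix(series, grid, ("S", "H"))
        pts = grid.included_points()
        for k, rec in enumerate(series.records):
            for tag in ("S", "H"):
                solo = field_values(rec, pts, tag, params=params)
                assert np.allclose(dm.raw[tag][k], solo, atol=1e-12)

    def test_empty_field_set_rejected(self, small_series):
        table, _ = small_series
        series = align_series(table, "ppa", SCAFFOLD_TEMPLATE_SMARTS)
        grid = build_grid(np.vstack([r.coords for r in table]))
        with pytest.raises(ParameterError):
            assemble_descriptor_matrix(series, grid, ())

    def test_column_order_field_major_z_fastest(self, small_series):
        table, _ = small_series
        series = align_series(table, "ppa", SCAFFOLD_TEMPLATE_SMARTS)
        grid = build_grid(np.vstack([r.coords for r in table]))
        dm = assemble_descriptor_matrix(series, grid, ("S", "H"))
        # field-major blocks
        tags = list(dm.column_fields)
        assert tags == sorted(tags, key=("S", "H").index)
        # z-fastest: flat lattice indices strictly increase within a block
        for tag in ("S", "H"):
            pts_idx = dm.column_points[dm.column_fields == tag]
            assert np.all(np.diff(pts_idx) > 0)
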