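"""Template-based rigid alignment of a congeneric series.

Three schemes place every ligand in one coordinate frame:

* ``PPA`` / ``PA`` — template alignment: the atoms matching a common
  substructure (SMARTS) are superposed onto the same atoms of a reference
  compound by least-squares rigid fitting (Kabsch).  The two scheme names
  differ only in which template is used (e.g. the bicyclic heteroaromatic
  core versus the lactam head group of an inhibitor series).
* ``DA`` — docking alignment: externally docked poses already share the
  receptor frame and are passed through unchanged.

Only rigid superposition is performed; conformers are aligned as supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .dataset import LigandRecord, LigandTable
from .errors import (
    DegenerateGeometryError,
    MissingPoseError,
    NoTemplateMatchError,
    ParameterError,
)

__all__ = [
    "TemplateMatch",
    "AlignedSeries",
    "match_template",
    "kabsch_superpose",
    "align_series",
]

SCHEMES = ("PPA", "PA", "DA")


@dataclass
class TemplateMatch:
    """Mapping from template atoms to one ligand's atoms."""

    ligand_id: str
    pattern: str
    mapping: list[tuple[int, int]]  # (template atom, ligand atom)

    def __post_init__(self) -> None:
        lig_atoms = [j for _, j in self.mapping]
        if len(set(lig_atoms)) != len(lig_atoms):
            raise ParameterError("template mapping is not injective")

    @property
    def ligand_atoms(self) -> list[int]:
        return [j for _, j in self.mapping]


@dataclass
class AlignedSeries:
    """A ligand table in a common frame plus alignment bookkeeping."""

    scheme: str
    reference_id: str | None
    records: LigandTable
    template_rmsd: dict[str, float] = field(default_factory=dict)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, why)

    def all_coords(self) -> np.ndarray:
        return np.vstack([r.coords for r in self.records])


def kabsch_superpose(
    mobile_coords: np.ndarray, reference_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation + translation of mobile onto reference.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords @ rotation.T + translation`` superposes the mobile set.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ParameterError("coordinate sets must both be (n, 3)")
    if mob.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points to superpose")

    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    a, b = mob - mc, ref - rc
    # Collinear point sets leave the rotation about the line undetermined.
    for pts in (a, b):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError("points are (nearly) collinear")

    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def _all_matches(mol: Chem.Mol, pattern: str) -> list[tuple[int, ...]]:
    patt = Chem.MolFromSmarts(pattern)
    if patt is None:
        raise ParameterError(f"cannot parse SMARTS {pattern!r}")
    return list(mol.GetSubstructMatches(patt, uniquify=False, maxMatches=5000))


def match_template(
    ligand: LigandRecord,
    pattern: str | Sequence[int],
    reference_coords: np.ndarray | None = None,
) -> TemplateMatch:
    """Find the template atoms of one ligand.

    ``pattern`` is a SMARTS string or an explicit list of ligand atom
    indices (for molecules where aromatic perception is toolkit-dependent).
    Symmetric templates admit several automorphic matches; when reference
    template coordinates are given the match with the lowest superposition
    RMSD is kept, otherwise the first match in canonical order.
    """
    if not isinstance(pattern, str):
        idx = list(pattern)
        if len(idx) < 3:
            raise ParameterError("explicit template needs >= 3 atoms")
        return TemplateMatch(
            ligand.id, f"atoms:{idx}", [(k, j) for k, j in enumerate(idx)]
        )

    matches = _all_matches(ligand.mol, pattern)
    if not matches:
        raise NoTemplateMatchError(ligand.id, pattern)
    if reference_coords is None or len(matches) == 1:
        best = matches[0]
    else:
        coords = ligand.coords
        best, best_rmsd = None, np.inf
        for m in matches:
            try:
                _, _, rmsd = kabsch_superpose(coords[list(m)], reference_coords)
            except DegenerateGeometryError:
                continue
            if rmsd < best_rmsd - 1e-12:
                best, best_rmsd = m, rmsd
        if best is None:
            raise DegenerateGeometryError(
                f"all template matches of {ligand.id!r} are degenerate"
            )
    return TemplateMatch(
        ligand.id, pattern, [(k, j) for k, j in enumerate(best)]
    )


def _pick_reference(
    table: LigandTable, pattern: str | Mapping[str, Sequence[int]]
) -> str:
    """Default reference: the most potent compound containing the template."""
    candidates = sorted(
        table.records,
        key=lambda r: (-(r.p_activity or -np.inf), r.id),
    )
    for r in candidates:
        try:
            pat = pattern if isinstance(pattern, str) else pattern[r.id]
            match_template(r, pat)
            return r.id
        except (NoTemplateMatchError, KeyError):
            continue
    raise NoTemplateMatchError("<any>", str(pattern))


def align_series(
    table: LigandTable,
    scheme: str,
    pattern_or_poses: str | Mapping[str, Sequence[int]] | Mapping[str, Chem.Mol] | None,
    reference_id: str | None = None,
) -> AlignedSeries:
    """Place all ligands of a table in one frame.

    For template schemes (``ppa``/``pa``) each ligand's template atoms are
    rigidly superposed onto the reference compound's; ligands lacking the
    template are listed in ``excluded`` rather than silently dropped.  For
    ``da`` the supplied docked poses are passed through unchanged.
    """
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ParameterError(f"scheme must be one of {SCHEMES}, got {scheme!r}")

    if scheme == "DA":
        poses = pattern_or_poses or {}
        records = []
        for r in table:
            if r.id not in poses:
                raise MissingPoseError(f"no docked pose for {r.id!r}")
            rec = r.copy()
            pose = poses[r.id]
            pose_mol = pose.mol if isinstance(pose, LigandRecord) else pose
            rec.mol = Chem.Mol(pose_mol)
            records.append(rec)
        return AlignedSeries(
            scheme, None, LigandTable(records, list(table.provenance))
        )

    pattern = pattern_or_poses
    if pattern is None:
        raise ParameterError("template schemes require a pattern")
    if reference_id is None:
        reference_id = _pick_reference(table, pattern)
    ref_record = table[reference_id]
    ref_pat = pattern if isinstance(pattern, str) else pattern[reference_id]
    ref_match = match_template(ref_record, ref_pat)
    ref_tpl_coords = ref_record.coords[ref_match.ligand_atoms]

    records: list[LigandRecord] = []
    rmsds: dict[str, float] = {}
    excluded: list[tuple[str, str]] = []
    for r in table:
        try:
            pat = pattern if isinstance(pattern, str) else pattern[r.id]
        except KeyError:
            excluded.append((r.id, "no template atom map supplied"))
            continue
        try:
            m = match_template(r, pat, reference_coords=ref_tpl_coords)
        except NoTemplateMatchError as exc:
            excluded.append((r.id, str(exc)))
            continue
        coords = r.coords
        rot, trans, rmsd = kabsch_superpose(
            coords[m.ligand_atoms], ref_tpl_coords
        )
        rec = r.copy()
        rec.set_coords(coords @ rot.T + trans)
        records.append(rec)
        rmsds[r.id] = rmsd
    return AlignedSeries(
        scheme,
        reference_id,
        LigandTable(records, list(table.provenance)),
        rmsds,
        excluded,
    )
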