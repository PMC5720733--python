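"""Ligand tables, activity transforms, and the activity-stratified split.

Compounds live in :class:`LigandRecord` objects — an RDKit molecule with a
single 3D conformer plus its identity and inhibitory activity.  Activities
are IC50 values in micromolar, modelled on the log scale as

    p_activity = log10(10^6 / IC50[uM])

so that 1 uM maps to 6.0 and more potent compounds score higher.

The train/test split sorts compounds by activity, cuts the sorted list into
``round(n * test_fraction)`` consecutive groups and draws one test compound
per group, so the test set spans the full activity range.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import (
    DomainError,
    DuplicateIdError,
    FormatError,
    MissingActivityError,
    ParameterError,
)

__all__ = [
    "LigandRecord",
    "LigandTable",
    "SplitAssignment",
    "to_log_activity",
    "read_ligand_table",
    "write_ligand_table",
    "stratified_split",
    "partial_charges",
]

CHARGE_PROP = "partial_charge"


def to_log_activity(ic50_um: float) -> float:
    """Convert an IC50 in uM to the log activity log10(10^6 / IC50).

    Strictly decreasing in IC50; 1 uM -> 6.0.
    """
    if not ic50_um > 0:
        raise DomainError(f"IC50 must be positive, got {ic50_um}")
    return 6.0 - math.log10(ic50_um)


@dataclass
class LigandRecord:
    """One 3D small molecule with identity and activity.

    The RDKit molecule carries the atoms, bonds, stereo annotations and one
    conformer; ``ic50`` is in uM and ``p_activity`` on the log scale.
    """

    id: str
    set_label: str
    mol: Chem.Mol
    ic50: float | None = None
    p_activity: float | None = None

    def __post_init__(self) -> None:
        if self.mol.GetNumConformers() != 1:
            raise FormatError(
                f"record {self.id!r} must have exactly one conformer"
            )
        if self.ic50 is not None:
            p = to_log_activity(self.ic50)
            if self.p_activity is None:
                self.p_activity = p
            elif abs(self.p_activity - p) > 1e-9:
                raise FormatError(
                    f"record {self.id!r}: p_activity inconsistent with IC50"
                )
        if not np.all(np.isfinite(self.coords)):
            raise FormatError(f"record {self.id!r} has non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        """Atom coordinates in Angstrom, shape (n_atoms, 3)."""
        return self.mol.GetConformer().GetPositions()

    def set_coords(self, xyz: np.ndarray) -> None:
        conf = self.mol.GetConformer()
        for i, p in enumerate(np.asarray(xyz, dtype=float)):
            conf.SetAtomPosition(i, p.tolist())

    def copy(self) -> "LigandRecord":
        return LigandRecord(
            id=self.id,
            set_label=self.set_label,
            mol=Chem.Mol(self.mol),
            ic50=self.ic50,
            p_activity=self.p_activity,
        )


def partial_charges(mol: Chem.Mol) -> np.ndarray:
    """Per-atom partial charges in e.

    Atoms carrying an explicit ``partial_charge`` property (e.g. from a CSV
    override) win; otherwise Gasteiger charges are computed once and cached
    on the molecule.
    """
    if not all(a.HasProp(CHARGE_PROP) for a in mol.GetAtoms()):
        AllChem.ComputeGasteigerCharges(mol)
        for a in mol.GetAtoms():
            if not a.HasProp(CHARGE_PROP):
                a.SetDoubleProp(
                    CHARGE_PROP, a.GetDoubleProp("_GasteigerCharge")
                )
    q = np.array([a.GetDoubleProp(CHARGE_PROP) for a in mol.GetAtoms()])
    return np.nan_to_num(q, nan=0.0)


@dataclass
class LigandTable:
    """An ordered collection of ligand records with unique ids."""

    records: list[LigandRecord]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise DuplicateIdError(f"duplicate compound id {r.id!r}")
            seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LigandRecord]:
        return iter(self.records)

    def __getitem__(self, cid: str) -> LigandRecord:
        for r in self.records:
            if r.id == cid:
                return r
        raise KeyError(cid)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, ids: Sequence[str]) -> "LigandTable":
        want = set(ids)
        return LigandTable(
            [r for r in self.records if r.id in want], list(self.provenance)
        )

    def activities(self) -> np.ndarray:
        return np.array([r.p_activity for r in self.records], dtype=float)


def read_ligand_table(
    sdf_path: str | Path,
    activities_csv_path: str | Path,
    charges_csv_path: str | Path | None = None,
) -> LigandTable:
    """Read a V2000 SDF and its activity CSV into a :class:`LigandTable`.

    The CSV must have columns ``id, set_label, ic50_uM``; every SDF record
    (matched by title or an ``id`` property) needs a CSV row.  An optional
    charges CSV (``id, atom_index, charge``) overrides computed partial
    charges per atom.
    """
    sdf_path, activities_csv_path = Path(sdf_path), Path(activities_csv_path)
    df = pd.read_csv(activities_csv_path, dtype={"id": str, "set_label": str})
    missing_cols = {"id", "set_label", "ic50_uM"} - set(df.columns)
    if missing_cols:
        raise FormatError(
            f"activity CSV lacks columns: {sorted(missing_cols)}"
        )
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise DuplicateIdError(f"duplicate id {dup!r} in activity CSV")
    acts = df.set_index("id")

    overrides: dict[str, dict[int, float]] = {}
    if charges_csv_path is not None:
        qdf = pd.read_csv(charges_csv_path, dtype={"id": str})
        for cid, grp in qdf.groupby("id"):
            overrides[cid] = dict(
                zip(grp["atom_index"].astype(int), grp["charge"].astype(float))
            )

    supplier = Chem.SDMolSupplier(str(sdf_path), removeHs=False)
    records: list[LigandRecord] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise FormatError(f"unparsable SDF record at index {idx}")
        cid = (
            mol.GetProp("id")
            if mol.HasProp("id")
            else mol.GetProp("_Name").strip()
        )
        if not cid:
            raise FormatError(f"SDF record {idx} has no id/title")
        if cid not in acts.index:
            raise MissingActivityError(
                f"no activity row for SDF record {cid!r}"
            )
        row = acts.loc[cid]
        for i, q in overrides.get(cid, {}).items():
            mol.GetAtomWithIdx(i).SetDoubleProp(CHARGE_PROP, q)
        records.append(
            LigandRecord(
                id=cid,
                set_label=str(row["set_label"]),
                mol=mol,
                ic50=float(row["ic50_uM"]),
            )
        )
    return LigandTable(records, [str(sdf_path), str(activities_csv_path)])


def write_ligand_table(
    table: LigandTable, sdf_path: str | Path, csv_path: str | Path
) -> None:
    """Write a table as a multi-record V2000 SDF plus activity CSV."""
    writer = Chem.SDWriter(str(sdf_path))
    writer.SetForceV3000(False)
    rows = []
    for r in table:
        mol = Chem.Mol(r.mol)
        mol.SetProp("_Name", r.id)
        mol.SetProp("id", r.id)
        writer.write(mol)
        rows.append(
            {"id": r.id, "set_label": r.set_label, "ic50_uM": r.ic50}
        )
    writer.close()
    pd.DataFrame(rows).to_csv(csv_path, index=False)


@dataclass
class SplitAssignment:
    """Disjoint train/test id lists plus the group structure that made them."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    group_boundaries: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ParameterError("train and test ids overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train": self.train_ids,
                    "test": self.test_ids,
                    "seed": self.seed,
                    "group_boundaries": [list(b) for b in self.group_boundaries],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitAssignment":
        d = json.loads(Path(path).read_text())
        return cls(
            train_ids=d["train"],
            test_ids=d["test"],
            seed=int(d["seed"]),
            group_boundaries=[tuple(b) for b in d["group_boundaries"]],
        )


def stratified_split(
    table: LigandTable, test_fraction: float = 0.2, seed: int = 0
) -> SplitAssignment:
    """Activity-stratified split: one test compound per activity group.

    Compounds are sorted by activity (ties broken by id), partitioned into
    ``round(n * test_fraction)`` consecutive groups (the remainder adds one
    extra member to the lowest-activity groups), and one member per group is
    drawn at random into the test set.
    """
    if not (0 < test_fraction <= 0.5):
        raise ParameterError(
            f"test_fraction must lie in (0, 0.5], got {test_fraction}"
        )
    if any(r.p_activity is None for r in table):
        raise ParameterError("all records need p_activity before splitting")
    n = len(table)
    n_groups = round(n * test_fraction)
    if n_groups < 1 or n < n_groups:
        raise ParameterError(
            f"cannot form {n_groups} groups from {n} records"
        )

    order = sorted(table.records, key=lambda r: (r.p_activity, r.id))
    base, rem = divmod(n, n_groups)
    boundaries: list[tuple[int, int]] = []
    start = 0
    for g in range(n_groups):
        size = base + (1 if g < rem else 0)
        boundaries.append((start, start + size))
        start += size

    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    train_ids: list[str] = []
    for lo, hi in boundaries:
        pick = lo + int(rng.integers(hi - lo))
        for i in range(lo, hi):
            (test_ids if i == pick else train_ids).append(order[i].id)
    return SplitAssignment(train_ids, test_ids, seed, boundaries)
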