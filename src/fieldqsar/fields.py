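"""Molecular interaction grids and the five-field descriptor matrix.

A rectangular lattice (default 1 A spacing) is built around the aligned
training molecules, padded 3 A beyond their bounding box; lattice points
closer than 2 A to any training atom are excluded.  At every included point
five fields are evaluated per compound:

``S``  steric        Lennard-Jones 12-6 energy of an sp3-carbon probe,
                     truncated at +30 kcal/mol,
``E``  electrostatic Coulomb energy of a +1 e probe over partial charges
                     (332.0636 q/r, dielectric 1), truncated at +-30,
``H``  hydrophobic   Gaussian-attenuated sum of Ghose-Crippen atomic
                     hydrophobicity contributions,
``A``  acceptor      Gaussian field over acceptor feature points projected
``D``  donor         1 A along the idealized interaction direction.

Field values per column are scaled by the training-set standard deviation;
columns with sd < 0.01 are eliminated before regression.  Column order is
field-major, lattice z-fastest, so descriptor matrices are reproducible.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import ChemicalFeatures, rdMolDescriptors

from .alignment import AlignedSeries
from .dataset import LigandRecord, partial_charges
from .errors import ParameterError

__all__ = [
    "FieldGrid",
    "AtomParameters",
    "DescriptorMatrix",
    "FIELD_TAGS",
    "build_grid",
    "steric_values",
    "electrostatic_values",
    "gaussian_property_values",
    "field_values",
    "assemble_descriptor_matrix",
]

FIELD_TAGS = ("S", "E", "H", "A", "D")
COULOMB_KCAL = 332.0636  # kcal*A/(mol*e^2), vacuum dielectric
DEFAULT_TRUNCATION = 30.0  # kcal/mol, applied to S (upper) and E (both signs)
DEFAULT_ALPHA = 0.3  # 1/A^2 Gaussian attenuation for H/A/D
PROJECTION_LENGTH = 1.0  # A beyond the heavy atom for donor/acceptor points

_FEATURE_FACTORY = None


def _feature_factory():
    global _FEATURE_FACTORY
    if _FEATURE_FACTORY is None:
        _FEATURE_FACTORY = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        )
    return _FEATURE_FACTORY


@dataclass
class AtomParameters:
    """Lennard-Jones table plus the probe used for the steric field.

    Elements are combined with Lorentz-Berthelot rules against an sp3-carbon
    probe.  The shipped table is a compact element-wise set; it can be
    replaced by any CSV with columns ``element, epsilon_kcal_mol, sigma_A``.
    """

    epsilon: dict[str, float]
    sigma: dict[str, float]
    probe_epsilon: float = 0.066
    probe_sigma: float = 3.50
    probe_charge: float = 1.0

    @classmethod
    def default(cls) -> "AtomParameters":
        with resources.files("fieldqsar.data").joinpath("lj_params.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls.from_frame(df)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AtomParameters":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AtomParameters":
        eps = dict(zip(df["element"], df["epsilon_kcal_mol"].astype(float)))
        sig = dict(zip(df["element"], df["sigma_A"].astype(float)))
        if any(e < 0 for e in eps.values()) or any(s <= 0 for s in sig.values()):
            raise ParameterError("epsilon must be >= 0 and sigma > 0")
        return cls(eps, sig)

    def combined(self, element: str) -> tuple[float, float]:
        """Lorentz-Berthelot probe-atom (epsilon, sigma)."""
        if element not in self.epsilon:
            raise ParameterError(f"no Lennard-Jones parameters for {element!r}")
        eps = float(np.sqrt(self.probe_epsilon * self.epsilon[element]))
        sig = 0.5 * (self.probe_sigma + self.sigma[element])
        return eps, sig


@dataclass
class FieldGrid:
    """A regular lattice with an inclusion mask over its points.

    Lattice points are enumerated x-major / z-fastest:
    ``flat = (ix * ny + iy) * nz + iz``.
    """

    origin: np.ndarray  # (3,) A
    spacing: float  # A
    dims: tuple[int, int, int]
    included_mask: np.ndarray  # flat bool, z-fastest

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    @property
    def n_included(self) -> int:
        return int(self.included_mask.sum())

    def lattice_points(self) -> np.ndarray:
        """All lattice coordinates, shape (n_points, 3), z-fastest order."""
        nx, ny, nz = self.dims
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
        return self.origin + idx * self.spacing

    def included_points(self) -> np.ndarray:
        return self.lattice_points()[self.included_mask]

    def translated(self, shift: np.ndarray) -> "FieldGrid":
        return FieldGrid(
            self.origin + np.asarray(shift, float),
            self.spacing,
            self.dims,
            self.included_mask.copy(),
        )


def build_grid(
    series: AlignedSeries | np.ndarray,
    spacing: float = 1.0,
    padding: float = 3.0,
    exclusion: float = 2.0,
) -> FieldGrid:
    """Build the training lattice around an aligned series.

    The box extends ``padding`` beyond the union bounding box of all atoms;
    points strictly closer than ``exclusion`` to any atom are masked out.
    The grid must be built from the training subset only so that the lattice
    definition never sees test compounds.
    """
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    coords = (
        series.all_coords() if isinstance(series, AlignedSeries) else np.asarray(series, float)
    )
    if coords.size == 0:
        raise ParameterError("cannot build a grid from an empty series")
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    dims = tuple(int(np.floor((hi[k] - lo[k]) / spacing + 1e-9)) + 1 for k in range(3))
    grid = FieldGrid(lo, spacing, dims, np.ones(int(np.prod(dims)), bool))
    pts = grid.lattice_points()
    # chunk over atoms to keep memory flat for big training sets
    min_d2 = np.full(len(pts), np.inf)
    for start in range(0, len(coords), 256):
        block = coords[start : start + 256]
        d2 = ((pts[:, None, :] - block[None, :, :]) ** 2).sum(axis=2)
        min_d2 = np.minimum(min_d2, d2.min(axis=1))
    grid.included_mask = min_d2 >= exclusion**2
    return grid


def _distances(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(n_points, n_centers) Euclidean distances."""
    return np.sqrt(
        np.maximum(
            ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), 0.0
        )
    )


def steric_values(
    mol_or_record,
    points: np.ndarray,
    params: AtomParameters | None = None,
    truncation: float = DEFAULT_TRUNCATION,
) -> np.ndarray:
    """Lennard-Jones probe energy at arbitrary points (kcal/mol).

    Summed over atoms, then truncated from above at ``truncation``; the
    attractive well is never clipped.
    """
    mol = _as_mol(mol_or_record)
    params = params or AtomParameters.default()
    coords = mol.GetConformer().GetPositions()
    eps = np.empty(mol.GetNumAtoms())
    sig = np.empty(mol.GetNumAtoms())
    for i, a in enumerate(mol.GetAtoms()):
        eps[i], sig[i] = params.combined(a.GetSymbol())
    r = np.maximum(_distances(np.asarray(points, float), coords), 1e-6)
    sr6 = (sig[None, :] / r) ** 6
    vals = (4.0 * eps[None, :] * (sr6**2 - sr6)).sum(axis=1)
    return np.minimum(vals, truncation)


def electrostatic_values(
    mol_or_record,
    points: np.ndarray,
    probe_charge: float = 1.0,
    truncation: float = DEFAULT_TRUNCATION,
) -> np.ndarray:
    """Coulomb probe energy at arbitrary points, truncated to +-30 kcal/mol."""
    mol = _as_mol(mol_or_record)
    q = partial_charges(mol)
    coords = mol.GetConformer().GetPositions()
    r = np.maximum(_distances(np.asarray(points, float), coords), 1e-6)
    vals = COULOMB_KCAL * probe_charge * (q[None, :] / r).sum(axis=1)
    return np.clip(vals, -truncation, truncation)


def _hydrophobic_centers(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    """Atom positions and Ghose-Crippen hydrophobicity weights."""
    contribs = rdMolDescriptors._CalcCrippenContribs(mol)
    weights = np.array([c[0] for c in contribs], dtype=float)
    if np.any(np.isnan(weights)):
        warnings.warn("atoms without hydrophobic parameters get weight 0")
        weights = np.nan_to_num(weights)
    return mol.GetConformer().GetPositions(), weights


def _projected_feature_centers(
    mol: Chem.Mol, family: str
) -> tuple[np.ndarray, np.ndarray]:
    """Donor/acceptor feature points projected along the interaction direction.

    Donors contribute one point per D-H bond, 1 A beyond the heavy atom along
    the D-H vector; acceptors one point along the lone-pair bisector (away
    from the mean of the heavy-atom neighbours).  Each point has weight +1.
    """
    conf = mol.GetConformer()
    pos = conf.GetPositions()
    centers: list[np.ndarray] = []
    for feat in _feature_factory().GetFeaturesForMol(mol):
        if feat.GetFamily() != family:
            continue
        for ai in feat.GetAtomIds():
            atom = mol.GetAtomWithIdx(ai)
            a = pos[ai]
            if family == "Donor":
                for nb in atom.GetNeighbors():
                    if nb.GetAtomicNum() == 1:
                        v = pos[nb.GetIdx()] - a
                        nrm = np.linalg.norm(v)
                        if nrm > 1e-6:
                            centers.append(a + PROJECTION_LENGTH * v / nrm)
            else:
                heavy = [
                    pos[nb.GetIdx()]
                    for nb in atom.GetNeighbors()
                    if nb.GetAtomicNum() > 1
                ]
                if heavy:
                    v = a - np.mean(heavy, axis=0)
                    nrm = np.linalg.norm(v)
                    v = v / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
                else:  # isolated acceptor: no preferred direction
                    v = np.array([0.0, 0.0, 1.0])
                centers.append(a + PROJECTION_LENGTH * v)
    if not centers:
        return np.zeros((0, 3)), np.zeros(0)
    return np.asarray(centers), np.ones(len(centers))


def gaussian_property_values(
    mol_or_record,
    points: np.ndarray,
    prop: str,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Gaussian similarity field sum_c p_c exp(-alpha r_c^2) (dimensionless)."""
    mol = _as_mol(mol_or_record)
    if prop == "hydrophobic":
        centers, weights = _hydrophobic_centers(mol)
    elif prop == "acceptor":
        centers, weights = _projected_feature_centers(mol, "Acceptor")
    elif prop == "donor":
        centers, weights = _projected_feature_centers(mol, "Donor")
    else:
        raise ParameterError(f"unknown Gaussian property {prop!r}")
    pts = np.asarray(points, float)
    if len(centers) == 0:
        return np.zeros(len(pts))
    r2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (weights[None, :] * np.exp(-alpha * r2)).sum(axis=1)


_PROP_BY_TAG = {"H": "hydrophobic", "A": "acceptor", "D": "donor"}


def field_values(
    mol_or_record,
    points: np.ndarray,
    tag: str,
    params: AtomParameters | None = None,
    alpha: float = DEFAULT_ALPHA,
    truncation: float = DEFAULT_TRUNCATION,
) -> np.ndarray:
    """Evaluate one field (``S``/``E``/``H``/``A``/``D``) at given points."""
    if tag == "S":
        return steric_values(mol_or_record, points, params, truncation)
    if tag == "E":
        return electrostatic_values(mol_or_record, points, truncation=truncation)
    if tag in _PROP_BY_TAG:
        return gaussian_property_values(mol_or_record, points, _PROP_BY_TAG[tag], alpha)
    raise ParameterError(f"unknown field tag {tag!r}")


def _as_mol(mol_or_record) -> Chem.Mol:
    if isinstance(mol_or_record, LigandRecord):
        return mol_or_record.mol
    return mol_or_record


@dataclass
class DescriptorMatrix:
    """Compounds x (field, grid point) descriptor block, scaled and pruned.

    ``X`` holds the scaled retained columns for all rows (training and test
    alike, both transformed with training statistics).  ``raw`` keeps the
    unscaled per-field blocks over all included grid points so alternative
    scaling protocols can be replayed without re-evaluating the fields.
    """

    ids: list[str]
    train_ids: list[str]
    field_set: tuple[str, ...]
    grid: FieldGrid
    X: np.ndarray  # (n, n_retained) scaled
    column_fields: np.ndarray  # (n_retained,) field tag per column
    column_points: np.ndarray  # (n_retained,) flat lattice index per column
    train_sd: np.ndarray  # (n_retained,) pre-scaling per-column training sd
    column_scale: np.ndarray = None  # (n_retained,) divisor applied per column
    raw: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    sd_threshold: float = 0.01
    scaling: str = "block"  # "block": per-field overall sd; "auto": per-column
    block_sd: dict[str, float] = field(default_factory=dict)
    activities: dict[str, float] | None = None  # observed response per row id

    @property
    def n_retained(self) -> int:
        return self.X.shape[1]

    def rows_for(self, ids: Sequence[str]) -> np.ndarray:
        index = {cid: k for k, cid in enumerate(self.ids)}
        return self.X[[index[cid] for cid in ids]]

    def subset_fields(self, fields: Sequence[str]) -> "DescriptorMatrix":
        """Column-select a field combination (elimination/scaling unchanged)."""
        fields = tuple(fields)
        bad = set(fields) - set(self.field_set)
        if bad:
            raise ParameterError(f"fields {sorted(bad)} not in matrix")
        keep = np.isin(self.column_fields, list(fields))
        return DescriptorMatrix(
            ids=self.ids,
            train_ids=self.train_ids,
            field_set=fields,
            grid=self.grid,
            X=self.X[:, keep],
            column_fields=self.column_fields[keep],
            column_points=self.column_points[keep],
            train_sd=self.train_sd[keep],
            column_scale=self.column_scale[keep],
            raw={f: self.raw[f] for f in fields if f in self.raw},
            sd_threshold=self.sd_threshold,
            scaling=self.scaling,
            block_sd={f: self.block_sd[f] for f in fields if f in self.block_sd},
            activities=self.activities,
        )


def assemble_descriptor_matrix(
    series: AlignedSeries,
    grid: FieldGrid,
    field_set: Sequence[str] = FIELD_TAGS,
    train_ids: Sequence[str] | None = None,
    params: AtomParameters | None = None,
    alpha: float = DEFAULT_ALPHA,
    truncation: float = DEFAULT_TRUNCATION,
    sd_threshold: float = 0.01,
    scaling: str = "block",
    keep_raw: bool = True,
) -> DescriptorMatrix:
    """Evaluate fields for every compound and scale/prune by training sd.

    Columns whose per-column training standard deviation is below
    ``sd_threshold`` are eliminated.  Retained columns are then scaled by a
    training-set standard deviation: with ``scaling="block"`` (default) each
    field's columns are divided by one sd computed over all of that field's
    retained training entries, putting the heterogeneous fields on a common
    footing while preserving the spatial variance structure within a field;
    ``scaling="auto"`` divides every column by its own sd (classical
    autoscaling, which equalizes high- and low-information grid points and
    is known to amplify remote low-variance columns).  Test rows are always
    transformed with the training statistics, never their own.
    """
    if scaling not in ("block", "auto"):
        raise ParameterError("scaling must be 'block' or 'auto'")
    field_set = tuple(dict.fromkeys(field_set))
    if not field_set:
        raise ParameterError("field_set must not be empty")
    bad = set(field_set) - set(FIELD_TAGS)
    if bad:
        raise ParameterError(f"unknown field tags {sorted(bad)}")
    params = params or AtomParameters.default()

    ids = series.records.ids
    train_ids = list(train_ids) if train_ids is not None else list(ids)
    train_rows = np.array([cid in set(train_ids) for cid in ids])
    if not train_rows.any():
        raise ParameterError("no training rows in series")

    pts = grid.included_points()
    flat_idx = np.flatnonzero(grid.included_mask)

    blocks, col_fields, col_points, col_sd, col_scale = [], [], [], [], []
    raw: dict[str, np.ndarray] = {}
    block_sd: dict[str, float] = {}
    for tag in field_set:
        vals = np.empty((len(ids), len(pts)))
        for k, rec in enumerate(series.records):
            vals[k] = field_values(
                rec, pts, tag, params=params, alpha=alpha, truncation=truncation
            )
        if keep_raw:
            raw[tag] = vals
        sd = vals[train_rows].std(axis=0, ddof=1) if train_rows.sum() > 1 else np.zeros(len(pts))
        retain = sd >= sd_threshold
        if scaling == "auto":
            scale = sd[retain]
            block_sd[tag] = 1.0
        else:
            train_block = vals[train_rows][:, retain]
            bsd = float(train_block.std(ddof=1)) if train_block.size > 1 else 1.0
            bsd = bsd if bsd > 1e-12 else 1.0
            block_sd[tag] = bsd
            scale = np.full(retain.sum(), bsd)
        blocks.append(vals[:, retain] / scale[None, :])
        col_fields.append(np.full(retain.sum(), tag))
        col_points.append(flat_idx[retain])
        col_sd.append(sd[retain])
        col_scale.append(scale)

    X = np.hstack(blocks) if blocks else np.zeros((len(ids), 0))
    if X.shape[1] == 0:
        warnings.warn(
            "all descriptor columns eliminated (no variance over training set)"
        )
    return DescriptorMatrix(
        ids=list(ids),
        train_ids=train_ids,
        field_set=field_set,
        grid=grid,
        X=X,
        column_fields=np.concatenate(col_fields) if col_fields else np.zeros(0, dtype="<U1"),
        column_points=np.concatenate(col_points) if col_points else np.zeros(0, int),
        train_sd=np.concatenate(col_sd) if col_sd else np.zeros(0),
        column_scale=np.concatenate(col_scale) if col_scale else np.zeros(0),
        raw=raw,
        sd_threshold=sd_threshold,
        scaling=scaling,
        block_sd=block_sd,
    )
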