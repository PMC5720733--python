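"""Synthetic congeneric series and toy receptor-ligand complexes.

No machine-readable structures are deposited for the inhibitor series the
pipeline targets, so testing uses generated stand-ins:

* :func:`generate_congeneric_series` builds a congeneric series — a rigid
  benzene scaffold with small rigid substituents (H/C/N/O/F elements) at
  two para ring positions, placed by fixed internal coordinates so that all
  compounds share the scaffold frame exactly.  Activities are planted as a
  linear function of the package's own steric and hydrophobic field values
  at two fixed probe regions, one near each substituent site, affinely
  rescaled to span ~6 log units (mirroring the activity breadth of a real
  inhibitor collection), plus Gaussian noise.  The ground truth (regions,
  scale, noiseless activities) is returned for recovery tests.  This
  validation is self-referential by construction: it checks that the
  pipeline recovers a signal expressed in its own descriptor language, not
  that the descriptors match any experiment.

* :func:`generate_toy_complexes` builds pseudo-receptor/ligand poses with
  H-bonds and pi-stacks planted at exact target distances (His961, Gln1001
  amide NH2/CO, Thr965 OH, Asn843, Phe972, Phe1004 analogs), so interaction
  detection and the Table-style aggregation can be tested against known
  geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .dataset import LigandRecord, LigandTable
from .errors import InfeasibleSpecError, ParameterError
from .fields import AtomParameters, gaussian_property_values, steric_values
from .interactions import (
    HBOND_DISTANCE_CUTOFF,
    PI_CENTROID_CUTOFF,
    ComplexPose,
    ReceptorAtom,
)

__all__ = [
    "SeriesConfig",
    "ComplexSpec",
    "PlantedInteraction",
    "generate_congeneric_series",
    "generate_toy_complexes",
    "default_receptor",
    "SCAFFOLD_TEMPLATE_SMARTS",
    "TRUE_FIELD_COMBINATION",
]

SCAFFOLD_TEMPLATE_SMARTS = "c1ccccc1"
TRUE_FIELD_COMBINATION = ("S", "H")

RING_RADIUS = 1.39  # A, aromatic C-C
CH_BOND = 1.08

# Substituent geometries in a local frame: attachment bond along +x from the
# ring carbon at the origin.  (element, xyz, bond order to previous atom or
# to the ring carbon for the first atom.)
_SUB_LIBRARY: dict[str, list[tuple[str, tuple[float, float, float], int, int]]] = {
    # name: [(element, xyz, bonded_to (-1 = ring C), order)]
    "H": [("H", (1.08, 0.0, 0.0), -1, 1)],
    "F": [("F", (1.35, 0.0, 0.0), -1, 1)],
    "CH3": [
        ("C", (1.50, 0.0, 0.0), -1, 1),
        ("H", (1.864, 1.028, 0.0), 0, 1),
        ("H", (1.864, -0.514, 0.890), 0, 1),
        ("H", (1.864, -0.514, -0.890), 0, 1),
    ],
    "CF3": [
        ("C", (1.50, 0.0, 0.0), -1, 1),
        ("F", (1.944, 1.254, 0.0), 0, 1),
        ("F", (1.944, -0.627, 1.086), 0, 1),
        ("F", (1.944, -0.627, -1.086), 0, 1),
    ],
    "OH": [
        ("O", (1.36, 0.0, 0.0), -1, 1),
        ("H", (1.593, 0.892, 0.0), 0, 1),
    ],
    "NH2": [
        ("N", (1.40, 0.0, 0.0), -1, 1),
        ("H", (1.905, 0.828, 0.283), 0, 1),
        ("H", (1.905, -0.828, 0.283), 0, 1),
    ],
    "CN": [
        ("C", (1.43, 0.0, 0.0), -1, 1),
        ("N", (2.59, 0.0, 0.0), 0, 3),
    ],
}


@dataclass
class SeriesConfig:
    """Conditions for one synthetic congeneric series."""

    n: int = 60
    noise_sd: float = 0.3  # log-activity units
    seed: int = 0
    sites: tuple[int, ...] = (0, 3)  # ring positions carrying substituents
    library: tuple[str, ...] = tuple(_SUB_LIBRARY)
    activity_range: tuple[float, float] = (3.5, 9.5)  # planted log-activity span
    field_weights: tuple[float, float] = (1.0, 1.0)  # (steric, hydrophobic) betas
    steric_region_radius: float = 6.4  # A from ring centre, along site 0
    hydrophobic_region_radius: float = 3.9  # A, along site 1
    set_label: str = "syn"

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ParameterError("need at least 10 compounds")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        unknown = set(self.library) - set(_SUB_LIBRARY)
        if unknown:
            raise ParameterError(f"unknown substituents {sorted(unknown)}")


def _site_frame(ring_pos: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = math.radians(60.0 * ring_pos)
    u = np.array([math.cos(theta), math.sin(theta), 0.0])  # radial, local +x
    w = np.array([-math.sin(theta), math.cos(theta), 0.0])  # local +y
    return u, w, np.array([0.0, 0.0, 1.0])


def _build_compound(groups_by_site: dict[int, str]) -> Chem.Mol:
    """Assemble scaffold + substituents with fixed internal coordinates."""
    rw = Chem.RWMol()
    coords: list[np.ndarray] = []
    ring_idx = []
    for k in range(6):
        a = Chem.Atom("C")
        a.SetIsAromatic(True)
        ring_idx.append(rw.AddAtom(a))
        u, _, _ = _site_frame(k)
        coords.append(RING_RADIUS * u)
    for k in range(6):
        rw.AddBond(ring_idx[k], ring_idx[(k + 1) % 6], Chem.BondType.AROMATIC)
    for k in range(6):
        group = groups_by_site.get(k, "H")
        u, w, z = _site_frame(k)
        anchor = RING_RADIUS * u
        local_atoms = _SUB_LIBRARY[group]
        added: list[int] = []
        for element, (lx, ly, lz), bonded_to, order in local_atoms:
            idx = rw.AddAtom(Chem.Atom(element))
            coords.append(anchor + lx * u + ly * w + lz * z)
            parent = ring_idx[k] if bonded_to == -1 else added[bonded_to]
            rw.AddBond(
                idx,
                parent,
                {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}[order],
            )
            added.append(idx)
    mol = rw.GetMol()
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(True)
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, p in enumerate(coords):
        # quantize to the SDF V2000 coordinate precision so that writing a
        # generated series and reading it back is the identity
        conf.SetAtomPosition(i, Point3D(*np.round(p, 4)))
    mol.AddConformer(conf)
    _check_clashes(mol)
    return mol


def _check_clashes(mol: Chem.Mol, min_dist: float = 1.0) -> None:
    pos = mol.GetConformer().GetPositions()
    bonded = {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    }
    n = len(pos)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) in bonded:
                continue
            if d[i, j] < min_dist:
                raise InfeasibleSpecError(
                    f"steric clash between atoms {i} and {j}: {d[i, j]:.2f} A"
                )


def generate_congeneric_series(
    config: SeriesConfig | None = None,
) -> tuple[LigandTable, dict]:
    """Generate a congeneric series with planted field-linear activities.

    Returns the ligand table and a ground-truth record holding the probe
    regions, the affine activity scale, per-compound noiseless activities
    and the true field combination.  Identical config and seed give
    identical output.
    """
    config = config or SeriesConfig()
    rng = np.random.default_rng(config.seed)
    params = AtomParameters.default()

    u0, _, _ = _site_frame(config.sites[0])
    u1, _, _ = _site_frame(config.sites[1])
    steric_center = config.steric_region_radius * u0
    hydro_center = config.hydrophobic_region_radius * u1
    w_s, w_h = config.field_weights
    if w_s == 0 and w_h == 0:
        raise ParameterError("at least one planted field weight must be nonzero")
    regions = [
        {"field": "S", "center": steric_center.tolist(), "weight": w_s},
        {"field": "H", "center": hydro_center.tolist(), "weight": w_h},
    ]

    lib = list(config.library)
    choices = rng.integers(len(lib), size=(config.n, len(config.sites)))
    mols: list[Chem.Mol] = []
    group_names: list[list[str]] = []
    for row in choices:
        groups = {site: lib[g] for site, g in zip(config.sites, row)}
        for attempt in range(100):
            try:
                mols.append(_build_compound(groups))
                break
            except InfeasibleSpecError:
                resample = rng.integers(len(lib), size=len(config.sites))
                groups = {
                    site: lib[g] for site, g in zip(config.sites, resample)
                }
        else:
            raise InfeasibleSpecError("could not place substituents in 100 tries")
        group_names.append([groups[s] for s in config.sites])

    pts = np.array([steric_center, hydro_center])
    s_raw = np.array([steric_values(m, pts[:1], params)[0] for m in mols])
    h_raw = np.array(
        [gaussian_property_values(m, pts[1:], "hydrophobic")[0] for m in mols]
    )

    # standardize each planted term so both fields carry comparable signal,
    # then rescale the sum to the target activity span (affine, hence still
    # linear in the field values)
    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        if sd < 1e-9:
            raise InfeasibleSpecError("planted field effect has no variance")
        return (v - v.mean()) / sd

    effect = w_s * _z(s_raw) + w_h * _z(h_raw)
    lo, hi = config.activity_range
    span = effect.max() - effect.min()
    if span < 1e-9:
        raise InfeasibleSpecError("planted activities are degenerate")
    y_true = lo + (effect - effect.min()) * (hi - lo) / span
    noise = rng.normal(0.0, config.noise_sd, size=config.n)
    y = y_true + noise

    records = []
    truth_y: dict[str, float] = {}
    for k, (mol, yk, ytk) in enumerate(zip(mols, y, y_true)):
        cid = f"{config.set_label}-{k + 1:03d}"
        ic50 = 10.0 ** (6.0 - yk)
        records.append(
            LigandRecord(id=cid, set_label=config.set_label, mol=mol, ic50=ic50)
        )
        truth_y[cid] = float(ytk)

    ground_truth = {
        "seed": config.seed,
        "true_fields": [
            f for f, w in zip(TRUE_FIELD_COMBINATION, config.field_weights) if w != 0
        ],
        "regions": regions,
        "activity_range": list(config.activity_range),
        "noise_sd": config.noise_sd,
        "noiseless_activity": truth_y,
        "substituents": {
            rec.id: dict(zip(map(str, config.sites), names))
            for rec, names in zip(records, group_names)
        },
    }
    return LigandTable(records, ["synthetic"]), ground_truth


# ---------------------------------------------------------------------------
# toy receptor-ligand complexes
# ---------------------------------------------------------------------------


@dataclass
class PlantedInteraction:
    """One interaction to realize (or to place safely beyond its cutoff)."""

    residue: str  # "His961", "Gln1001", "Thr965", "Asn843", "Phe972", "Phe1004"
    kind: str  # "hbond" | "pi_parallel" | "pi_tshaped"
    group: str = ""  # "NH2" or "CO" for Gln1001; ignored elsewhere
    distance: float = 3.0  # A, target heavy-atom / centroid distance
    distance_sd: float = 0.0
    present: bool = True


@dataclass
class ComplexSpec:
    """Pseudo-receptor placements plus per-pose planted interactions."""

    interactions: list[PlantedInteraction]
    n_poses: int = 1
    set_label: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.interactions:
            raise ParameterError("spec must plant at least one interaction")
        for p in self.interactions:
            cutoff = (
                PI_CENTROID_CUTOFF
                if p.kind.startswith("pi")
                else HBOND_DISTANCE_CUTOFF
            )
            if p.present and p.distance > cutoff:
                raise InfeasibleSpecError(
                    f"{p.residue}: planted-present distance {p.distance} "
                    f"exceeds the {cutoff} A cutoff"
                )
            if not p.present and p.distance <= cutoff:
                raise InfeasibleSpecError(
                    f"{p.residue}: planted-absent distance {p.distance} "
                    f"is within the {cutoff} A cutoff"
                )


def _hexagon(center: np.ndarray, normal: np.ndarray, radius: float = RING_RADIUS):
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return [
        center
        + radius * (math.cos(math.radians(60 * k)) * e1 + math.sin(math.radians(60 * k)) * e2)
        for k in range(6)
    ]


def _pentagon(center: np.ndarray, normal: np.ndarray, radius: float = 1.16):
    normal = normal / np.linalg.norm(normal)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(normal, e1)
    e2 /= np.linalg.norm(e2)
    e1 = np.cross(e2, normal)
    return [
        center
        + radius * (math.cos(math.radians(72 * k)) * e1 + math.sin(math.radians(72 * k)) * e2)
        for k in range(5)
    ]


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def default_receptor() -> tuple[list[ReceptorAtom], dict]:
    """Fixed pseudo-receptor residues and their planting geometry.

    Returns the atom list plus, per (residue, group), the anchor point and
    unit direction along which a ligand partner realizes a target distance.
    """
    atoms: list[ReceptorAtom] = []
    geom: dict[tuple[str, str], dict] = {}

    def add(name, res_name, res_seq, element, xyz):
        atoms.append(
            ReceptorAtom(name, res_name, res_seq, "A", element, np.asarray(xyz, float))
        )

    # Phe1004: benzene in the xy-plane at the origin; partners stack along +z
    phe4 = _hexagon(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    for nm, p in zip(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"], phe4):
        add(nm, "PHE", 1004, "C", p)
    geom[("Phe1004", "ring")] = {
        "anchor": np.zeros(3),
        "direction": np.array([0.0, 0.0, 1.0]),
        "normal": np.array([0.0, 0.0, 1.0]),
    }

    # Phe972: second aromatic ring, well separated
    c972 = np.array([9.0, -5.0, 0.0])
    for nm, p in zip(
        ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"],
        _hexagon(c972, np.array([0.0, 0.0, 1.0])),
    ):
        add(nm, "PHE", 972, "C", p)
    geom[("Phe972", "ring")] = {
        "anchor": c972,
        "direction": np.array([0.0, 0.0, 1.0]),
        "normal": np.array([0.0, 0.0, 1.0]),
    }

    # His961: imidazole in the xy-plane; NE2-H donor points radially outward
    his_center = np.array([-6.0, 5.0, 3.0])
    ring = _pentagon(his_center, np.array([0.0, 0.0, 1.0]))
    for nm, el, p in zip(
        ["CG", "ND1", "CE1", "NE2", "CD2"],
        ["C", "N", "C", "N", "C"],
        ring,
    ):
        add(nm, "HIS", 961, el, p)
    ne2 = ring[3]
    u_his = _unit(ne2 - his_center)
    add("HE2", "HIS", 961, "H", ne2 + 1.01 * u_his)
    geom[("His961", "ring")] = {"anchor": ne2, "direction": u_his}

    # Gln1001 side-chain amide: NE2 donor up, OE1 acceptor down
    cd = np.array([7.0, 4.0, 3.0])
    oe1 = cd + 1.23 * np.array([0.0, -1.0, 0.0])
    u_ne2 = _unit([0.0, 0.94, 0.342])
    ne2q = cd + 1.33 * u_ne2
    add("CG", "GLN", 1001, "C", cd + 1.52 * np.array([-0.8, 0.0, -0.6]))
    add("CD", "GLN", 1001, "C", cd)
    add("OE1", "GLN", 1001, "O", oe1)
    add("NE2", "GLN", 1001, "N", ne2q)
    add("HE21", "GLN", 1001, "H", ne2q + 1.01 * u_ne2)
    add("HE22", "GLN", 1001, "H", ne2q + 1.01 * _unit([0.9, 0.2, 0.37]))
    geom[("Gln1001", "NH2")] = {"anchor": ne2q, "direction": u_ne2}
    geom[("Gln1001", "CO")] = {
        "anchor": oe1,
        "direction": np.array([0.0, -1.0, 0.0]),
        "acceptor": True,
    }

    # Thr965 hydroxyl
    og1 = np.array([14.0, 9.0, 5.0])
    u_thr = _unit([0.3, 0.6, 0.74])
    add("CB", "THR", 965, "C", og1 + 1.43 * np.array([0.0, -0.7, -0.714]))
    add("OG1", "THR", 965, "O", og1)
    add("HG1", "THR", 965, "H", og1 + 0.96 * u_thr)
    geom[("Thr965", "OH")] = {"anchor": og1, "direction": u_thr}

    # Asn843 side-chain amide
    cg = np.array([-9.0, -7.0, 1.0])
    od1 = cg + 1.23 * np.array([0.0, -1.0, 0.0])
    u_nd2 = _unit([0.34, 0.94, 0.0])
    nd2 = cg + 1.33 * u_nd2
    add("CG", "ASN", 843, "C", cg)
    add("OD1", "ASN", 843, "O", od1)
    add("ND2", "ASN", 843, "N", nd2)
    add("HD21", "ASN", 843, "H", nd2 + 1.01 * u_nd2)
    add("HD22", "ASN", 843, "H", nd2 + 1.01 * _unit([0.94, -0.2, 0.28]))
    geom[("Asn843", "NH2")] = {"anchor": nd2, "direction": u_nd2}

    return atoms, geom


def _add_fragment(rw, coords, frag):
    """frag: list of (element, xyz, bonded_to index within frag or None, order)."""
    added = []
    for element, xyz, bonded_to, order in frag:
        idx = rw.AddAtom(Chem.Atom(element))
        coords.append(np.asarray(xyz, float))
        if bonded_to is not None:
            rw.AddBond(
                idx,
                added[bonded_to],
                {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}[order],
            )
        added.append(idx)
    return added


def _acceptor_fragment(o_pos: np.ndarray, toward: np.ndarray) -> list:
    """Formaldehyde with its carbonyl O at ``o_pos``, C kept off-axis."""
    side = np.cross(toward, [0.0, 0.0, 1.0])
    if np.linalg.norm(side) < 0.1:
        side = np.cross(toward, [0.0, 1.0, 0.0])
    side = _unit(side)
    c = o_pos + 1.22 * side
    h1 = c + 1.09 * _unit(side + np.array([0.0, 0.0, 0.9]))
    h2 = c + 1.09 * _unit(side + np.array([0.0, 0.0, -0.9]))
    return [
        ("O", o_pos, None, 1),
        ("C", c, 0, 2),
        ("H", h1, 1, 1),
        ("H", h2, 1, 1),
    ]


def _donor_fragment(n_pos: np.ndarray, h_toward: np.ndarray) -> list:
    """Methylamine with one N-H aimed along ``h_toward``."""
    h_toward = _unit(h_toward)
    side = np.cross(h_toward, [0.0, 0.0, 1.0])
    if np.linalg.norm(side) < 0.1:
        side = np.cross(h_toward, [0.0, 1.0, 0.0])
    side = _unit(side)
    c = n_pos + 1.47 * _unit(-h_toward + 0.8 * side)
    h_n2 = n_pos + 1.01 * _unit(-h_toward - 0.8 * side)
    frag = [
        ("N", n_pos, None, 1),
        ("H", n_pos + 1.01 * h_toward, 0, 1),
        ("H", h_n2, 0, 1),
        ("C", c, 0, 1),
    ]
    up = np.array([0.0, 0.0, 1.0])
    for k, d in enumerate([up, _unit(side + up * -0.5), _unit(-side + up * -0.5)]):
        frag.append(("H", c + 1.09 * d, 3, 1))
    return frag


def generate_toy_complexes(spec: ComplexSpec) -> list[ComplexPose]:
    """Construct poses realizing the planted interactions exactly.

    Present interactions are realized within 1e-2 A of their (per-pose
    sampled) target distance; absent ones are placed beyond the detection
    cutoff.  Fragment chemistry is deliberately minimal (formaldehyde
    acceptors, methylamine donors, benzene rings) — geometry, not realism,
    is the point.
    """
    receptor, geom = default_receptor()
    rng = np.random.default_rng(spec.seed)
    poses: list[ComplexPose] = []

    for k in range(spec.n_poses):
        rw = Chem.RWMol()
        coords: list[np.ndarray] = []
        for planted in spec.interactions:
            d = planted.distance + (
                rng.normal(0.0, planted.distance_sd)
                if planted.distance_sd > 0
                else 0.0
            )
            cutoff = (
                PI_CENTROID_CUTOFF
                if planted.kind.startswith("pi")
                else HBOND_DISTANCE_CUTOFF
            )
            # keep sampled distances on the intended side of the cutoff
            d = min(d, cutoff - 0.05) if planted.present else max(d, cutoff + 0.05)
            d = max(d, 2.5)

            key = (planted.residue, planted.group or _default_group(planted.residue))
            if key not in geom:
                raise InfeasibleSpecError(f"no planting geometry for {key}")
            g = geom[key]
            anchor, direction = g["anchor"], g["direction"]

            if planted.kind.startswith("pi"):
                centroid = anchor + d * direction
                if planted.kind == "pi_tshaped":
                    ring_normal = _unit(np.cross(g["normal"], [1.0, 0.0, 0.0]))
                else:
                    ring_normal = g["normal"]
                ring_pts = _hexagon(centroid, ring_normal)
                frag = [("C", p, None if i == 0 else i - 1, 1) for i, p in enumerate(ring_pts)]
                idxs = _add_fragment(rw, coords, frag)
                rw.AddBond(idxs[5], idxs[0], Chem.BondType.SINGLE)
                for b in rw.GetBonds():
                    if b.GetBeginAtomIdx() in idxs and b.GetEndAtomIdx() in idxs:
                        b.SetBondType(Chem.BondType.AROMATIC)
                        b.SetIsAromatic(True)
                for i in idxs:
                    rw.GetAtomWithIdx(i).SetIsAromatic(True)
                for p, i in zip(ring_pts, idxs):
                    h = rw.AddAtom(Chem.Atom("H"))
                    coords.append(centroid + _unit(p - centroid) * (RING_RADIUS + CH_BOND))
                    rw.AddBond(h, i, Chem.BondType.SINGLE)
            elif g.get("acceptor"):
                # receptor acceptor: ligand donates; N at distance d, N-H aimed back
                n_pos = anchor + d * direction
                _add_fragment(rw, coords, _donor_fragment(n_pos, -direction))
            else:
                # receptor donor: ligand accepts; carbonyl O on the D-H axis
                o_pos = anchor + d * direction
                _add_fragment(rw, coords, _acceptor_fragment(o_pos, direction))

        mol = rw.GetMol()
        for atom in mol.GetAtoms():
            atom.SetNoImplicit(True)
        Chem.SanitizeMol(mol)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, p in enumerate(coords):
            conf.SetAtomPosition(i, Point3D(*np.round(p, 4)))
        mol.AddConformer(conf)
        mol.SetProp("_Name", f"{spec.set_label}-pose-{k + 1}")
        poses.append(
            ComplexPose(
                receptor=receptor,
                ligand=mol,
                pose_id=f"{spec.set_label}-pose-{k + 1}",
                set_label=spec.set_label,
            )
        )
    return poses


def _default_group(residue: str) -> str:
    if residue.startswith("Phe"):
        return "ring"
    if residue == "His961":
        return "ring"
    if residue == "Thr965":
        return "OH"
    if residue == "Asn843":
        return "NH2"
    return "NH2"
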