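"""Protein-ligand H-bond and pi-stacking geometry, and pose filtering.

Hydrogen bonds are recorded between donor and acceptor heavy atoms across
the receptor-ligand interface when the heavy-atom distance is at most
4.0 A and the D-H...A angle at least 120 deg (both configurable; receptor
donor hydrogens are placed at idealized geometry when absent).

Pi-stacking is recorded for aromatic ring pairs whose centroid distance is
at most 5.5 A, classified by the angle between ring normals: <= 30 deg is
parallel (sandwich / parallel-displaced), >= 60 deg is T-shaped, and the
band in between is reported unclassified with its angle.

A pose *complies* with a required-interaction specification (the essential
chemical interactions of an analog series, e.g. H-bonds to His961 and
Gln1001 plus pi-stacking with Phe1004, with Thr965 as an allowed H-bond
alternate) when every requirement — or one of its alternates — is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import FormatError, ParameterError
from .fields import _feature_factory

__all__ = [
    "ReceptorAtom",
    "ComplexPose",
    "InteractionRecord",
    "detect_hbonds",
    "detect_pi_stacking",
    "ecidal_filter",
    "summarize_interactions",
    "read_receptor_pdb",
    "write_receptor_pdb",
    "DEFAULT_ECIDAL_SPEC",
]

HBOND_DISTANCE_CUTOFF = 4.0  # A, donor-acceptor heavy atoms
HBOND_ANGLE_CUTOFF = 120.0  # deg, D-H...A
PI_CENTROID_CUTOFF = 5.5  # A, ring centroid-centroid
PI_PARALLEL_MAX_ANGLE = 30.0  # deg between ring normals
PI_TSHAPED_MIN_ANGLE = 60.0


@dataclass
class ReceptorAtom:
    name: str
    res_name: str
    res_seq: int
    chain: str
    element: str
    xyz: np.ndarray

    @property
    def residue(self) -> str:
        return f"{self.res_name.capitalize()}{self.res_seq}"


@dataclass
class ComplexPose:
    """One receptor + one docked ligand pose."""

    receptor: list[ReceptorAtom]
    ligand: Chem.Mol
    pose_id: str
    set_label: str = ""

    def __post_init__(self) -> None:
        if self.ligand.GetNumConformers() != 1:
            raise FormatError(f"pose {self.pose_id!r} needs one conformer")


@dataclass
class InteractionRecord:
    kind: str  # hbond | pi_parallel | pi_tshaped | pi_unclassified
    residue: str  # e.g. "Gln1001"
    group: str  # e.g. "NH2", "CO", "OH", "ring"
    ligand_part: str  # atom index or ring atom tuple, as text
    r: float  # A
    angle: float  # deg

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.residue, self.group, self.kind)


# (res_name, atom_name) -> (roles, group tag).  Side-chain polar atoms of the
# residues that matter for a nucleotide-binding pocket, plus backbone N/O.
RECEPTOR_POLAR: dict[tuple[str, str], tuple[frozenset, str]] = {
    ("HIS", "ND1"): (frozenset({"donor", "acceptor"}), "ring"),
    ("HIS", "NE2"): (frozenset({"donor", "acceptor"}), "ring"),
    ("GLN", "NE2"): (frozenset({"donor"}), "NH2"),
    ("GLN", "OE1"): (frozenset({"acceptor"}), "CO"),
    ("ASN", "ND2"): (frozenset({"donor"}), "NH2"),
    ("ASN", "OD1"): (frozenset({"acceptor"}), "CO"),
    ("THR", "OG1"): (frozenset({"donor", "acceptor"}), "OH"),
    ("SER", "OG"): (frozenset({"donor", "acceptor"}), "OH"),
    ("TYR", "OH"): (frozenset({"donor", "acceptor"}), "OH"),
}
BACKBONE_POLAR = {"N": (frozenset({"donor"}), "bb"), "O": (frozenset({"acceptor"}), "bb")}

RECEPTOR_RING_ATOMS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
    ],
}

# Required interactions of the analog series, with the observed hydroxyl
# alternate for the Gln1001 H-bond.
DEFAULT_ECIDAL_SPEC: list[dict] = [
    {"kind": "hbond", "residue": "His961"},
    {"kind": "hbond", "residue": "Gln1001",
     "alternates": [{"kind": "hbond", "residue": "Thr965"}]},
    {"kind": "pi", "residue": "Phe1004"},
]


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _residue_atoms(
    receptor: Sequence[ReceptorAtom],
) -> dict[tuple[str, int, str], list[ReceptorAtom]]:
    out: dict[tuple[str, int, str], list[ReceptorAtom]] = {}
    for a in receptor:
        out.setdefault((a.res_name, a.res_seq, a.chain), []).append(a)
    return out


def _receptor_donor_hydrogens(
    donor: ReceptorAtom, residue_atoms: list[ReceptorAtom]
) -> list[np.ndarray]:
    """Explicit hydrogens bonded to a donor, or one idealized position."""
    hs = [
        a.xyz
        for a in residue_atoms
        if a.element == "H" and np.linalg.norm(a.xyz - donor.xyz) < 1.3
    ]
    if hs:
        return hs
    heavy = [
        a.xyz
        for a in residue_atoms
        if a.element != "H"
        and a.name != donor.name
        and np.linalg.norm(a.xyz - donor.xyz) < 1.8
    ]
    if not heavy:
        return []
    v = donor.xyz - np.mean(heavy, axis=0)
    n = np.linalg.norm(v)
    if n < 1e-6:
        return []
    return [donor.xyz + 1.0 * v / n]


def _ligand_polar_atoms(mol: Chem.Mol) -> tuple[list[int], list[int]]:
    """(donor heavy atoms with explicit H, acceptor heavy atoms)."""
    donors: list[int] = []
    acceptors: list[int] = []
    for feat in _feature_factory().GetFeaturesForMol(mol):
        fam = feat.GetFamily()
        if fam not in ("Donor", "Acceptor"):
            continue
        for ai in feat.GetAtomIds():
            atom = mol.GetAtomWithIdx(ai)
            if fam == "Donor" and any(
                nb.GetAtomicNum() == 1 for nb in atom.GetNeighbors()
            ):
                donors.append(ai)
            elif fam == "Acceptor":
                acceptors.append(ai)
    return sorted(set(donors)), sorted(set(acceptors))


def detect_hbonds(
    pose: ComplexPose,
    distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> list[InteractionRecord]:
    """All interface H-bonds, in both donor-acceptor directions.

    Distance is measured between the donor and acceptor heavy atoms; the
    angle criterion is the D-H...A angle using the best available hydrogen.
    """
    lig = pose.ligand
    lig_pos = lig.GetConformer().GetPositions()
    lig_donors, lig_acceptors = _ligand_polar_atoms(lig)
    by_res = _residue_atoms(pose.receptor)
    records: list[InteractionRecord] = []

    for (res_name, res_seq, _chain), atoms in by_res.items():
        for a in atoms:
            roles_group = RECEPTOR_POLAR.get((res_name, a.name)) or BACKBONE_POLAR.get(
                a.name if a.name in ("N", "O") else ""
            )
            if roles_group is None:
                continue
            roles, group = roles_group
            if "donor" in roles:
                hs = _receptor_donor_hydrogens(a, atoms)
                for ai in lig_acceptors:
                    r = float(np.linalg.norm(a.xyz - lig_pos[ai]))
                    if r > distance_cutoff:
                        continue
                    best = max(
                        (_angle_deg(a.xyz - h, lig_pos[ai] - h) for h in hs),
                        default=None,
                    )
                    if best is not None and best >= angle_cutoff:
                        records.append(
                            InteractionRecord(
                                "hbond", a.residue, group, str(ai), r, best
                            )
                        )
            if "acceptor" in roles:
                for di in lig_donors:
                    r = float(np.linalg.norm(a.xyz - lig_pos[di]))
                    if r > distance_cutoff:
                        continue
                    datom = lig.GetAtomWithIdx(di)
                    angles = [
                        _angle_deg(
                            lig_pos[di] - lig_pos[nb.GetIdx()],
                            a.xyz - lig_pos[nb.GetIdx()],
                        )
                        for nb in datom.GetNeighbors()
                        if nb.GetAtomicNum() == 1
                    ]
                    best = max(angles, default=None)
                    if best is not None and best >= angle_cutoff:
                        records.append(
                            InteractionRecord(
                                "hbond", a.residue, group, str(di), r, best
                            )
                        )
    return records


def _plane_normal(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    return vt[2]


def _ligand_aromatic_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    info = mol.GetRingInfo()
    rings = []
    for ring in info.AtomRings():
        if len(ring) in (5, 6) and all(
            mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring
        ):
            rings.append(tuple(ring))
    return rings


def detect_pi_stacking(
    pose: ComplexPose,
    centroid_cutoff: float = PI_CENTROID_CUTOFF,
    parallel_max_angle: float = PI_PARALLEL_MAX_ANGLE,
    tshaped_min_angle: float = PI_TSHAPED_MIN_ANGLE,
) -> list[InteractionRecord]:
    """Aromatic ring pairs within the centroid cutoff, classified by angle."""
    lig_pos = pose.ligand.GetConformer().GetPositions()
    lig_rings = _ligand_aromatic_rings(pose.ligand)
    by_res = _residue_atoms(pose.receptor)
    records: list[InteractionRecord] = []
    for (res_name, res_seq, _chain), atoms in by_res.items():
        ring_defs = RECEPTOR_RING_ATOMS.get(res_name, [])
        name_map = {a.name: a for a in atoms}
        for ring_names in ring_defs:
            if not all(n in name_map for n in ring_names):
                continue
            rec_pts = np.array([name_map[n].xyz for n in ring_names])
            rec_centroid = rec_pts.mean(axis=0)
            rec_normal = _plane_normal(rec_pts)
            residue = atoms[0].residue
            for ring in lig_rings:
                pts = lig_pos[list(ring)]
                r = float(np.linalg.norm(pts.mean(axis=0) - rec_centroid))
                if r > centroid_cutoff:
                    continue
                ang = _angle_deg(rec_normal, _plane_normal(pts))
                ang = min(ang, 180.0 - ang)
                if ang <= parallel_max_angle:
                    kind = "pi_parallel"
                elif ang >= tshaped_min_angle:
                    kind = "pi_tshaped"
                else:
                    kind = "pi_unclassified"
                records.append(
                    InteractionRecord(kind, residue, "ring", str(ring), r, ang)
                )
    return records


def _requirement_met(req: dict, records: Sequence[InteractionRecord]) -> bool:
    kind = req.get("kind", "hbond")
    for rec in records:
        if kind == "pi":
            if not rec.kind.startswith("pi"):
                continue
        elif rec.kind != kind:
            continue
        if rec.residue != req["residue"]:
            continue
        if "group" in req and rec.group != req["group"]:
            continue
        return True
    return any(
        _requirement_met(alt, records) for alt in req.get("alternates", [])
    )


def _requirement_name(req: dict) -> str:
    base = f"{req['residue']} {req.get('kind', 'hbond')}"
    if "group" in req:
        base += f":{req['group']}"
    return base


def ecidal_filter(
    records: Sequence[InteractionRecord], spec: Sequence[dict]
) -> tuple[bool, list[str], list[str]]:
    """Check a pose's interactions against a required-interaction spec.

    Each spec entry needs a ``residue`` and optional ``kind`` (default
    ``hbond``; ``pi`` matches any stacking geometry), ``group``, and
    ``alternates`` (same shape).  Returns (compliant, missing, satisfied).
    """
    if not spec:
        raise ParameterError("required-interaction spec must not be empty")
    missing, satisfied = [], []
    for req in spec:
        (satisfied if _requirement_met(req, records) else missing).append(
            _requirement_name(req)
        )
    return (not missing, missing, satisfied)


def summarize_interactions(
    analyzed_poses: Sequence[tuple[str, Sequence[InteractionRecord]]],
) -> pd.DataFrame:
    """Aggregate per-pose interactions into a per-set distance table.

    ``analyzed_poses`` pairs each pose's set label with its interaction
    records.  Per (set, residue, group, kind) the pose count N and the mean
    and sample sd (n-1 denominator; 0 when N = 1) of the distance are
    reported, keeping only the shortest distance per pose per key.
    """
    rows: dict[tuple[str, str, str, str], list[float]] = {}
    for set_label, records in analyzed_poses:
        best: dict[tuple[str, str, str], float] = {}
        for rec in records:
            k = rec.key
            if k not in best or rec.r < best[k]:
                best[k] = rec.r
        for (residue, group, kind), r in best.items():
            rows.setdefault((set_label, residue, group, kind), []).append(r)

    out = []
    for (set_label, residue, group, kind), dists in sorted(rows.items()):
        arr = np.asarray(dists)
        out.append(
            {
                "set": set_label,
                "residue": residue,
                "group": group,
                "kind": kind,
                "N": len(arr),
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            }
        )
    return pd.DataFrame(
        out, columns=["set", "residue", "group", "kind", "N", "mean", "sd"]
    )


def read_receptor_pdb(path: str | Path) -> list[ReceptorAtom]:
    """Read receptor atoms from a PDB file."""
    import gemmi

    st = gemmi.read_structure(str(path))
    atoms: list[ReceptorAtom] = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    atoms.append(
                        ReceptorAtom(
                            name=atom.name,
                            res_name=res.name,
                            res_seq=res.seqid.num,
                            chain=chain.name,
                            element=atom.element.name,
                            xyz=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            ),
                        )
                    )
        break  # first model only
    if not atoms:
        raise FormatError(f"no atoms read from {path}")
    return atoms


def write_receptor_pdb(atoms: Sequence[ReceptorAtom], path: str | Path) -> None:
    """Write receptor atoms as a single-model PDB file."""
    import gemmi

    # group atoms first: gemmi add_* copies objects, so build bottom-up
    by_chain: dict[str, dict[tuple[str, int], list[ReceptorAtom]]] = {}
    for a in atoms:
        by_chain.setdefault(a.chain, {}).setdefault(
            (a.res_name, a.res_seq), []
        ).append(a)

    st = gemmi.Structure()
    st.name = "pseudo-receptor"
    model = gemmi.Model("1")
    for chain_name, residues in by_chain.items():
        chain = gemmi.Chain(chain_name)
        for (res_name, res_seq), res_atoms in residues.items():
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(str(res_seq))
            for a in res_atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.xyz)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
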