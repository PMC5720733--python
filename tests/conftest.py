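import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from rdkit import Chem
from rdkit.Geometry import Point3D

from fieldqsar.dataset import LigandRecord, LigandTable
from fieldqsar.synthetic import SeriesConfig, generate_congeneric_series

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def single_atom_record(cid: str, element: str = "C", xyz=(0.0, 0.0, 0.0),
                       ic50: float = 1.0, charge: float = 0.0) -> LigandRecord:
    """A one-atom molecule with a conformer, for plumbing tests."""
    rw = Chem.RWMol()
    a = Chem.Atom(element)
    a.SetNoImplicit(True)
    rw.AddAtom(a)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(1)
    conf.SetAtomPosition(0, Point3D(*xyz))
    mol.AddConformer(conf)
    mol.GetAtomWithIdx(0).SetDoubleProp("partial_charge", charge)
    return LigandRecord(id=cid, set_label="t", mol=mol, ic50=ic50)


def dummy_table(n: int, seed: int = 0) -> LigandTable:
    """n one-atom records with distinct activities, for split tests."""
    rng = np.random.default_rng(seed)
    ic50s = 10.0 ** rng.uniform(-3, 2, n)
    return LigandTable(
        [
            single_atom_record(f"cmp-{k:03d}", ic50=float(ic50s[k]))
            for k in range(n)
        ]
    )


@pytest.fixture(scope="session")
def small_series():
    """A small noiseless synthetic series shared across tests."""
    return generate_congeneric_series(SeriesConfig(n=15, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def default_series():
    """The default-condition synthetic series (n=60, sigma=0.3)."""
    return generate_congeneric_series(SeriesConfig(seed=11))
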