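import numpy as np
import pytest

from molsnap import chemio, synthgen
from molsnap.chemio import Molecule3D, MoleculeRecord


@pytest.fixture(scope="session")
def ten_records() -> list[MoleculeRecord]:
    """Ten small synthetic molecules with rule-driven activities."""
    smis = synthgen.generate_library(10, seed=11)
    return synthgen.assign_activity(smis, synthgen.RuleParams(seed=11))


@pytest.fixture(scope="session")
def benzene3d() -> Molecule3D:
    return chemio.embed_3d(MoleculeRecord("benzene", "c1ccccc1", 1.0), seed=3)


@pytest.fixture(scope="session")
def methane3d() -> Molecule3D:
    return chemio.embed_3d(MoleculeRecord("methane", "C", 1.0), seed=0)


@pytest.fixture(scope="session")
def hcl3d() -> Molecule3D:
    """A two-atom molecule: convenient for projection geometry checks."""
    return Molecule3D(
        "hcl",
        ["H", "Cl"],
        np.array([[0.0, 0.0, 0.0], [1.27, 0.0, 0.0]]),
        [(0, 1, 1.0)],
    )
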