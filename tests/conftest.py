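import numpy as np
import pytest

from dnabind.dna import DnaElement
from dnabind.fixtures import (FixtureSpec, ProbeSpec, _Builder, build_fixture,
                              build_ideal_bdna, build_peptide)


@pytest.fixture(scope="session")
def ideal_12mer():
    return build_ideal_bdna("ATGCATGCATGC")


@pytest.fixture(scope="session")
def helix_mj_fixture():
    """Helix probe hydrogen-bonded to the major groove, with its truth."""
    spec = FixtureSpec("ATGCATGCATGC",
                       [ProbeSpec("helix", DnaElement.MAJOR, "hbond")],
                       seed=3)
    return build_fixture(spec, entry_id="hmj")


@pytest.fixture(scope="session")
def loop_phobic_fixture():
    """Loop probe in hydrophobic contact with the thymine methyl."""
    spec = FixtureSpec("ATGCATGCATGC",
                       [ProbeSpec("loop", DnaElement.MAJOR, "hydrophobic")],
                       seed=5)
    return build_fixture(spec, entry_id="lphob")


def peptide_structure(res_list, chain="A", base=1, entry="pep"):
    """Freeze a build_peptide result into a Structure."""
    b = _Builder(entry)
    for i, r in enumerate(res_list):
        for name, pos in r.items():
            if name.startswith("_"):
                continue
            b.add(chain, base + i, r.get("_name", "ALA"), name, pos)
    return b.freeze()


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
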