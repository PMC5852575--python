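import numpy as np
import pytest

from rnaocclusion import Atom, Structure


def make_peptide(n_residues: int = 3, chain: str = "A",
                 first_res: int = 1) -> Structure:
    """A tiny backbone-only peptide (N, CA, C per residue) along x."""
    atoms = []
    serial = 1
    for r in range(n_residues):
        base = np.array([3.8 * r, 0.0, 0.0])
        for name, offset in (("N", [0.0, 0.0, 0.0]),
                             ("CA", [1.2, 0.8, 0.0]),
                             ("C", [2.4, 0.0, 0.3])):
            atoms.append(Atom(
                serial=serial, name=name, element=name[0], res_name="ALA",
                res_id=first_res + r, chain=chain,
                coords=base + np.array(offset)))
            serial += 1
    return Structure(atoms, label="peptide")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR with sign fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def peptide():
    return make_peptide()
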