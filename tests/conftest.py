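import numpy as np
import pytest

from metacv import AtomRecord, Structure, ToyOligomerSpec, gen_toy_oligomer


def make_random_soup(seed: int, n_residues: int = 40, box: float = 22.0) -> Structure:
    """Random 'soup' of charged/polar residues for detection-oracle tests.

    Each residue carries only the atoms relevant to contact detection (acidic
    oxygens, basic nitrogens, donors with their hydrogens, acceptors) at
    uniformly random positions; hydrogens sit within 1 A of their donor.
    About 200 atoms at the default size.
    """
    rng = np.random.default_rng(seed)
    templates = {
        "GLU": [("OE1", "O"), ("OE2", "O"), ("CD", "C")],
        "LYS": [("NZ", "N"), ("HZ1", "H"), ("CE", "C")],
        "ARG": [("NE", "N"), ("HE", "H"), ("NH1", "N"), ("HH11", "H"), ("CZ", "C")],
        "SER": [("OG", "O"), ("HG", "H"), ("CB", "C")],
        "GLY": [("N", "N"), ("H", "H"), ("O", "O"), ("CA", "C")],
    }
    names = list(templates)
    atoms = []
    serial = 1
    for r in range(n_residues):
        res_name = names[int(rng.integers(len(names)))]
        chain = "ABC"[int(rng.integers(3))]
        base = rng.uniform(0, box, size=3)
        anchor = {}
        for name, element in templates[res_name]:
            if element == "H":
                donor = {"HZ1": "NZ", "HE": "NE", "HH11": "NH1", "HG": "OG", "H": "N"}[name]
                pos = anchor[donor] + rng.normal(0, 0.4, size=3)
                pos = anchor[donor] + (pos - anchor[donor]) / np.linalg.norm(pos - anchor[donor])
            else:
                pos = base + rng.uniform(-1.5, 1.5, size=3)
                anchor[name] = pos
            atoms.append(AtomRecord(serial, name, element, res_name, r + 1, chain,
                                    tuple(float(x) for x in pos)))
            serial += 1
    return Structure(atoms)


@pytest.fixture
def hexamer60() -> Structure:
    return gen_toy_oligomer(ToyOligomerSpec(twist=60.0))


@pytest.fixture
def hexamer40() -> Structure:
    return gen_toy_oligomer(ToyOligomerSpec(twist=40.0))
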