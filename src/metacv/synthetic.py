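"""Synthetic fixtures: every pipeline stage is testable without external data.

Provides (i) two-state Gaussian descriptor populations with a known optimal
discriminant, standing in for the contact-distance distributions of two
metastable conformers; (ii) toy helical oligomers with plantable salt bridges
or hydrogen bonds and a controllable per-interface twist; (iii) interpolated
transition trajectories between two conformers; and (iv) quadrature reference
free-energy differences for 1D double wells.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .constants import KB
from .hlda import harmonic_scatter
from .potentials import DoubleWell
from .structures import AtomRecord, Structure, Trajectory


class SyntheticError(ValueError):
    pass


@dataclass
class TwoStateSpec:
    """Two multivariate-Gaussian descriptor populations (A and B)."""

    mu_a: np.ndarray
    mu_b: np.ndarray
    sigma_a: np.ndarray
    sigma_b: np.ndarray
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        self.mu_b = np.asarray(self.mu_b, dtype=float)
        self.sigma_a = np.atleast_2d(np.asarray(self.sigma_a, dtype=float))
        self.sigma_b = np.atleast_2d(np.asarray(self.sigma_b, dtype=float))
        if self.n < 2:
            raise SyntheticError("need n >= 2 samples per state")
        for s in (self.sigma_a, self.sigma_b):
            if not np.allclose(s, s.T) or np.linalg.eigvalsh(s).min() < -1e-12:
                raise SyntheticError("covariances must be symmetric PSD")

    @property
    def dimension(self) -> int:
        return self.mu_a.shape[0]


def gen_two_state_descriptors(spec: TwoStateSpec
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draws for both states plus the ground-truth discriminant direction w*.

    w* = normalize(S_w^-1 (mu_A - mu_B)) with S_w the harmonic covariance mean
    of the *population* covariances — the direction an exact HLDA would find.
    """
    rng = np.random.default_rng(spec.seed)
    x_a = rng.multivariate_normal(spec.mu_a, spec.sigma_a, size=spec.n)
    x_b = rng.multivariate_normal(spec.mu_b, spec.sigma_b, size=spec.n)
    s_w = harmonic_scatter(spec.sigma_a, spec.sigma_b)
    w = np.linalg.solve(s_w, spec.mu_a - spec.mu_b)
    w_star = w / np.linalg.norm(w)
    return x_a, x_b, w_star


# --- toy oligomers ----------------------------------------------------------

#: (atom name, element, res_name, res_seq, local position) — one small protomer
#: with a backbone donor/acceptor, an acidic (GLU), a basic (LYS) and a
#: hydroxyl (SER) residue, hydrogens included for every donor.
_TEMPLATE: list[tuple[str, str, str, int, tuple[float, float, float]]] = [
    # res 1: GLY backbone
    ("N", "N", "GLY", 1, (0.0, 0.0, 0.0)),
    ("H", "H", "GLY", 1, (-0.9, -0.4, 0.0)),
    ("CA", "C", "GLY", 1, (1.4, 0.4, 0.0)),
    ("C", "C", "GLY", 1, (2.4, -0.6, 0.5)),
    ("O", "O", "GLY", 1, (2.2, -1.8, 0.4)),
    # res 2: GLU
    ("N", "N", "GLU", 2, (3.6, -0.1, 1.0)),
    ("H", "H", "GLU", 2, (3.7, 0.9, 1.1)),
    ("CA", "C", "GLU", 2, (4.8, -0.9, 1.4)),
    ("C", "C", "GLU", 2, (6.0, -0.1, 1.9)),
    ("O", "O", "GLU", 2, (6.0, 1.1, 1.9)),
    ("CB", "C", "GLU", 2, (5.2, -1.8, 0.3)),
    ("CG", "C", "GLU", 2, (6.3, -2.8, 0.6)),
    ("CD", "C", "GLU", 2, (6.7, -3.6, -0.6)),
    ("OE1", "O", "GLU", 2, (6.1, -3.5, -1.7)),
    ("OE2", "O", "GLU", 2, (7.7, -4.4, -0.5)),
    # res 3: LYS
    ("N", "N", "LYS", 3, (7.1, -0.8, 2.3)),
    ("H", "H", "LYS", 3, (7.1, -1.8, 2.3)),
    ("CA", "C", "LYS", 3, (8.4, -0.2, 2.7)),
    ("C", "C", "LYS", 3, (9.5, -1.2, 3.1)),
    ("O", "O", "LYS", 3, (9.3, -2.4, 3.1)),
    ("CB", "C", "LYS", 3, (8.9, 0.7, 1.6)),
    ("CE", "C", "LYS", 3, (10.1, 1.6, 2.0)),
    ("NZ", "N", "LYS", 3, (10.6, 2.5, 0.9)),
    ("HZ1", "H", "LYS", 3, (11.4, 3.1, 1.2)),
    # res 4: SER
    ("N", "N", "SER", 4, (10.7, -0.7, 3.5)),
    ("H", "H", "SER", 4, (10.9, 0.3, 3.5)),
    ("CA", "C", "SER", 4, (11.9, -1.5, 3.9)),
    ("C", "C", "SER", 4, (13.1, -0.7, 4.3)),
    ("O", "O", "SER", 4, (13.1, 0.5, 4.3)),
    ("CB", "C", "SER", 4, (12.3, -2.4, 2.8)),
    ("OG", "O", "SER", 4, (13.3, -3.3, 3.2)),
    ("HG", "H", "SER", 4, (13.6, -3.9, 2.5)),
]

#: atoms used to realize a planted contact, per kind: (side-A atom, side-B atoms moved with it)
_PLANT_ATOMS = {
    "salt_bridge": (("GLU", 2, "OE1", ()), ("LYS", 3, "NZ", ())),
    "hbond": (("SER", 4, "OG", ("HG",)), ("GLY", 1, "O", ())),
}


@dataclass
class PlantedContact:
    kind: str  # salt_bridge | hbond
    protomer_a: str
    protomer_b: str
    target_distance: float

    def __post_init__(self) -> None:
        if self.kind not in _PLANT_ATOMS:
            raise SyntheticError(f"unknown planted contact kind {self.kind!r}")
        if self.target_distance <= 0:
            raise SyntheticError("planted distance must be positive")


@dataclass
class ToyOligomerSpec:
    """Helical oligomer: template protomer repeated with per-interface twist and rise."""

    n_protomers: int = 6
    twist: float = 60.0   # degrees about z per interface
    rise: float = 8.0     # A along z per interface
    radius: float = 12.0  # A, offset of the template from the helix axis
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    jitter: float = 0.0   # A, isotropic Gaussian noise on template atoms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_protomers < 2:
            raise SyntheticError("need at least 2 protomers")


def _rot_z(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def gen_toy_oligomer(spec: ToyOligomerSpec) -> Structure:
    """Build the oligomer, then adjust planted contact atoms to their target distances.

    Protomer i is the template rotated by ``i * twist`` about z and translated
    by ``i * rise`` along z; chains are labeled A, B, ...  Each planted contact
    moves the side-A atom (plus its riders, e.g. a donor hydrogen) along the
    existing interatomic direction so the target distance is met exactly; an
    atom claimed by two constraints is a conflict and raises.
    """
    rng = np.random.default_rng(spec.seed)
    chains = [chr(ord("A") + i) for i in range(spec.n_protomers)]
    atoms: list[AtomRecord] = []
    serial = 1
    for i, chain in enumerate(chains):
        rot = _rot_z(i * spec.twist)
        shift = np.array([0.0, 0.0, i * spec.rise])
        for name, element, res_name, res_seq, pos in _TEMPLATE:
            p = rot @ (np.asarray(pos) + np.array([spec.radius, 0.0, 0.0])) + shift
            if spec.jitter > 0:
                p = p + rng.normal(0.0, spec.jitter, size=3)
            atoms.append(AtomRecord(serial, name, element, res_name, res_seq, chain,
                                    tuple(float(x) for x in p)))
            serial += 1
    struct = Structure(atoms)
    coords = struct.coords()
    moved: dict[int, str] = {}

    def idx(chain: str, res_seq: int, name: str) -> int:
        return struct.index_of(chain, res_seq, name)

    for pc in spec.planted_contacts:
        (res_a, seq_a, name_a, riders), (res_b, seq_b, name_b, _) = _PLANT_ATOMS[pc.kind]
        ia = idx(pc.protomer_a, seq_a, name_a)
        ib = idx(pc.protomer_b, seq_b, name_b)
        for moving in (ia, *[idx(pc.protomer_a, seq_a, r) for r in riders]):
            if moving in moved:
                raise SyntheticError(
                    f"planted contact conflict: atom index {moving} already moved for "
                    f"{moved[moving]!r}, requested again for {pc.kind} "
                    f"{pc.protomer_a}-{pc.protomer_b}"
                )
            moved[moving] = f"{pc.kind} {pc.protomer_a}-{pc.protomer_b}"
        u = coords[ia] - coords[ib]
        u = u / np.linalg.norm(u)
        new_a = coords[ib] + pc.target_distance * u
        if pc.kind == "hbond":
            # keep the donor hydrogen collinear, 1.0 A from the donor toward the acceptor
            ih = idx(pc.protomer_a, seq_a, riders[0])
            coords[ih] = coords[ib] + (pc.target_distance - 1.0) * u
        coords[ia] = new_a
    return struct.with_coords(coords)


def gen_transition_trajectory(struct_a: Structure, struct_b: Structure,
                              n_frames: int, noise_sigma: float = 0.0,
                              seed: int = 0, frame_stride: float = 1.0) -> Trajectory:
    """Linear coordinate interpolation from A to B plus isotropic Gaussian jitter."""
    if [a.key for a in struct_a.atoms] != [b.key for b in struct_b.atoms]:
        raise SyntheticError("structures must have identical atom sets, in order")
    if n_frames < 1:
        raise SyntheticError("need at least one frame")
    rng = np.random.default_rng(seed)
    ca, cb = struct_a.coords(), struct_b.coords()
    lam = np.linspace(0.0, 1.0, n_frames) if n_frames > 1 else np.array([0.0])
    frames = (1 - lam)[:, None, None] * ca[None] + lam[:, None, None] * cb[None]
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)
    return Trajectory(frames, struct_a, frame_stride=frame_stride)


def double_well_reference(pot: DoubleWell, temperature: float = 300.0) -> float:
    """Quadrature reference Delta F = F(right well) - F(left well), kJ/mol.

    The dividing point is the interior maximum of U between the wells; each
    basin partition function is an adaptive quadrature of exp(-U/kBT).
    """
    left, right = pot.well_positions()
    res = minimize_scalar(lambda x: -pot.energy(x), bounds=(left, right), method="bounded")
    split = float(res.x)
    if not (left < split < right) or pot.energy(split) <= max(pot.energy(left), pot.energy(right)):
        raise SyntheticError("no interior barrier maximum found between the wells")
    beta = 1.0 / (KB * temperature)
    z_left, _ = quad(lambda x: np.exp(-beta * pot.energy(x)), -np.inf, split)
    z_right, _ = quad(lambda x: np.exp(-beta * pot.energy(x)), split, np.inf)
    return float(-np.log(z_right / z_left) / beta)
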