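"""Salt-bridge and hydrogen-bond detection, protomer-scope filtering,
occupancies, and descriptor time series.

Geometric criteria
------------------
* Salt bridge: any side-chain oxygen of an acidic group (Asp OD1/OD2,
  Glu OE1/OE2, C-terminal OXT) within ``cutoff`` (default 6 A) of any
  side-chain nitrogen of a basic group (Lys NZ, Arg NE/NH1/NH2,
  His ND1/NE2).  One contact is reported per (acidic residue, basic
  residue) pair; the canonical atom pair is the closest O-N pair.
* Hydrogen bond: donor-acceptor heavy-atom distance <= ``d_cut``
  (default 3.0 A) and deviation from linearity of D-H...A, i.e.
  180 deg minus the angle at the hydrogen, <= ``ang_cut`` (default 30 deg).

Pairs within the same residue are never reported.  Hydrogen positions must
be present in the input; they are never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial import cKDTree

from .structures import Structure, Trajectory

AtomId = tuple[str, int, str]  # (chain_id, res_seq, atom_name)


class ContactError(ValueError):
    """Raised for missing annotations or unusable contact input."""


#: Acidic side-chain oxygens per residue name ("*" applies to every residue).
ACIDIC_OXYGENS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "*": frozenset({"OXT"}),
}

#: Basic side-chain nitrogens per residue name.
BASIC_NITROGENS: dict[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

#: Hydrogen-bond donors: (res_name, heavy-atom name) -> names of bonded hydrogens.
HBOND_DONORS: dict[tuple[str, str], tuple[str, ...]] = {
    ("*", "N"): ("H", "HN", "H1", "H2", "H3"),
    ("SER", "OG"): ("HG",),
    ("THR", "OG1"): ("HG1",),
    ("TYR", "OH"): ("HH",),
    ("CYS", "SG"): ("HG",),
    ("LYS", "NZ"): ("HZ1", "HZ2", "HZ3"),
    ("ARG", "NE"): ("HE",),
    ("ARG", "NH1"): ("HH11", "HH12"),
    ("ARG", "NH2"): ("HH21", "HH22"),
    ("ASN", "ND2"): ("HD21", "HD22"),
    ("GLN", "NE2"): ("HE21", "HE22"),
    ("HIS", "ND1"): ("HD1",),
    ("HIS", "NE2"): ("HE2",),
    ("TRP", "NE1"): ("HE1",),
}

#: Hydrogen-bond acceptors: res_name -> heavy-atom names ("*" = every residue).
HBOND_ACCEPTORS: dict[str, frozenset[str]] = {
    "*": frozenset({"O", "OXT"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "HIS": frozenset({"ND1", "NE2"}),
}


def _atom_str(a: AtomId) -> str:
    return f"{a[0]}/{a[1]}/{a[2]}"


def _parse_atom_str(s: str) -> AtomId:
    chain, res, name = s.split("/")
    return (chain, int(res), name)


@dataclass(frozen=True)
class ContactDescriptor:
    """One candidate salt bridge or hydrogen bond (an atom-pair distance descriptor).

    For hydrogen bonds ``atom_a`` is the donor heavy atom and ``atom_b`` the
    acceptor; the label is canonicalized (sorted atom ids) so that the same
    physical pair always maps to the same label.
    """

    kind: str  # "salt_bridge" | "hbond"
    atom_a: AtomId
    atom_b: AtomId
    protomer_a: str
    protomer_b: str

    @property
    def label(self) -> str:
        first, second = sorted((_atom_str(self.atom_a), _atom_str(self.atom_b)))
        return f"{self.kind}:{first}-{second}"

    def touches_residues(self, residues: Iterable[tuple[str, int]]) -> bool:
        rset = set(residues)
        return (self.atom_a[0], self.atom_a[1]) in rset or (self.atom_b[0], self.atom_b[1]) in rset


@dataclass
class ContactSet:
    """Ordered, de-duplicated contact collection (sorted by canonical label)."""

    contacts: list[ContactDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_label: dict[str, ContactDescriptor] = {}
        for c in self.contacts:
            by_label.setdefault(c.label, c)
        self.contacts = [by_label[lab] for lab in sorted(by_label)]

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self) -> Iterator[ContactDescriptor]:
        return iter(self.contacts)

    def __getitem__(self, i: int) -> ContactDescriptor:
        return self.contacts[i]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.contacts]

    def union(self, other: "ContactSet") -> "ContactSet":
        return ContactSet(self.contacts + other.contacts)


@dataclass
class OccupancyTable:
    """Fraction of frames satisfying the contact criterion, per contact label."""

    contacts: ContactSet
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        labels = set(self.contacts.labels)
        for lab, f in self.fractions.items():
            if lab not in labels:
                raise ContactError(f"occupancy key {lab!r} not in contact set")
            if not (0.0 <= f <= 1.0):
                raise ContactError(f"occupancy {f} for {lab!r} outside [0, 1]")

    def __getitem__(self, label: str) -> float:
        return self.fractions[label]


def _lookup(table: dict, res_name: str, atom_name: str) -> bool:
    return atom_name in table.get(res_name, frozenset()) | table.get("*", frozenset())


def _protomer(topology: Structure, chain: str) -> str:
    return topology.protomer_map[chain]


def detect_salt_bridges(frame: np.ndarray, topology: Structure,
                        cutoff: float = 6.0) -> ContactSet:
    """Residue-level salt bridges in one frame; canonical atoms = closest O-N pair."""
    frame = np.asarray(frame, dtype=float)
    o_idx = [i for i, a in enumerate(topology.atoms)
             if _lookup(ACIDIC_OXYGENS, a.res_name, a.name)]
    n_idx = [i for i, a in enumerate(topology.atoms)
             if _lookup(BASIC_NITROGENS, a.res_name, a.name)]
    if not o_idx or not n_idx:
        return ContactSet([])
    tree = cKDTree(frame[n_idx])
    best: dict[tuple, tuple[float, int, int]] = {}
    for oi, neighbors in zip(o_idx, tree.query_ball_point(frame[o_idx], cutoff)):
        ao = topology.atoms[oi]
        for j in neighbors:
            ni = n_idx[j]
            an = topology.atoms[ni]
            if (ao.chain_id, ao.res_seq) == (an.chain_id, an.res_seq):
                continue
            d = float(np.linalg.norm(frame[oi] - frame[ni]))
            key = (ao.chain_id, ao.res_seq, an.chain_id, an.res_seq)
            if key not in best or d < best[key][0]:
                best[key] = (d, oi, ni)
    contacts = []
    for (d, oi, ni) in best.values():
        ao, an = topology.atoms[oi], topology.atoms[ni]
        contacts.append(ContactDescriptor(
            "salt_bridge",
            (ao.chain_id, ao.res_seq, ao.name),
            (an.chain_id, an.res_seq, an.name),
            _protomer(topology, ao.chain_id),
            _protomer(topology, an.chain_id),
        ))
    return ContactSet(contacts)


def _donor_hydrogens(topology: Structure) -> dict[int, list[int]]:
    """Map donor heavy-atom index -> indices of its bonded hydrogens (by name)."""
    by_residue: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(topology.atoms):
        by_residue.setdefault((a.chain_id, a.res_seq), {})[a.name] = i
    donors: dict[int, list[int]] = {}
    for i, a in enumerate(topology.atoms):
        h_names = HBOND_DONORS.get((a.res_name, a.name)) or HBOND_DONORS.get(("*", a.name))
        if h_names is None:
            continue
        res_atoms = by_residue[(a.chain_id, a.res_seq)]
        hs = [res_atoms[h] for h in h_names if h in res_atoms]
        if not hs:
            raise ContactError(
                f"donor {a.chain_id}/{a.res_seq}/{a.name} has no hydrogen coordinates "
                f"(expected one of {h_names}); hydrogens are required, not inferred"
            )
        donors[i] = hs
    return donors


def detect_hbonds(frame: np.ndarray, topology: Structure,
                  d_cut: float = 3.0, ang_cut: float = 30.0) -> ContactSet:
    """Hydrogen bonds in one frame (distance + deviation-from-linearity criterion)."""
    frame = np.asarray(frame, dtype=float)
    donors = _donor_hydrogens(topology)
    acc_idx = [i for i, a in enumerate(topology.atoms)
               if _lookup(HBOND_ACCEPTORS, a.res_name, a.name)]
    if not donors or not acc_idx:
        return ContactSet([])
    tree = cKDTree(frame[acc_idx])
    don_list = list(donors)
    contacts = []
    for di, neighbors in zip(don_list, tree.query_ball_point(frame[don_list], d_cut)):
        ad = topology.atoms[di]
        for j in neighbors:
            ai = acc_idx[j]
            aa = topology.atoms[ai]
            if (ad.chain_id, ad.res_seq) == (aa.chain_id, aa.res_seq):
                continue
            if _hbond_angle_ok(frame, di, donors[di], ai, ang_cut):
                contacts.append(ContactDescriptor(
                    "hbond",
                    (ad.chain_id, ad.res_seq, ad.name),
                    (aa.chain_id, aa.res_seq, aa.name),
                    _protomer(topology, ad.chain_id),
                    _protomer(topology, aa.chain_id),
                ))
    return ContactSet(contacts)


def _hbond_angle_ok(frame: np.ndarray, donor: int, hydrogens: list[int],
                    acceptor: int, ang_cut: float) -> bool:
    for hi in hydrogens:
        v1 = frame[donor] - frame[hi]
        v2 = frame[acceptor] - frame[hi]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if 180.0 - angle <= ang_cut:
            return True
    return False


def filter_protomer_scope(contacts: ContactSet, protomer_map: dict[str, str],
                          terminal: set[str]) -> ContactSet:
    """Keep interprotomer contacts, plus intraprotomer ones within terminal protomers."""
    kept = []
    for c in contacts:
        pa, pb = c.protomer_a, c.protomer_b
        if pa not in protomer_map.values() or pb not in protomer_map.values():
            raise ContactError(f"contact protomers ({pa}, {pb}) not in protomer map")
        if pa != pb or pa in terminal:
            kept.append(c)
    return ContactSet(kept)


def _contact_satisfied(frame: np.ndarray, topology: Structure, c: ContactDescriptor,
                       donors: dict[int, list[int]] | None,
                       salt_cutoff: float, hb_dist: float, hb_angle: float) -> bool:
    ia = topology.index_of(*c.atom_a)
    ib = topology.index_of(*c.atom_b)
    d = float(np.linalg.norm(frame[ia] - frame[ib]))
    if c.kind == "salt_bridge":
        return d <= salt_cutoff
    if d > hb_dist:
        return False
    assert donors is not None
    if ia not in donors:
        raise ContactError(f"contact {c.label}: donor atom has no annotated hydrogens")
    return _hbond_angle_ok(frame, ia, donors[ia], ib, hb_angle)


def occupancy(traj: Trajectory, contacts: ContactSet,
              salt_cutoff: float = 6.0, hb_dist: float = 3.0,
              hb_angle: float = 30.0) -> OccupancyTable:
    """Per-contact fraction of frames satisfying the geometric criterion.

    Salt-bridge occupancy tracks the canonical atom pair's distance (the same
    quantity :func:`descriptor_series` reports), so the two views agree.
    """
    donors = _donor_hydrogens(traj.topology) if any(c.kind == "hbond" for c in contacts) else None
    fractions = {}
    for c in contacts:
        hits = sum(
            _contact_satisfied(f, traj.topology, c, donors, salt_cutoff, hb_dist, hb_angle)
            for f in traj.frames
        )
        fractions[c.label] = hits / traj.n_frames
    return OccupancyTable(contacts, fractions)


def state_descriptor_pool(occ_state1: OccupancyTable, occ_state2: OccupancyTable,
                          min_occ: float = 0.5, exclusive: bool = False) -> ContactSet:
    """Union of contacts occupied (>= ``min_occ``) in at least one state.

    With ``exclusive=True`` a contact must additionally fall below ``min_occ``
    in the other state, keeping only state-distinguishing contacts.
    """
    by_label: dict[str, ContactDescriptor] = {}
    for c in occ_state1.contacts.union(occ_state2.contacts):
        by_label[c.label] = c
    kept = []
    for lab, c in by_label.items():
        f1 = occ_state1.fractions.get(lab, 0.0)
        f2 = occ_state2.fractions.get(lab, 0.0)
        qualifies = f1 >= min_occ or f2 >= min_occ
        if exclusive:
            qualifies = (f1 >= min_occ) != (f2 >= min_occ)
        if qualifies:
            kept.append(c)
    return ContactSet(kept)


def descriptor_series(traj: Trajectory, pool: ContactSet) -> np.ndarray:
    """(n_frames, n_descriptors) matrix of canonical atom-pair distances, A."""
    if len(pool) == 0:
        return np.zeros((traj.n_frames, 0))
    ia = np.array([traj.topology.index_of(*c.atom_a) for c in pool])
    ib = np.array([traj.topology.index_of(*c.atom_b) for c in pool])
    diff = traj.frames[:, ia, :] - traj.frames[:, ib, :]
    return np.linalg.norm(diff, axis=2)


def write_contacts(path, contacts: ContactSet, occ: OccupancyTable | None = None) -> None:
    """Serialize a contact set (optionally with occupancies) to tab-delimited text."""
    lines = ["label\tkind\tatom_a\tatom_b\tprotomer_a\tprotomer_b\toccupancy"]
    for c in contacts:
        f = occ.fractions.get(c.label, float("nan")) if occ is not None else float("nan")
        lines.append("\t".join([
            c.label, c.kind, _atom_str(c.atom_a), _atom_str(c.atom_b),
            c.protomer_a, c.protomer_b, f"{f:.6f}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_contacts(path) -> tuple[ContactSet, dict[str, float]]:
    """Read a contact table written by :func:`write_contacts`."""
    lines = Path(path).read_text().splitlines()
    contacts, fractions = [], {}
    for line in lines[1:]:
        if not line.strip():
            continue
        label, kind, sa, sb, pa, pb, occ_s = line.split("\t")
        c = ContactDescriptor(kind, _parse_atom_str(sa), _parse_atom_str(sb), pa, pb)
        contacts.append(c)
        f = float(occ_s)
        if f == f:  # skip NaN
            fractions[c.label] = f
    return ContactSet(contacts), fractions
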