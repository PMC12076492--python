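"""Harmonic linear discriminant analysis (HLDA) collective variables.

Given descriptor samples from two metastable states A and B (here: contact
distances), the within-class scatter is the harmonic average of the per-state
covariances,

    S_w = (Sigma_A^-1 + Sigma_B^-1)^-1 ,

which upweights the state with the smaller variance, and the discriminant
direction is

    w  ∝  S_w^-1 (mu_A - mu_B) ,

normalized to unit length.  The CV is the projection s(R) = w . d(R), where
d(R) are the descriptor distances.  Any constant prefactor on S_w leaves the
direction unchanged and is omitted.  The sign is fixed so state A (the first
argument) maps to the larger CV value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .contacts import ContactDescriptor, ContactSet, descriptor_series, _atom_str, _parse_atom_str
from .structures import Selection, Structure, center_of_mass


class HLDAError(ValueError):
    pass


@dataclass
class StateStatistics:
    """Sample mean (A) and ridge-regularized covariance (A^2) of one state."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int
    labels: list[str]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        d = self.mu.shape[0]
        if self.sigma.shape != (d, d) or len(self.labels) != d:
            raise HLDAError("dimension mismatch between mu, sigma and labels")
        if not np.allclose(self.sigma, self.sigma.T):
            raise HLDAError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-10:
            raise HLDAError("covariance must be PSD (up to 1e-10)")


@dataclass
class HLDAModel:
    """Harmonic scatter matrix and unit-norm discriminant direction."""

    s_w: np.ndarray
    w: np.ndarray
    labels: list[str]
    regularization: float = 1e-6

    def __post_init__(self) -> None:
        self.s_w = np.asarray(self.s_w, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not np.isclose(np.linalg.norm(self.w), 1.0):
            raise HLDAError("direction w must have unit norm")
        if len(self.labels) != self.w.shape[0]:
            raise HLDAError("labels/direction dimension mismatch")

    @property
    def contributions(self) -> np.ndarray:
        """|w_i| — the magnitude each descriptor contributes to the CV."""
        return np.abs(self.w)


@dataclass
class ComDistanceCV:
    """CV variant 1: distance between the centers of mass of two selections."""

    sel_a: Selection
    sel_b: Selection


@dataclass
class LinearComboCV:
    """CV variant 2: weighted sum of contact distances (the HLDA projection)."""

    contacts: ContactSet
    weights: np.ndarray
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != len(self.contacts):
            raise HLDAError("weights length must equal number of contacts")


CVDefinition = Union[ComDistanceCV, LinearComboCV]


def state_statistics(descriptor_matrix: np.ndarray, labels: Sequence[str],
                     ridge: float = 1e-6) -> StateStatistics:
    """Mean and (n-1)-normalized covariance with ridge ``ridge`` (A^2) on the diagonal."""
    x = np.asarray(descriptor_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise HLDAError("need at least 2 frames to estimate state statistics")
    mu = x.mean(axis=0)
    sigma = np.cov(x, rowvar=False, ddof=1).reshape(x.shape[1], x.shape[1])
    sigma = sigma + ridge * np.eye(x.shape[1])
    return StateStatistics(mu, sigma, n=x.shape[0], labels=list(labels))


def harmonic_scatter(sigma_a: np.ndarray, sigma_b: np.ndarray) -> np.ndarray:
    """Harmonic mean of two covariance matrices: (Sigma_A^-1 + Sigma_B^-1)^-1."""
    sigma_a = np.asarray(sigma_a, dtype=float)
    sigma_b = np.asarray(sigma_b, dtype=float)
    try:
        inv_sum = np.linalg.inv(sigma_a) + np.linalg.inv(sigma_b)
        s_w = np.linalg.inv(inv_sum)
    except np.linalg.LinAlgError as exc:
        raise HLDAError(f"singular covariance despite ridge: {exc}") from exc
    return 0.5 * (s_w + s_w.T)  # enforce exact symmetry


def hlda_direction(stats_a: StateStatistics, stats_b: StateStatistics,
                   s_w: np.ndarray | None = None,
                   regularization: float = 1e-6) -> HLDAModel:
    """Unit-norm discriminant direction, oriented so state A scores higher."""
    if stats_a.labels != stats_b.labels:
        raise HLDAError("state statistics have different descriptor labels")
    if s_w is None:
        s_w = harmonic_scatter(stats_a.sigma, stats_b.sigma)
    dmu = stats_a.mu - stats_b.mu
    if np.allclose(dmu, 0.0):
        raise HLDAError("state means coincide; discriminant direction undefined")
    w = np.linalg.solve(s_w, dmu)
    w = w / np.linalg.norm(w)
    if float(w @ dmu) < 0:
        w = -w
    return HLDAModel(s_w, w, list(stats_a.labels), regularization)


def evaluate_cv(cv: CVDefinition, *, descriptors: np.ndarray | None = None,
                frame: np.ndarray | None = None, topology: Structure | None = None,
                masses: dict | None = None) -> float:
    """Evaluate a CV on a descriptor vector or on a structure frame (A)."""
    if isinstance(cv, LinearComboCV):
        if descriptors is None:
            if frame is None or topology is None:
                raise HLDAError("linear-combo CV needs descriptors or (frame, topology)")
            from .structures import Trajectory

            d = descriptor_series(Trajectory(np.asarray(frame)[None], topology), cv.contacts)[0]
        else:
            d = np.asarray(descriptors, dtype=float)
            if d.shape[0] != cv.weights.shape[0]:
                raise HLDAError("descriptor vector length mismatch")
        return float(cv.weights @ d + cv.offset)
    if isinstance(cv, ComDistanceCV):
        if frame is None or topology is None:
            raise HLDAError("COM-distance CV needs frame and topology")
        ca = center_of_mass(frame, topology, cv.sel_a, masses)
        cb = center_of_mass(frame, topology, cv.sel_b, masses)
        return float(np.linalg.norm(ca - cb))
    raise HLDAError(f"unknown CV definition {type(cv)!r}")


def rank_and_select(model: HLDAModel, pool: ContactSet,
                    residue_filter: set[tuple[str, int]] | None = None,
                    k: int = 32) -> LinearComboCV:
    """Top-``k`` descriptors by |w_i| (after an optional residue filter), renormalized.

    ``residue_filter`` keeps only contacts touching at least one listed
    (chain, res_seq); an empty/None filter keeps everything.  Ties in |w_i|
    break toward the lexicographically smaller label.  If fewer than ``k``
    descriptors survive, all survivors are kept and a warning is issued.
    """
    if k < 1:
        raise HLDAError("k must be >= 1")
    if pool.labels != model.labels:
        raise HLDAError("contact pool does not match model labels")
    candidates = list(range(len(model.labels)))
    if residue_filter:
        candidates = [i for i in candidates if pool[i].touches_residues(residue_filter)]
    if len(candidates) < k:
        warnings.warn(
            f"only {len(candidates)} descriptors survive the residue filter (< k={k}); "
            "keeping all survivors"
        )
    order = sorted(candidates, key=lambda i: (-abs(model.w[i]), model.labels[i]))
    kept = sorted(order[:k], key=lambda i: model.labels[i])
    weights = model.w[kept]
    weights = weights / np.linalg.norm(weights)
    return LinearComboCV(ContactSet([pool[i] for i in kept]), weights)


# --- serialization ----------------------------------------------------------

def write_model(path, model: HLDAModel) -> None:
    """One row per descriptor (label, weight, |contribution|), sorted by contribution."""
    order = np.argsort(-model.contributions, kind="stable")
    lines = ["label\tweight\tcontribution"]
    for i in order:
        lines.append(f"{model.labels[i]}\t{model.w[i]:.10f}\t{model.contributions[i]:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_cv_text(cv: CVDefinition, topology: Structure) -> str:
    """Emit the CV as a PLUMED-dialect input snippet (DISTANCE/COM/COMBINE).

    Atom references use the 1-based positional index in ``topology``.  Each
    distance line is preceded by a ``#!`` comment carrying the contact metadata
    needed for lossless re-import by :func:`parse_cv_text`.  Floats print with
    ``%.6f`` so output is bit-stable for a given CV.
    """
    lines = []
    if isinstance(cv, LinearComboCV):
        for i, c in enumerate(cv.contacts, start=1):
            ia = topology.index_of(*c.atom_a) + 1
            ib = topology.index_of(*c.atom_b) + 1
            lines.append(f"#! contact d{i} {c.kind} {_atom_str(c.atom_a)} "
                         f"{_atom_str(c.atom_b)} {c.protomer_a} {c.protomer_b}")
            lines.append(f"d{i}: DISTANCE ATOMS={ia},{ib}")
        args = ",".join(f"d{i}" for i in range(1, len(cv.contacts) + 1))
        coeffs = ",".join(f"{w:.6f}" for w in cv.weights)
        lines.append(f"cv: COMBINE ARG={args} COEFFICIENTS={coeffs} PERIODIC=NO")
        if cv.offset:
            lines.append(f"#! offset {cv.offset:.6f}")
    elif isinstance(cv, ComDistanceCV):
        for tag, sel in (("ga", cv.sel_a), ("gb", cv.sel_b)):
            serials = ",".join(str(i + 1) for i in sel.resolve(topology))
            lines.append(f"#! selection {tag} chain={sel.chain_id} "
                         f"range={sel.res_range} names={sorted(sel.atom_names) if sel.atom_names else None}")
            lines.append(f"{tag}: COM ATOMS={serials}")
        lines.append("cv: DISTANCE ATOMS=ga,gb")
    else:
        raise HLDAError(f"unknown CV definition {type(cv)!r}")
    return "\n".join(lines) + "\n"


def parse_cv_text(text: str, topology: Structure) -> CVDefinition:
    """Re-import a linear-combination CV exported by :func:`export_cv_text`."""
    contacts: list[ContactDescriptor] = []
    weights: np.ndarray | None = None
    offset = 0.0
    meta: dict[str, ContactDescriptor] = {}
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("#! contact"):
            _, _, tag, kind, sa, sb, pa, pb = line.split()
            meta[tag] = ContactDescriptor(kind, _parse_atom_str(sa), _parse_atom_str(sb), pa, pb)
        elif line.startswith("#! offset"):
            offset = float(line.split()[2])
        elif "COMBINE" in line:
            fields = dict(tok.split("=", 1) for tok in line.split()[2:] if "=" in tok)
            args = fields["ARG"].split(",")
            contacts = [meta[tag] for tag in args]
            weights = np.array([float(x) for x in fields["COEFFICIENTS"].split(",")])
    if weights is None:
        raise HLDAError("no COMBINE line found; only linear-combo CVs can be parsed")
    cs = ContactSet(contacts)
    # ContactSet sorts by label; realign weights accordingly
    order = sorted(range(len(contacts)), key=lambda i: contacts[i].label)
    return LinearComboCV(cs, weights[order], offset)
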