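"""Free-energy landscape post-processing.

Free-energy grids and minima, k-means partitioning of CV space, selection of
a representative (centroid) frame for a basin, basin-stability checks for
follow-up unbiased runs, Kabsch RMSD, and the oligomer twist angle relating
consecutive protomers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import KB
from .structures import Selection, Structure


class LandscapeError(ValueError):
    pass


@dataclass
class FESGrid:
    """Free energy (kJ/mol) on a uniform per-CV grid; minimum shifted to zero."""

    axes: list[np.ndarray]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(len(a) for a in self.axes):
            raise LandscapeError("grid shape does not match axes")
        if not np.all(np.isfinite(self.values)):
            raise LandscapeError("free energy must be finite everywhere")

    @property
    def ndim(self) -> int:
        return len(self.axes)


@dataclass
class ClusterResult:
    """k-means partition of CV-space samples."""

    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int


@dataclass
class BasinRegion:
    """Axis-aligned box in CV space (closed on both ends)."""

    bounds: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not lo < hi:
                raise LandscapeError(f"region bound ({lo}, {hi}) must satisfy lo < hi")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ok = np.ones(pts.shape[0], dtype=bool)
        for j, (lo, hi) in enumerate(self.bounds):
            ok &= (pts[:, j] >= lo) & (pts[:, j] <= hi)
        return ok


def find_minima(grid: FESGrid, depth_cut: float | None = None
                ) -> list[tuple[tuple[int, ...], float]]:
    """Strict local minima (value below every existing neighbor, full stencil).

    Only minima with value <= ``depth_cut`` are kept (all, if None); sorted by
    value ascending.
    """
    vals = grid.values
    if min(vals.shape) < 3:
        raise LandscapeError("grid needs at least 3 points per axis")
    out = []
    offsets = [o for o in product((-1, 0, 1), repeat=vals.ndim) if any(o)]
    for idx in np.ndindex(vals.shape):
        v = vals[idx]
        is_min = True
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= n < s for n, s in zip(nb, vals.shape)):
                if vals[nb] <= v:
                    is_min = False
                    break
        if is_min and (depth_cut is None or v <= depth_cut):
            out.append((idx, float(v)))
    return sorted(out, key=lambda t: t[1])


def kmeans_cluster(points: np.ndarray, k: int, seed: int, n_init: int = 10) -> ClusterResult:
    """k-means (k-means++ starts, best of ``n_init`` by inertia), deterministic in ``seed``."""
    from sklearn.cluster import KMeans

    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < k:
        raise LandscapeError(f"cannot form {k} clusters from {points.shape[0]} points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)
    return ClusterResult(km.labels_.copy(), km.cluster_centers_.copy(),
                         float(km.inertia_), seed)


def select_centroid_frame(points: np.ndarray, result: ClusterResult, cluster_label: int) -> int:
    """Index of the member sample closest to its cluster centroid (ties: smallest index)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    members = np.flatnonzero(result.labels == cluster_label)
    if members.size == 0:
        raise LandscapeError(f"cluster {cluster_label} is empty")
    d = np.linalg.norm(points[members] - result.centroids[cluster_label], axis=1)
    return int(members[np.argmin(d)])


def stability_fraction(cv_series: np.ndarray, region: BasinRegion) -> float:
    """Fraction of samples with every CV inside the (closed) region box."""
    series = np.atleast_2d(np.asarray(cv_series, dtype=float))
    if series.shape[0] == 0:
        raise LandscapeError("empty CV series")
    if series.shape[1] != len(region.bounds):
        series = series.reshape(-1, len(region.bounds))
    return float(region.contains(series).mean())


def is_stable(cv_series: np.ndarray, region: BasinRegion, threshold: float = 1.0) -> bool:
    """Did the run stay in the basin?  Strict by default (every sample inside)."""
    return stability_fraction(cv_series, region) >= threshold


def kabsch_rotation(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Proper rotation R (3x3) minimizing ||(b - <b>) - R (a - <a>)||; SVD Kabsch."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                selection: Selection | None = None,
                topology: Structure | None = None) -> float:
    """Minimum RMSD (A) over rigid superposition (proper rotations only)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if selection is not None:
        if topology is None:
            raise LandscapeError("a Selection needs the topology to resolve")
        idx = selection.resolve(topology)
        a, b = a[idx], b[idx]
    if a.shape != b.shape:
        raise LandscapeError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise LandscapeError("need at least 3 atoms for superposition")
    r = kabsch_rotation(a, b)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    diff = b0 - a0 @ r.T
    return float(np.sqrt((diff**2).sum() / a.shape[0]))


def rotation_angle(r: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, degrees: arccos((tr R - 1)/2)."""
    return float(np.degrees(np.arccos(np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0))))


def twist_angle(structure: Structure, protomer_order: Sequence[str],
                res_range: tuple[int, int] | None = None,
                atom_names: frozenset[str] | None = None,
                cumulative: bool = False) -> float:
    """Twist angle (degrees) relating consecutive protomers of an oligomer.

    For each consecutive pair in ``protomer_order`` the optimal rigid rotation
    mapping protomer i onto protomer i+1 is computed over matched atoms (same
    res_seq and atom name, optionally restricted by ``res_range`` /
    ``atom_names``), and its rotation angle extracted.  Returns the mean over
    interfaces, or the sum if ``cumulative``.
    """
    if len(protomer_order) < 2:
        raise LandscapeError("need at least two protomers")
    chains_of = {}
    for chain, prot in structure.protomer_map.items():
        chains_of.setdefault(prot, []).append(chain)
    coords = structure.coords()

    def matched_atoms(prot: str) -> dict[tuple[int, str], int]:
        out = {}
        for i, a in enumerate(structure.atoms):
            if structure.protomer_map[a.chain_id] != prot:
                continue
            if res_range is not None and not (res_range[0] <= a.res_seq <= res_range[1]):
                continue
            if atom_names is not None and a.name not in atom_names:
                continue
            out[(a.res_seq, a.name)] = i
        return out

    angles = []
    for pa, pb in zip(protomer_order[:-1], protomer_order[1:]):
        ma, mb = matched_atoms(pa), matched_atoms(pb)
        common = sorted(set(ma) & set(mb))
        if len(common) < 3:
            raise LandscapeError(f"protomers {pa} and {pb} share fewer than 3 matched atoms")
        ca = coords[[ma[k] for k in common]]
        cb = coords[[mb[k] for k in common]]
        angles.append(rotation_angle(kabsch_rotation(ca, cb)))
    return float(np.sum(angles) if cumulative else np.mean(angles))


def basin_delta_f(grid: FESGrid, split: float, temperature: float = 300.0) -> float:
    """Free-energy difference (kJ/mol) between the basins right and left of ``split``.

    1D only: Delta F = -kB T ln(Z_right / Z_left) with Z from trapezoidal
    integration of exp(-F/kBT) over each side of the dividing point.
    """
    if grid.ndim != 1:
        raise LandscapeError("basin_delta_f is defined for 1D grids")
    s = grid.axes[0]
    w = np.exp(-grid.values / (KB * temperature))
    left = s <= split
    right = s >= split
    z_left = np.trapezoid(w[left], s[left])
    z_right = np.trapezoid(w[right], s[right])
    return float(-KB * temperature * np.log(z_right / z_left))


# --- serialization ----------------------------------------------------------

def write_fes(path, grid: FESGrid) -> None:
    """Whitespace table: one row per grid node (axis values then free energy)."""
    shape = " ".join(str(len(a)) for a in grid.axes)
    lines = [f"# fes shape {shape}"]
    mesh = np.meshgrid(*grid.axes, indexing="ij")
    flat = [m.ravel() for m in mesh] + [grid.values.ravel()]
    for row in zip(*flat):
        lines.append(" ".join(f"{x:.8f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fes(path) -> FESGrid:
    lines = Path(path).read_text().splitlines()
    shape = tuple(int(x) for x in lines[0].split("shape")[1].split())
    data = np.array([[float(x) for x in line.split()] for line in lines[1:] if line.strip()])
    axes = []
    for dim in range(len(shape)):
        col = data[:, dim].reshape(shape)
        axes.append(np.unique(col))
    return FESGrid(axes, data[:, -1].reshape(shape))


def write_clusters(path, result: ClusterResult) -> None:
    lines = ["index\tlabel"]
    lines += [f"{i}\t{lab}" for i, lab in enumerate(result.labels)]
    Path(path).write_text("\n".join(lines) + "\n")
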