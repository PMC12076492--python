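"""HILLS / COLVAR text tables in the PLUMED column convention.

HILLS: ``#! FIELDS time <cv...> <sigma_cv...> height biasf`` with one row per
deposited Gaussian.  COLVAR: ``#! FIELDS time <cv...>`` with one row per
record.  Both are whitespace-delimited plain text, interoperable with the
files an enhanced-sampling engine writes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .sampling import Hill


def _cv_names(d: int) -> list[str]:
    return [f"cv{i + 1}" for i in range(d)]


def write_hills(path, hills: Sequence[Hill], bias_factor: float, dt: float = 1.0) -> None:
    """Write hills with time = deposit_step * dt (ps)."""
    if not hills:
        Path(path).write_text("#! FIELDS time height biasf\n")
        return
    d = len(hills[0].center)
    names = _cv_names(d)
    header = "#! FIELDS time " + " ".join(names) + " " + \
        " ".join(f"sigma_{n}" for n in names) + " height biasf"
    lines = [header]
    for h in hills:
        row = [h.deposit_step * dt, *h.center, *h.widths, h.height, bias_factor]
        lines.append(" ".join(f"{x:.9f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hills(path, dt: float = 1.0) -> tuple[list[Hill], float]:
    """Read a HILLS table; returns (hills, bias_factor)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#!"):
        raise ValueError("missing '#! FIELDS' header in HILLS file")
    fields = lines[0].split()[2:]
    d = sum(1 for f in fields if f.startswith("sigma_"))
    hills: list[Hill] = []
    biasf = float("nan")
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        vals = [float(x) for x in line.split()]
        time, center, widths, height, biasf = (
            vals[0], vals[1:1 + d], vals[1 + d:1 + 2 * d], vals[1 + 2 * d], vals[2 + 2 * d])
        hills.append(Hill(tuple(center), tuple(widths), height, int(round(time / dt))))
    return hills, biasf


def write_colvar(path, times: np.ndarray, cv: np.ndarray) -> None:
    cv = np.atleast_2d(np.asarray(cv, dtype=float))
    if cv.shape[0] != len(times):
        cv = cv.T
    header = "#! FIELDS time " + " ".join(_cv_names(cv.shape[1]))
    lines = [header]
    for t, row in zip(times, cv):
        lines.append(" ".join(f"{x:.9f}" for x in (t, *row)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_colvar(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (times, cv) with cv shaped (n_records, n_cvs)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append([float(x) for x in line.split()])
    data = np.asarray(rows)
    return data[:, 0], data[:, 1:]
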