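"""Biased Langevin sampling in CV space.

Implements the three bias potentials used to drive and map a two-state
transition:

* **Ratchet-and-pawl**: a one-sided harmonic ``V = k/2 (s - s_best)^2`` that
  acts only when the CV regresses past its best-achieved value ``s_best`` in
  the chosen direction, rectifying thermal fluctuations toward the target
  state without ever pushing past new ground.
* **Well-tempered metadynamics**: periodic deposition of repulsive Gaussian
  hills whose height decays as ``W = w0 exp(-V(s)/(kB (gamma-1) T))``; the
  free energy is recovered as ``F(s) = -(gamma/(gamma-1)) V(s)``.
* **Harmonic walls**: one-sided quadratic restraints ``kappa (s - bound)^2``
  confining the CV to the physically meaningful range.

The integrator is the BAOAB discretization of underdamped Langevin dynamics
for a fictitious particle of mass ``m`` (amu) on an analytic toy potential.
All runs are exactly reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import KB, KJMOL_IN_AMU_A2_PS2
from .potentials import ToyPotential


class SamplingError(RuntimeError):
    pass


@dataclass
class LangevinParams:
    """Integrator parameters.  dt in ps, friction in 1/ps, temperature in K, mass in amu."""

    dt: float = 0.01
    friction: float = 5.0
    temperature: float = 300.0
    mass: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction <= 0 or self.temperature <= 0:
            raise ValueError("dt, friction and temperature must be positive")


@dataclass
class RatchetBias:
    """One-sided harmonic pawl on a single CV (Eq.: V = k/2 (s - s_best)^2 when lagging)."""

    k: float  # kJ/mol/A^2
    direction: int = 1  # +1: push toward larger CV, -1: smaller
    s_best: float | None = None
    cv_index: int = 0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    def lag(self, s: float) -> float:
        """Signed shortfall of ``s`` behind ``s_best`` (positive when lagging)."""
        if self.s_best is None:
            return 0.0
        return self.direction * (self.s_best - s)

    def energy_and_gradient(self, s_vec: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(s_vec)
        s = float(s_vec[self.cv_index])
        lag = self.lag(s)
        if lag <= 0:
            return 0.0, grad
        delta = s - self.s_best
        grad[self.cv_index] = self.k * delta
        return 0.5 * self.k * delta * delta, grad

    def update(self, s_vec: np.ndarray) -> None:
        s = float(s_vec[self.cv_index])
        if self.s_best is None or self.lag(s) <= 0:
            self.s_best = s


def ratchet_energy_and_update(s: float, bias: RatchetBias) -> tuple[float, RatchetBias]:
    """Pure form of the ratchet rule: bias energy at ``s`` plus the updated pawl."""
    vec = np.zeros(bias.cv_index + 1)
    vec[bias.cv_index] = s
    energy, _ = bias.energy_and_gradient(vec)
    updated = replace(bias)
    updated.update(vec)
    return energy, updated


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian."""

    center: tuple[float, ...]
    widths: tuple[float, ...]
    height: float  # kJ/mol
    deposit_step: int
    walker: int = 0


@dataclass
class MetaDSchedule:
    """Well-tempered deposition schedule."""

    w0: float = 1.2            # kJ/mol
    pace: int = 500            # steps between deposits
    bias_factor: float = 20.0  # gamma
    widths: tuple[float, ...] = (0.05,)  # per-CV sigma, CV units
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        self.widths = tuple(float(w) for w in self.widths)
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")


def metad_height(v_bias_at_s: float, sched: MetaDSchedule) -> float:
    """Well-tempered hill height: w0 * exp(-V(s) / (kB (gamma-1) T))."""
    return sched.w0 * float(np.exp(-v_bias_at_s / (KB * (sched.bias_factor - 1.0) * sched.temperature)))


def bias_energy(s: np.ndarray | float, hills: Sequence[Hill]) -> float:
    """Total metadynamics bias at CV point ``s`` (kJ/mol)."""
    if not hills:
        return 0.0
    s = np.asarray(s, dtype=float).reshape(-1)
    centers = np.array([h.center for h in hills])
    widths = np.array([h.widths for h in hills])
    heights = np.array([h.height for h in hills])
    z = ((s[None, :] - centers) / widths) ** 2
    return float((heights * np.exp(-0.5 * z.sum(axis=1))).sum())


@dataclass
class MetaDBias:
    """Live metadynamics bias: shared hill store plus fast vectorized evaluation.

    Hill evaluation is exact by default.  For long 1D runs an optional grid
    cache (``grid_range=(lo, hi)``, spacing ``min(widths)/5``) accelerates the
    per-step force to O(1); deposit heights always use the exact hill sum, and
    points outside the cached range fall back to exact evaluation.
    """

    schedule: MetaDSchedule
    hills: list[Hill] = field(default_factory=list)
    grid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        d = len(self.schedule.widths)
        self._centers = np.empty((0, d))
        self._heights = np.empty(0)
        self._grid = None
        if self.grid_range is not None:
            if d != 1:
                raise ValueError("grid cache is supported for 1D CVs only")
            lo, hi = self.grid_range
            self._h = min(self.schedule.widths) / 5.0
            self._grid = np.arange(lo, hi + self._h, self._h)
            self._gv = np.zeros_like(self._grid)
            self._gg = np.zeros_like(self._grid)
        for h in self.hills:
            self._append_arrays(h)

    def _append_arrays(self, hill: Hill) -> None:
        self._centers = np.vstack([self._centers, np.asarray(hill.center)])
        self._heights = np.append(self._heights, hill.height)
        if self._grid is not None:
            c, sig = hill.center[0], hill.widths[0]
            e = hill.height * np.exp(-0.5 * ((self._grid - c) / sig) ** 2)
            self._gv += e
            self._gg += -e * (self._grid - c) / sig**2

    def exact_energy_and_gradient(self, s: np.ndarray) -> tuple[float, np.ndarray]:
        if self._heights.size == 0:
            return 0.0, np.zeros_like(s)
        sig = np.asarray(self.schedule.widths)
        diff = s[None, :] - self._centers
        g = self._heights * np.exp(-0.5 * ((diff / sig) ** 2).sum(axis=1))
        energy = float(g.sum())
        grad = -(g[:, None] * diff / sig**2).sum(axis=0)  # dV/ds of the Gaussian sum
        return energy, grad

    def energy_and_gradient(self, s: np.ndarray) -> tuple[float, np.ndarray]:
        if self._grid is not None and self._heights.size:
            x = float(s[0])
            f = (x - self._grid[0]) / self._h
            i = int(f)
            if 0 <= i < self._grid.size - 1:
                t = f - i
                v = (1 - t) * self._gv[i] + t * self._gv[i + 1]
                g = (1 - t) * self._gg[i] + t * self._gg[i + 1]
                return float(v), np.array([g])
        return self.exact_energy_and_gradient(s)

    def deposit(self, s: np.ndarray, step: int, walker: int = 0) -> Hill:
        v_here, _ = self.exact_energy_and_gradient(s)
        h = Hill(tuple(float(x) for x in s), self.schedule.widths,
                 metad_height(v_here, self.schedule), step, walker)
        self.hills.append(h)
        self._append_arrays(h)
        return h


@dataclass
class WallRestraint:
    """One-sided quadratic walls ``kappa (s - bound)^2`` outside [lower, upper]."""

    lower: Sequence[float | None] | None = None
    upper: Sequence[float | None] | None = None
    kappa: float = 100.0  # kJ/mol/unit^2

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            for lo, hi in zip(self.lower, self.upper):
                if lo is not None and hi is not None and not lo < hi:
                    raise ValueError("wall lower bound must be below upper bound")

    def energy_and_gradient(self, s: np.ndarray) -> tuple[float, np.ndarray]:
        energy = 0.0
        grad = np.zeros_like(s)
        for i, si in enumerate(s):
            lo = self.lower[i] if self.lower is not None else None
            hi = self.upper[i] if self.upper is not None else None
            if lo is not None and si < lo:
                energy += self.kappa * (si - lo) ** 2
                grad[i] += 2.0 * self.kappa * (si - lo)
            if hi is not None and si > hi:
                energy += self.kappa * (si - hi) ** 2
                grad[i] += 2.0 * self.kappa * (si - hi)
        return energy, grad


def wall_energy(s: np.ndarray | float, wall: WallRestraint) -> float:
    s = np.asarray(s, dtype=float).reshape(-1)
    return wall.energy_and_gradient(s)[0]


@dataclass
class SimResult:
    """Recorded CV trajectory (and hills, for metadynamics runs)."""

    times: np.ndarray          # ps
    cv: np.ndarray             # (n_records, d)
    hills: list[Hill]
    final_position: np.ndarray
    final_velocity: np.ndarray


class _Engine:
    """One Langevin walker; stepping is shared by single- and multi-walker drivers."""

    def __init__(self, pot: ToyPotential, biases: Sequence, params: LangevinParams,
                 s0: np.ndarray | None, walker: int = 0):
        self.pot = pot
        self.biases = list(biases)
        self.params = params
        self.walker = walker
        self.rng = np.random.default_rng(params.seed)
        self.x = (np.zeros(pot.dimension) if s0 is None
                  else np.asarray(s0, dtype=float).reshape(-1).copy())
        sigma_v = np.sqrt(KB * params.temperature * KJMOL_IN_AMU_A2_PS2 / params.mass)
        self.v = self.rng.normal(0.0, sigma_v, size=pot.dimension)
        self.step = 0
        # BAOAB constants
        self._a = np.exp(-params.friction * params.dt)
        self._b = sigma_v * np.sqrt(1.0 - self._a**2)
        self._accel_scale = KJMOL_IN_AMU_A2_PS2 / params.mass
        self._force = self._total_force()
        self.metad = next((b for b in self.biases if isinstance(b, MetaDBias)), None)
        self.ratchets = [b for b in self.biases if isinstance(b, RatchetBias)]
        for r in self.ratchets:
            r.update(self.x)

    def _total_force(self) -> np.ndarray:
        grad = self.pot.gradient(self.x).astype(float).copy()
        for b in self.biases:
            _, g = b.energy_and_gradient(self.x)
            grad += g
        if not np.all(np.isfinite(grad)):
            raise SamplingError(f"non-finite force at step {self.step}, s={self.x}")
        return -grad

    def advance(self, n_steps: int, record_stride: int,
                rec_times: list, rec_cv: list) -> None:
        dt = self.params.dt
        for _ in range(n_steps):
            self.step += 1
            self.v += 0.5 * dt * self._accel_scale * self._force
            self.x += 0.5 * dt * self.v
            self.v = self._a * self.v + self._b * self.rng.normal(size=self.x.shape)
            self.x += 0.5 * dt * self.v
            for r in self.ratchets:
                r.update(self.x)
            if self.metad is not None and self.step % self.metad.schedule.pace == 0:
                self.metad.deposit(self.x, self.step, self.walker)
            self._force = self._total_force()
            self.v += 0.5 * dt * self._accel_scale * self._force
            if self.step % record_stride == 0:
                rec_times.append(self.step * dt)
                rec_cv.append(self.x.copy())


def integrate(pot: ToyPotential, biases: Sequence, params: LangevinParams,
              n_steps: int, record_stride: int = 10,
              s0: np.ndarray | float | None = None) -> SimResult:
    """Run BAOAB Langevin dynamics under the given bias terms.

    ``biases`` may contain :class:`RatchetBias`, :class:`MetaDBias` and
    :class:`WallRestraint` instances in any combination.  Hills are deposited
    every ``pace`` steps when a :class:`MetaDBias` is present.  Identical
    inputs (seed included) give identical output.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if s0 is not None and np.isscalar(s0):
        s0 = np.array([float(s0)])
    eng = _Engine(pot, biases, params, s0)
    times: list[float] = []
    cv: list[np.ndarray] = []
    eng.advance(n_steps, record_stride, times, cv)
    hills = eng.metad.hills if eng.metad is not None else []
    return SimResult(np.asarray(times), np.asarray(cv), list(hills), eng.x.copy(), eng.v.copy())


@dataclass
class WalkerPool:
    """Multiple-walker configuration: per-walker seeds/starts, shared hill list."""

    n_walkers: int
    seeds: Sequence[int]
    starts: Sequence[np.ndarray | float]
    sync_stride: int = 500

    def __post_init__(self) -> None:
        if self.n_walkers < 1:
            raise ValueError("need at least one walker")
        if len(self.seeds) != self.n_walkers or len(self.starts) != self.n_walkers:
            raise ValueError("seeds and starts must match n_walkers")


def run_multiple_walkers(pool: WalkerPool, pot: ToyPotential, sched: MetaDSchedule,
                         params: LangevinParams, n_steps: int,
                         extra_biases: Sequence = (), record_stride: int = 10
                         ) -> tuple[list[Hill], list[SimResult]]:
    """Advance walkers round-robin in ``sync_stride`` blocks over one shared hill list.

    Returns the combined hill list (time-ordered by deposit step, then walker)
    and per-walker results.  A one-walker pool reproduces
    :func:`integrate` bit for bit.
    """
    shared = MetaDBias(sched)
    engines = []
    for w in range(pool.n_walkers):
        p = replace(params, seed=pool.seeds[w])
        s0 = pool.starts[w]
        s0 = np.array([float(s0)]) if np.isscalar(s0) else np.asarray(s0, dtype=float)
        engines.append(_Engine(pot, [shared, *extra_biases], p, s0, walker=w))
    recs: list[tuple[list, list]] = [([], []) for _ in engines]
    done = 0
    while done < n_steps:
        block = min(pool.sync_stride, n_steps - done)
        for eng, (times, cv) in zip(engines, recs):
            eng.advance(block, record_stride, times, cv)
        done += block
    results = [
        SimResult(np.asarray(t), np.asarray(c), list(shared.hills), eng.x.copy(), eng.v.copy())
        for eng, (t, c) in zip(engines, recs)
    ]
    combined = sorted(shared.hills, key=lambda h: (h.deposit_step, h.walker))
    return combined, results


def fes_from_hills(hills: Sequence[Hill], grid_spec: Sequence[tuple[float, float, int]],
                   gamma: float):
    """Well-tempered FES estimate: F(s) = -(gamma/(gamma-1)) V(s), min-shifted to zero.

    ``grid_spec`` is one (lo, hi, n_points) triple per CV.  Returns a
    :class:`metacv.landscape.FESGrid`.
    """
    from .landscape import FESGrid

    if gamma <= 1:
        raise ValueError("bias factor must exceed 1")
    axes = [np.linspace(lo, hi, n) for lo, hi, n in grid_spec]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    v = np.zeros(points.shape[0])
    if hills:
        centers = np.array([h.center for h in hills])
        widths = np.array([h.widths for h in hills])
        heights = np.array([h.height for h in hills])
        chunk = max(1, int(2e7 // max(1, len(hills))))
        for i in range(0, points.shape[0], chunk):
            z = ((points[i:i + chunk, None, :] - centers[None, :, :]) / widths[None, :, :]) ** 2
            v[i:i + chunk] = (heights[None, :] * np.exp(-0.5 * z.sum(axis=2))).sum(axis=1)
    f = -(gamma / (gamma - 1.0)) * v
    f -= f.min()
    return FESGrid(axes, f.reshape([len(ax) for ax in axes]))
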