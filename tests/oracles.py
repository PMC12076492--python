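"""Independent reference implementations used only to cross-check the package.

Each oracle takes a deliberately different route from the implementation it
checks: exhaustive O(N^2)/O(N^3) scans for contact detection, a dense
generalized eigendecomposition for the discriminant direction, the Horn
quaternion method for superposition, and dense Riemann sums for basin
free energies.
"""

from __future__ import annotations

import numpy as np

from metacv.contacts import (
    ACIDIC_OXYGENS, BASIC_NITROGENS, HBOND_ACCEPTORS, HBOND_DONORS,
)


def brute_force_salt_bridges(frame, topology, cutoff=6.0):
    """All-pairs scan; returns the set of canonical (atom_a, atom_b) pairs."""

    def is_acidic(a):
        return a.name in ACIDIC_OXYGENS.get(a.res_name, frozenset()) | ACIDIC_OXYGENS["*"]

    def is_basic(a):
        return a.name in BASIC_NITROGENS.get(a.res_name, frozenset())

    best = {}
    for i, ai in enumerate(topology.atoms):
        if not is_acidic(ai):
            continue
        for j, aj in enumerate(topology.atoms):
            if not is_basic(aj):
                continue
            if (ai.chain_id, ai.res_seq) == (aj.chain_id, aj.res_seq):
                continue
            d = float(np.linalg.norm(np.asarray(frame[i]) - np.asarray(frame[j])))
            if d <= cutoff:
                key = (ai.chain_id, ai.res_seq, aj.chain_id, aj.res_seq)
                if key not in best or d < best[key][0]:
                    best[key] = (d, ai.key, aj.key)
    return {frozenset((a, b)) for _, a, b in best.values()}


def brute_force_hbonds(frame, topology, d_cut=3.0, ang_cut=30.0):
    """Exhaustive donor-hydrogen-acceptor triple scan."""
    by_res = {}
    for i, a in enumerate(topology.atoms):
        by_res.setdefault((a.chain_id, a.res_seq), {})[a.name] = i
    out = set()
    for i, d_atom in enumerate(topology.atoms):
        h_names = (HBOND_DONORS.get((d_atom.res_name, d_atom.name))
                   or HBOND_DONORS.get(("*", d_atom.name)))
        if h_names is None:
            continue
        h_idx = [by_res[(d_atom.chain_id, d_atom.res_seq)][h]
                 for h in h_names if h in by_res[(d_atom.chain_id, d_atom.res_seq)]]
        for j, a_atom in enumerate(topology.atoms):
            ok = a_atom.name in (HBOND_ACCEPTORS.get(a_atom.res_name, frozenset())
                                 | HBOND_ACCEPTORS["*"])
            if not ok or (d_atom.chain_id, d_atom.res_seq) == (a_atom.chain_id, a_atom.res_seq):
                continue
            if np.linalg.norm(np.asarray(frame[i]) - np.asarray(frame[j])) > d_cut:
                continue
            for hi in h_idx:
                v1 = np.asarray(frame[i]) - np.asarray(frame[hi])
                v2 = np.asarray(frame[j]) - np.asarray(frame[hi])
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if 180.0 - ang <= ang_cut:
                    out.add(frozenset((d_atom.key, a_atom.key)))
                    break
    return out


def rayleigh_direction(sigma_a, sigma_b, mu_a, mu_b):
    """Top generalized eigenvector of max w' (dmu dmu') w / w' S_w w, dense solve."""
    from scipy.linalg import eigh

    s_w = np.linalg.inv(np.linalg.inv(sigma_a) + np.linalg.inv(sigma_b))
    dmu = np.asarray(mu_a) - np.asarray(mu_b)
    b = np.outer(dmu, dmu)
    vals, vecs = eigh(b, s_w)
    w = vecs[:, -1]
    w = w / np.linalg.norm(w)
    if w @ dmu < 0:
        w = -w
    return w


def quaternion_rmsd(coords_a, coords_b):
    """Horn's closed-form quaternion superposition RMSD."""
    a = np.asarray(coords_a, float) - np.mean(coords_a, axis=0)
    b = np.asarray(coords_b, float) - np.mean(coords_b, axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    e0 = (a**2).sum() + (b**2).sum()
    msd = max(0.0, (e0 - 2.0 * lam) / a.shape[0])
    return float(np.sqrt(msd))


def grid_minima_scan(values, depth_cut=None):
    """Exhaustive neighbor scan for strict local minima (full Chebyshev stencil)."""
    from itertools import product

    values = np.asarray(values)
    offsets = [o for o in product((-1, 0, 1), repeat=values.ndim) if any(o)]
    out = []
    for idx in np.ndindex(values.shape):
        ok = True
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= n < s for n, s in zip(nb, values.shape)) and values[nb] <= values[idx]:
                ok = False
                break
        if ok and (depth_cut is None or values[idx] <= depth_cut):
            out.append((idx, float(values[idx])))
    return sorted(out, key=lambda t: t[1])


def riemann_delta_f(energy_fn, split, temperature, lo=-60.0, hi=60.0, n=1_000_000):
    """Dense Riemann-sum basin free-energy difference (right minus left of split)."""
    from metacv.constants import KB

    beta = 1.0 / (KB * temperature)
    x = np.linspace(lo, hi, n)
    w = np.exp(-beta * energy_fn(x))  # energy_fn must be vectorized
    dx = x[1] - x[0]
    z_left = w[x <= split].sum() * dx
    z_right = w[x > split].sum() * dx
    return float(-np.log(z_right / z_left) / beta)
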