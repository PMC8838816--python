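"""Numba force kernels (internal units: nm, kJ/mol, kJ mol^-1 nm^-1)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bonded_energy_forces(pos, bi, bj, b0, kb, box, pbc, forces):
    """Harmonic bonds V = 1/2 k (r - r0)^2; accumulates into ``forces``."""
    e = 0.0
    for n in range(bi.size):
        i = bi[n]
        j = bj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if pbc:
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - b0[n]
        e += 0.5 * kb[n] * dr * dr
        if r > 0.0:
            fscal = -kb[n] * dr / r
            forces[i, 0] += fscal * dx
            forces[i, 1] += fscal * dy
            forces[i, 2] += fscal * dz
            forces[j, 0] -= fscal * dx
            forces[j, 1] -= fscal * dy
            forces[j, 2] -= fscal * dz
    return e


@njit(cache=True)
def lj_energy_forces(pos, pi, pj, sig, eps, vshift, cutoff2, box, pbc, forces):
    """Truncated-and-shifted Lennard-Jones 12-6 over an explicit pair list."""
    e = 0.0
    for n in range(pi.size):
        i = pi[n]
        j = pj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if pbc:
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff2 or r2 == 0.0:
            continue
        inv_r2 = 1.0 / r2
        sr2 = sig[n] * sig[n] * inv_r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        e += 4.0 * eps[n] * (sr12 - sr6) - vshift[n]
        fscal = 24.0 * eps[n] * (2.0 * sr12 - sr6) * inv_r2
        forces[i, 0] += fscal * dx
        forces[i, 1] += fscal * dy
        forces[i, 2] += fscal * dz
        forces[j, 0] -= fscal * dx
        forces[j, 1] -= fscal * dy
        forces[j, 2] -= fscal * dz
    return e
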