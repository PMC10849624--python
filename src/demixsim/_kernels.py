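"""Numba kernels: pairwise forces and the BAOAB Langevin inner loop.

Everything here works in GROMACS-style units (nm, ps, amu, kJ/mol), which are
internally consistent: 1 kJ/mol == 1 amu nm^2 ps^-2.

The nonbonded model is a hydropathy-scaled Lennard-Jones (Ashbaugh-Hatch)
term plus a Debye-Hueckel screened electrostatic term; both are truncated and
shifted to zero at their cutoffs.  Pair tables (``sig_ij``, ``lam_ij``,
``qq_ij``) are dense N x N matrices precomputed by the engine; ``lam_ij``
already contains any homotypic scaling factors.  Bonded first neighbours are
excluded from the nonbonded sum via ``excl``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def compute_forces(
    pos,
    box,
    sig_ij,
    lam_ij,
    qq_ij,
    excl,
    eps,
    ah_cut,
    dh_cut,
    debye,
    bonds,
    bond_k,
    bond_r0,
    forces,
):
    """Fill ``forces`` (N,3) in place; return potential energy (kJ/mol)."""
    n = pos.shape[0]
    for i in range(n):
        for k in range(3):
            forces[i, k] = 0.0
    pe = 0.0
    ah_cut2 = ah_cut * ah_cut
    dh_cut2 = dh_cut * dh_cut
    cut2 = ah_cut2 if ah_cut2 > dh_cut2 else dh_cut2
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx -= box[0] * np.round(dx / box[0])
            dy -= box[1] * np.round(dy / box[1])
            dz -= box[2] * np.round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cut2:
                continue
            r = np.sqrt(r2)
            fr = 0.0  # force magnitude / r
            if r2 < ah_cut2:
                sig = sig_ij[i, j]
                lam = lam_ij[i, j]
                sr2 = sig * sig / r2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                philj = 4.0 * eps * (sr12 - sr6)
                # d(phi_lj)/dr * r = -4 eps (12 sr12 - 6 sr6)
                dphilj_r = -24.0 * eps * (2.0 * sr12 - sr6) / r2
                src = sig / ah_cut
                src6 = src ** 6
                shift = lam * 4.0 * eps * (src6 * src6 - src6)
                if r <= SIXTH_ROOT_2 * sig:
                    pe += philj + (1.0 - lam) * eps - shift
                    fr += -dphilj_r
                else:
                    pe += lam * philj - shift
                    fr += -lam * dphilj_r
            qq = qq_ij[i, j]
            if qq != 0.0 and r2 < dh_cut2:
                ex = np.exp(-r / debye)
                pe += qq * (ex / r - np.exp(-dh_cut / debye) / dh_cut)
                # -d/dr [qq e^{-r/ld}/r] / r
                fr += qq * ex * (1.0 / (r2 * r) + 1.0 / (r2 * debye))
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        pe += 0.5 * bond_k * (r - bond_r0) ** 2
        if r > 0.0:
            fr = -bond_k * (r - bond_r0) / r
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
    return pe


@njit(cache=True)
def baoab_chunk(
    pos,
    vel,
    mass,
    box,
    sig_ij,
    lam_ij,
    qq_ij,
    excl,
    eps,
    ah_cut,
    dh_cut,
    debye,
    bonds,
    bond_k,
    bond_r0,
    dt,
    c1,
    kT,
    noise,
):
    """Integrate ``noise.shape[0]`` BAOAB steps in place.

    ``c1 = exp(-friction * dt)``; with ``c1 == 1`` the O-step is the identity
    and the scheme reduces to velocity Verlet (NVE).  Returns the potential
    and kinetic energies after the last step.
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    forces = np.empty((n, 3))
    pe = compute_forces(
        pos, box, sig_ij, lam_ij, qq_ij, excl, eps, ah_cut, dh_cut, debye,
        bonds, bond_k, bond_r0, forces,
    )
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    half_dt = 0.5 * dt
    for s in range(nsteps):
        for i in range(n):
            inv_m = 1.0 / mass[i]
            sd = c2 * np.sqrt(kT * inv_m)
            for k in range(3):
                v = vel[i, k] + half_dt * forces[i, k] * inv_m
                pos[i, k] += half_dt * v
                v = c1 * v + sd * noise[s, i, k]
                pos[i, k] += half_dt * v
                vel[i, k] = v
        pe = compute_forces(
            pos, box, sig_ij, lam_ij, qq_ij, excl, eps, ah_cut, dh_cut, debye,
            bonds, bond_k, bond_r0, forces,
        )
        for i in range(n):
            inv_m = 1.0 / mass[i]
            for k in range(3):
                vel[i, k] += half_dt * forces[i, k] * inv_m
    ke = 0.0
    for i in range(n):
        ke += 0.5 * mass[i] * (
            vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
        )
    return pe, ke
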