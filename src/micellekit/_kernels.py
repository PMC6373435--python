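"""Numba force/integration kernels for the reduced Langevin engine.

Pairwise terms: truncated-and-shifted 12-6 Lennard-Jones between beads of
different molecules (well depth from a symmetric type-pair table, single
sigma), plus Debye-screened Coulomb between charged beads.  Bonds are
harmonic.  Distances use the minimum-image convention in an orthorhombic
box.  The cell-list path requires at least three cells per dimension and
falls back to the all-pairs loop otherwise; both produce identical physics
(accumulation order may differ at floating-point rounding level).
"""

import math

import numpy as np
from numba import njit

#: Coulomb constant in kJ mol^-1 nm e^-2
F_ELEC = 138.935458


@njit(cache=True, inline="always")
def _min_image(d, box_l):
    return d - box_l * math.floor(d / box_l + 0.5)


@njit(cache=True, inline="always")
def _pair_interaction(
    dx, dy, dz, r2, ti, tj, qq, eps_mat, sigma2, shift_factor, lj_cut2,
    ke, inv_debye, coul_cut, coul_shift_per_qq, forces, i, j,
):
    """Accumulate force/energy of one nonbonded pair; returns energy."""
    e = 0.0
    epsilon = eps_mat[ti, tj]
    if epsilon > 0.0 and r2 < lj_cut2:
        sr2 = sigma2 / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        e += 4.0 * epsilon * (sr12 - sr6) - epsilon * shift_factor
        fs = 24.0 * epsilon * (2.0 * sr12 - sr6) / r2
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    if qq != 0.0:
        r = math.sqrt(r2)
        if r < coul_cut:
            screen = math.exp(-r * inv_debye)
            e += ke * qq * (screen / r - coul_shift_per_qq)
            fs = ke * qq * screen * (1.0 / r + inv_debye) / r2
            forces[i, 0] += fs * dx
            forces[i, 1] += fs * dy
            forces[i, 2] += fs * dz
            forces[j, 0] -= fs * dx
            forces[j, 1] -= fs * dy
            forces[j, 2] -= fs * dz
    return e


@njit(cache=True)
def _nonbonded_allpairs(
    pos, box, mol, type_idx, charge, eps_mat, sigma2, shift_factor, lj_cut2,
    ke, inv_debye, coul_cut, coul_shift_per_qq, forces,
):
    n = pos.shape[0]
    energy = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if mol[i] == mol[j]:
                continue
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= coul_cut * coul_cut and r2 >= lj_cut2:
                continue
            energy += _pair_interaction(
                dx, dy, dz, r2, type_idx[i], type_idx[j],
                charge[i] * charge[j], eps_mat, sigma2, shift_factor, lj_cut2,
                ke, inv_debye, coul_cut, coul_shift_per_qq, forces, i, j,
            )
    return energy


@njit(cache=True)
def _nonbonded_celllist(
    pos, box, mol, type_idx, charge, eps_mat, sigma2, shift_factor, lj_cut2,
    ke, inv_debye, coul_cut, coul_shift_per_qq, forces,
):
    n = pos.shape[0]
    cut = max(math.sqrt(lj_cut2), coul_cut)
    ncx = max(1, int(box[0] / cut))
    ncy = max(1, int(box[1] / cut))
    ncz = max(1, int(box[2] / cut))
    ncell = ncx * ncy * ncz
    head = -np.ones(ncell, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * ncx) % ncx
        cy = int(pos[i, 1] / box[1] * ncy) % ncy
        cz = int(pos[i, 2] / box[2] * ncz) % ncz
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        nxt[i] = head[c]
        head[c] = i

    # half-shell of 13 neighbour offsets plus the cell itself
    offsets = np.array(
        [
            (0, 0, 0),
            (1, 0, 0), (0, 1, 0), (0, 0, 1),
            (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
            (0, 1, 1), (0, 1, -1),
            (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
        ],
        dtype=np.int64,
    )
    energy = 0.0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                for o in range(offsets.shape[0]):
                    nx = (cx + offsets[o, 0]) % ncx
                    ny = (cy + offsets[o, 1]) % ncy
                    nz = (cz + offsets[o, 2]) % ncz
                    c2 = (nx * ncy + ny) * ncz + nz
                    same = c2 == c
                    if same and o != 0:
                        continue  # wrapped back onto itself (few cells)
                    i = head[c]
                    while i >= 0:
                        j = head[c2] if not same else nxt[i]
                        while j >= 0:
                            if mol[i] != mol[j]:
                                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 < coul_cut * coul_cut or r2 < lj_cut2:
                                    energy += _pair_interaction(
                                        dx, dy, dz, r2, type_idx[i], type_idx[j],
                                        charge[i] * charge[j], eps_mat, sigma2,
                                        shift_factor, lj_cut2, ke, inv_debye,
                                        coul_cut, coul_shift_per_qq, forces, i, j,
                                    )
                            j = nxt[j]
                        i = nxt[i]
    return energy


@njit(cache=True)
def _bond_forces(pos, box, bonds, r0, k_bond, forces):
    energy = 0.0
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        energy += 0.5 * k_bond * dr * dr
        fs = -k_bond * dr / r
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    return energy


@njit(cache=True)
def compute_forces(
    pos, box, mol, type_idx, charge, eps_mat, sigma2, shift_factor, lj_cut2,
    ke, inv_debye, coul_cut, coul_shift_per_qq, bonds, r0, k_bond, use_cell,
):
    """Total potential energy and forces (kJ/mol, kJ/mol/nm)."""
    forces = np.zeros_like(pos)
    if use_cell:
        e = _nonbonded_celllist(
            pos, box, mol, type_idx, charge, eps_mat, sigma2, shift_factor,
            lj_cut2, ke, inv_debye, coul_cut, coul_shift_per_qq, forces,
        )
    else:
        e = _nonbonded_allpairs(
            pos, box, mol, type_idx, charge, eps_mat, sigma2, shift_factor,
            lj_cut2, ke, inv_debye, coul_cut, coul_shift_per_qq, forces,
        )
    e += _bond_forces(pos, box, bonds, r0, k_bond, forces)
    return e, forces


@njit(cache=True)
def baoab_chunk(
    pos, vel, box, mol, type_idx, charge, eps_mat, sigma2, shift_factor,
    lj_cut2, ke, inv_debye, coul_cut, coul_shift_per_qq, bonds, r0, k_bond,
    use_cell, forces, noise, dt, c1, c2, inv_mass,
):
    """Advance `noise.shape[0]` BAOAB Langevin steps in place.

    c1 = exp(-gamma*dt), c2 = sqrt(kT/m * (1 - c1^2)); with gamma = 0 the
    scheme reduces to velocity Verlet.  Returns the final potential energy.
    """
    n_steps = noise.shape[0]
    n = pos.shape[0]
    e = 0.0
    for s in range(n_steps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d] * inv_mass
                pos[i, d] += 0.5 * dt * vel[i, d]
                vel[i, d] = c1 * vel[i, d] + c2 * noise[s, i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
                pos[i, d] -= box[d] * math.floor(pos[i, d] / box[d])
        e, new_forces = compute_forces(
            pos, box, mol, type_idx, charge, eps_mat, sigma2, shift_factor,
            lj_cut2, ke, inv_debye, coul_cut, coul_shift_per_qq, bonds, r0,
            k_bond, use_cell,
        )
        for i in range(n):
            for d in range(3):
                forces[i, d] = new_forces[i, d]
                vel[i, d] += 0.5 * dt * forces[i, d] * inv_mass
    return e
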