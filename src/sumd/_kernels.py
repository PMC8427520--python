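"""Numba-compiled force evaluation and BAOAB Langevin integration.

These kernels are internal: :mod:`sumd.engine` wraps them behind the
documented engine API. All forces are computed in kcal/(mol A) and
converted to accelerations with the 418.4 factor (see :mod:`sumd.constants`).

Role codes used throughout: 0 = ligand, 1 = receptor, 2 = solvent.
"""

import numpy as np
from numba import njit

ROLE_LIGAND = 0
ROLE_RECEPTOR = 1
ROLE_SOLVENT = 2


@njit(cache=False)
def _forces(pos, roles, forces,
            site_center, funnel_depth, funnel_width,
            rep_sigma, rep_eps,
            conf_center, conf_radius_lig, conf_radius_sol, conf_k,
            dw_height, dw_half_sep, dw_transverse_k,
            restraint_k, restraint_ref):
    """Fill ``forces`` (kcal/mol/A) for the composite toy potential."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0

    # funnel well: Gaussian attraction of each ligand bead to the site center
    if funnel_depth > 0.0:
        w2 = funnel_width * funnel_width
        for i in range(n):
            if roles[i] == ROLE_LIGAND:
                dx = pos[i, 0] - site_center[0]
                dy = pos[i, 1] - site_center[1]
                dz = pos[i, 2] - site_center[2]
                r2 = dx * dx + dy * dy + dz * dz
                g = funnel_depth / w2 * np.exp(-0.5 * r2 / w2)
                forces[i, 0] -= g * dx
                forces[i, 1] -= g * dy
                forces[i, 2] -= g * dz

    # quartic double well along x (centered on the origin) for ligand beads
    if dw_height > 0.0:
        a2 = dw_half_sep * dw_half_sep
        a4 = a2 * a2
        for i in range(n):
            if roles[i] == ROLE_LIGAND:
                x = pos[i, 0]
                forces[i, 0] -= 4.0 * dw_height * x * (x * x - a2) / a4
                forces[i, 1] -= 2.0 * dw_transverse_k * pos[i, 1]
                forces[i, 2] -= 2.0 * dw_transverse_k * pos[i, 2]

    # pairwise soft-core repulsion, skipping receptor-receptor pairs
    if rep_eps > 0.0:
        for i in range(n):
            for j in range(i + 1, n):
                if roles[i] == ROLE_RECEPTOR and roles[j] == ROLE_RECEPTOR:
                    continue
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= rep_sigma * rep_sigma or r2 < 1e-16:
                    continue
                r = np.sqrt(r2)
                f = 2.0 * rep_eps / rep_sigma * (1.0 - r / rep_sigma) / r
                forces[i, 0] += f * dx
                forces[i, 1] += f * dy
                forces[i, 2] += f * dz
                forces[j, 0] -= f * dx
                forces[j, 1] -= f * dy
                forces[j, 2] -= f * dz

    # confining sphere (flat inside, harmonic outside); radius by role
    if conf_k > 0.0:
        for i in range(n):
            if roles[i] == ROLE_RECEPTOR:
                continue
            radius = conf_radius_lig if roles[i] == ROLE_LIGAND else conf_radius_sol
            dx = pos[i, 0] - conf_center[0]
            dy = pos[i, 1] - conf_center[1]
            dz = pos[i, 2] - conf_center[2]
            rho = np.sqrt(dx * dx + dy * dy + dz * dz)
            if rho > radius:
                f = -2.0 * conf_k * (rho - radius) / rho
                forces[i, 0] += f * dx
                forces[i, 1] += f * dy
                forces[i, 2] += f * dz

    # optional harmonic restraint of receptor beads to their reference
    if restraint_k > 0.0:
        for i in range(n):
            if roles[i] == ROLE_RECEPTOR:
                forces[i, 0] -= 2.0 * restraint_k * (pos[i, 0] - restraint_ref[i, 0])
                forces[i, 1] -= 2.0 * restraint_k * (pos[i, 1] - restraint_ref[i, 1])
                forces[i, 2] -= 2.0 * restraint_k * (pos[i, 2] - restraint_ref[i, 2])


@njit(cache=False)
def _add_bias_force(pos, roles, forces, site_center,
                    grid_dv, grid_x0, grid_dx):
    """Add -dV/ds projected on the centroid-distance CV gradient.

    The CV is the distance between the geometric center of the ligand
    beads and the site center. grid_dv holds dV/ds at uniformly spaced
    CV values starting at grid_x0 with spacing grid_dx.
    """
    n = pos.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    nlig = 0
    for i in range(n):
        if roles[i] == ROLE_LIGAND:
            cx += pos[i, 0]
            cy += pos[i, 1]
            cz += pos[i, 2]
            nlig += 1
    if nlig == 0:
        return 0.0
    cx /= nlig
    cy /= nlig
    cz /= nlig
    dx = cx - site_center[0]
    dy = cy - site_center[1]
    dz = cz - site_center[2]
    s = np.sqrt(dx * dx + dy * dy + dz * dz)
    if s < 1e-9:
        return s
    # linear interpolation of dV/ds on the grid (clamped at the ends)
    u = (s - grid_x0) / grid_dx
    if u <= 0.0:
        dvds = grid_dv[0]
    elif u >= grid_dv.shape[0] - 1:
        dvds = grid_dv[grid_dv.shape[0] - 1]
    else:
        k = int(u)
        frac = u - k
        dvds = grid_dv[k] * (1.0 - frac) + grid_dv[k + 1] * frac
    f = -dvds / (s * nlig)
    for i in range(n):
        if roles[i] == ROLE_LIGAND:
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
    return s


@njit(cache=False)
def _baoab_chunk(pos, vel, roles, mobile, acc_scale, n_steps, dt,
                 c_fric, c_noise, noise,
                 site_center, funnel_depth, funnel_width,
                 rep_sigma, rep_eps,
                 conf_center, conf_radius_lig, conf_radius_sol, conf_k,
                 dw_height, dw_half_sep, dw_transverse_k,
                 restraint_k, restraint_ref,
                 bias_on, grid_dv, grid_x0, grid_dx):
    """Integrate ``n_steps`` BAOAB steps in place.

    acc_scale[i] = 418.4/mass_i converts kcal/(mol A) to A/ps^2.
    c_fric = exp(-friction*dt); c_noise[i] = sqrt(kB*T/m_i)*sqrt(1-c_fric^2)
    in A/ps. noise has shape (n_steps, N, 3); entries for non-mobile beads
    are ignored. Returns 0 on success, the (1-based) step index of the
    first non-finite coordinate otherwise.
    """
    n = pos.shape[0]
    forces = np.empty((n, 3))
    _forces(pos, roles, forces, site_center, funnel_depth, funnel_width,
            rep_sigma, rep_eps, conf_center, conf_radius_lig,
            conf_radius_sol, conf_k, dw_height, dw_half_sep,
            dw_transverse_k, restraint_k, restraint_ref)
    if bias_on:
        _add_bias_force(pos, roles, forces, site_center,
                        grid_dv, grid_x0, grid_dx)
    half = 0.5 * dt
    for step in range(n_steps):
        for i in range(n):
            if not mobile[i]:
                continue
            for d in range(3):
                vel[i, d] += half * forces[i, d] * acc_scale[i]
                pos[i, d] += half * vel[i, d]
                vel[i, d] = c_fric * vel[i, d] + c_noise[i] * noise[step, i, d]
                pos[i, d] += half * vel[i, d]
        _forces(pos, roles, forces, site_center, funnel_depth, funnel_width,
                rep_sigma, rep_eps, conf_center, conf_radius_lig,
                conf_radius_sol, conf_k, dw_height, dw_half_sep,
                dw_transverse_k, restraint_k, restraint_ref)
        if bias_on:
            _add_bias_force(pos, roles, forces, site_center,
                            grid_dv, grid_x0, grid_dx)
        blown = False
        for i in range(n):
            if not mobile[i]:
                continue
            for d in range(3):
                vel[i, d] += half * forces[i, d] * acc_scale[i]
                if not np.isfinite(pos[i, d]) or abs(pos[i, d]) > 1e6:
                    blown = True
        if blown:
            return step + 1
    return 0
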