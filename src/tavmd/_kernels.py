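"""Numba inner kernels for the toy bead force field.

The force field itself is defined in :mod:`tavmd.cgmodel`; this module only
holds the hot per-step loop (bonds, virtual-bond angles, torsions, excluded
volume) compiled with numba so that multi-million-step trajectories run at
interactive speed on one core.
"""

import numpy as np
from numba import njit

_DEG = 180.0 / np.pi


@njit(cache=True)
def toy_energy_forces_kernel(coords, k_bond, b0, k_theta, theta0_deg,
                             c1, c3, c1s, eps_ev, sigma_ev, ev_min_sep):
    """Energy and exact negative gradient of the toy bead potential.

    Angles enter the harmonic term in degrees (k_theta is per deg^2).
    Returns (e_bond, e_angle, e_dihedral, e_ev, forces).
    """
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    e_bond = 0.0
    e_angle = 0.0
    e_dih = 0.0
    e_ev = 0.0

    # bonds
    for i in range(n - 1):
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - b0
        e_bond += 0.5 * k_bond * dr * dr
        f = -k_bond * dr / r  # dV/dr along the bond, applied to bead i+1
        forces[i + 1, 0] += f * dx
        forces[i + 1, 1] += f * dy
        forces[i + 1, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz

    # virtual-bond angles (vertex at j)
    for j in range(1, n - 1):
        ux = coords[j - 1, 0] - coords[j, 0]
        uy = coords[j - 1, 1] - coords[j, 1]
        uz = coords[j - 1, 2] - coords[j, 2]
        vx = coords[j + 1, 0] - coords[j, 0]
        vy = coords[j + 1, 1] - coords[j, 1]
        vz = coords[j + 1, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0 - 1e-12:
            ct = 1.0 - 1e-12
        if ct < -1.0 + 1e-12:
            ct = -1.0 + 1e-12
        theta = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        dtheta_deg = theta * _DEG - theta0_deg
        e_angle += 0.5 * k_theta * dtheta_deg * dtheta_deg
        # dV/dtheta in rad^-1
        dv = k_theta * dtheta_deg * _DEG
        # dtheta/dri = (ct*uhat - vhat)/(nu*st); dtheta/drk = (ct*vhat - uhat)/(nv*st)
        gix = (ct * ux / nu - vx / nv) / (nu * st)
        giy = (ct * uy / nu - vy / nv) / (nu * st)
        giz = (ct * uz / nu - vz / nv) / (nu * st)
        gkx = (ct * vx / nv - ux / nu) / (nv * st)
        gky = (ct * vy / nv - uy / nu) / (nv * st)
        gkz = (ct * vz / nv - uz / nu) / (nv * st)
        forces[j - 1, 0] -= dv * gix
        forces[j - 1, 1] -= dv * giy
        forces[j - 1, 2] -= dv * giz
        forces[j + 1, 0] -= dv * gkx
        forces[j + 1, 1] -= dv * gky
        forces[j + 1, 2] -= dv * gkz
        forces[j, 0] += dv * (gix + gkx)
        forces[j, 1] += dv * (giy + gky)
        forces[j, 2] += dv * (giz + gkz)

    # torsions about bond (j, j+1), beads j-1..j+2
    for j in range(1, n - 2):
        b1x = coords[j, 0] - coords[j - 1, 0]
        b1y = coords[j, 1] - coords[j - 1, 1]
        b1z = coords[j, 2] - coords[j - 1, 2]
        b2x = coords[j + 1, 0] - coords[j, 0]
        b2y = coords[j + 1, 1] - coords[j, 1]
        b2z = coords[j + 1, 2] - coords[j, 2]
        b3x = coords[j + 2, 0] - coords[j + 1, 0]
        b3y = coords[j + 2, 1] - coords[j + 1, 1]
        b3z = coords[j + 2, 2] - coords[j + 1, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-18 or n2sq < 1e-18:
            continue  # collinear triple: torsion undefined, zero contribution
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = b2n * (b1x * n2x + b1y * n2y + b1z * n2z)
        gamma = np.arctan2(y, x)
        e_dih += c1 * (1.0 + np.cos(gamma)) + c3 * (1.0 + np.cos(3.0 * gamma)) \
            + c1s * np.sin(gamma)
        dv = -c1 * np.sin(gamma) - 3.0 * c3 * np.sin(3.0 * gamma) \
            + c1s * np.cos(gamma)
        # standard torsion gradient
        g1x = -b2n / n1sq * n1x
        g1y = -b2n / n1sq * n1y
        g1z = -b2n / n1sq * n1z
        g4x = b2n / n2sq * n2x
        g4y = b2n / n2sq * n2y
        g4z = b2n / n2sq * n2z
        d12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        d32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        g2x = -g1x - d12 * g1x + d32 * g4x
        g2y = -g1y - d12 * g1y + d32 * g4y
        g2z = -g1z - d12 * g1z + d32 * g4z
        g3x = -g4x + d12 * g1x - d32 * g4x
        g3y = -g4y + d12 * g1y - d32 * g4y
        g3z = -g4z + d12 * g1z - d32 * g4z
        forces[j - 1, 0] -= dv * g1x
        forces[j - 1, 1] -= dv * g1y
        forces[j - 1, 2] -= dv * g1z
        forces[j, 0] -= dv * g2x
        forces[j, 1] -= dv * g2y
        forces[j, 2] -= dv * g2z
        forces[j + 1, 0] -= dv * g3x
        forces[j + 1, 1] -= dv * g3y
        forces[j + 1, 2] -= dv * g3z
        forces[j + 2, 0] -= dv * g4x
        forces[j + 2, 1] -= dv * g4y
        forces[j + 2, 2] -= dv * g4z

    # purely repulsive excluded volume, zero at and beyond r = sigma_ev
    if eps_ev > 0.0:
        sig2 = sigma_ev * sigma_ev
        for i in range(n):
            for j in range(i + ev_min_sep, n):
                dx = coords[j, 0] - coords[i, 0]
                dy = coords[j, 1] - coords[i, 1]
                dz = coords[j, 2] - coords[i, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= sig2:
                    continue
                s2 = sig2 / r2
                s6 = s2 * s2 * s2
                e_ev += eps_ev * (s6 * s6 - 2.0 * s6 + 1.0)
                # dV/dr = -12 eps/r (s12 - s6); force on j along +d for repulsion
                fr = 12.0 * eps_ev * (s6 * s6 - s6) / r2
                forces[j, 0] += fr * dx
                forces[j, 1] += fr * dy
                forces[j, 2] += fr * dz
                forces[i, 0] -= fr * dx
                forces[i, 1] -= fr * dy
                forces[i, 2] -= fr * dz

    return e_bond, e_angle, e_dih, e_ev, forces
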