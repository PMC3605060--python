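"""Numba-compiled hot loops for the force field and collective coordinate.

Each kernel mirrors a vectorised numpy implementation in
:mod:`knotfold.cg_forcefield` / :mod:`knotfold.contact_maps`; the test suite
asserts agreement between the two routes.  Import of this module must never
fail the package: ``HAVE_NUMBA`` gates usage.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def ff_energy_force(x, bond_r0, angle_t0, dihedral_p0,
                    native_pairs, native_sigma, nonnative_pairs,
                    qc_eps, charge_product,
                    k_bond, k_angle, kd1, kd3, native_eps,
                    ev_sigma, ev_eps, ev_cap,
                    qc_range, qc_width, debye_length, coulomb_prefactor):
    """Total force (N,3) and energy components (bonded, native, qc, el, ev)."""
    n = x.shape[0]
    f = np.zeros((n, 3))
    e_bond = 0.0
    for i in range(n - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        dz = x[i + 1, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[i]
        e_bond += k_bond * dr * dr
        g = 2.0 * k_bond * dr / r
        f[i + 1, 0] -= g * dx
        f[i + 1, 1] -= g * dy
        f[i + 1, 2] -= g * dz
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz

    for i in range(n - 2):
        ux = x[i, 0] - x[i + 1, 0]
        uy = x[i, 1] - x[i + 1, 1]
        uz = x[i, 2] - x[i + 1, 2]
        vx = x[i + 2, 0] - x[i + 1, 0]
        vy = x[i + 2, 1] - x[i + 1, 1]
        vz = x[i + 2, 2] - x[i + 1, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(max(1.0 - c * c, 1e-12))
        dtheta = theta - angle_t0[i]
        e_bond += k_angle * dtheta * dtheta
        dE = 2.0 * k_angle * dtheta
        pref = -dE / s
        gux = pref * (vx / (nu * nv) - c * ux / (nu * nu))
        guy = pref * (vy / (nu * nv) - c * uy / (nu * nu))
        guz = pref * (vz / (nu * nv) - c * uz / (nu * nu))
        gvx = pref * (ux / (nu * nv) - c * vx / (nv * nv))
        gvy = pref * (uy / (nu * nv) - c * vy / (nv * nv))
        gvz = pref * (uz / (nu * nv) - c * vz / (nv * nv))
        f[i, 0] -= gux
        f[i, 1] -= guy
        f[i, 2] -= guz
        f[i + 1, 0] += gux + gvx
        f[i + 1, 1] += guy + gvy
        f[i + 1, 2] += guz + gvz
        f[i + 2, 0] -= gvx
        f[i + 2, 1] -= gvy
        f[i + 2, 2] -= gvz

    for i in range(n - 3):
        b1x = x[i + 1, 0] - x[i, 0]
        b1y = x[i + 1, 1] - x[i, 1]
        b1z = x[i + 1, 2] - x[i, 2]
        b2x = x[i + 2, 0] - x[i + 1, 0]
        b2y = x[i + 2, 1] - x[i + 1, 1]
        b2z = x[i + 2, 2] - x[i + 1, 2]
        b3x = x[i + 3, 0] - x[i + 2, 0]
        b3y = x[i + 3, 1] - x[i + 2, 1]
        b3z = x[i + 3, 2] - x[i + 2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        m1x = (n1y * b2z - n1z * b2y) / nb2
        m1y = (n1z * b2x - n1x * b2z) / nb2
        m1z = (n1x * b2y - n1y * b2x) / nb2
        yy = m1x * n2x + m1y * n2y + m1z * n2z
        xx = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(yy, xx)
        dphi = phi - dihedral_p0[i]
        e_bond += kd1 * (1.0 - np.cos(dphi)) + kd3 * (1.0 - np.cos(3.0 * dphi))
        dE = kd1 * np.sin(dphi) + 3.0 * kd3 * np.sin(3.0 * dphi)
        n1sq = max(n1x * n1x + n1y * n1y + n1z * n1z, 1e-2)
        n2sq = max(n2x * n2x + n2y * n2y + n2z * n2z, 1e-2)
        a1 = nb2 / n1sq
        a4 = nb2 / n2sq
        d1x, d1y, d1z = a1 * n1x, a1 * n1y, a1 * n1z
        d4x, d4y, d4z = -a4 * n2x, -a4 * n2y, -a4 * n2z
        c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        d2x = -(1.0 + c12) * d1x + c32 * d4x
        d2y = -(1.0 + c12) * d1y + c32 * d4y
        d2z = -(1.0 + c12) * d1z + c32 * d4z
        d3x = c12 * d1x - (1.0 + c32) * d4x
        d3y = c12 * d1y - (1.0 + c32) * d4y
        d3z = c12 * d1z - (1.0 + c32) * d4z
        f[i, 0] -= dE * d1x
        f[i, 1] -= dE * d1y
        f[i, 2] -= dE * d1z
        f[i + 1, 0] -= dE * d2x
        f[i + 1, 1] -= dE * d2y
        f[i + 1, 2] -= dE * d2z
        f[i + 2, 0] -= dE * d3x
        f[i + 2, 1] -= dE * d3y
        f[i + 2, 2] -= dE * d3z
        f[i + 3, 0] -= dE * d4x
        f[i + 3, 1] -= dE * d4y
        f[i + 3, 2] -= dE * d4z

    e_native = 0.0
    for k in range(native_pairs.shape[0]):
        i = native_pairs[k, 0]
        j = native_pairs[k, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        r_lin = 0.8 * native_sigma[k]
        rc = r if r > r_lin else r_lin
        s = native_sigma[k] / rc
        s10 = s ** 10
        s12 = s10 * s * s
        v = native_eps * (5.0 * s12 - 6.0 * s10)
        dv = native_eps * (-60.0 * s12 + 60.0 * s10) / rc
        if r < r_lin:
            v += dv * (r - r_lin)
        e_native += v
        g = dv / r
        f[i, 0] -= g * dx
        f[i, 1] -= g * dy
        f[i, 2] -= g * dz
        f[j, 0] += g * dx
        f[j, 1] += g * dy
        f[j, 2] += g * dz

    e_qc = 0.0
    e_el = 0.0
    e_ev = 0.0
    r_cap = ev_sigma * (ev_eps / ev_cap) ** (1.0 / 12.0) if ev_eps > 0 else 0.0
    slope = -12.0 * ev_cap / r_cap if ev_eps > 0 else 0.0
    for k in range(nonnative_pairs.shape[0]):
        i = nonnative_pairs[k, 0]
        j = nonnative_pairs[k, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dv = 0.0
        if ev_eps > 0.0:
            if r < r_cap:
                e_ev += ev_cap + slope * (r - r_cap)
                dv += slope
            else:
                v = ev_eps * (ev_sigma / r) ** 12
                e_ev += v
                dv += -12.0 * v / r
        if qc_eps[k] != 0.0:
            sig = 1.0 / (1.0 + np.exp((r - qc_range) / qc_width))
            e_qc += qc_eps[k] * sig
            dv += qc_eps[k] * (-sig * (1.0 - sig) / qc_width)
        if charge_product[k] != 0.0:
            v = coulomb_prefactor * charge_product[k] * np.exp(
                -r / debye_length) / r
            e_el += v
            dv += -v * (1.0 / r + 1.0 / debye_length)
        if dv != 0.0:
            g = dv / r
            f[i, 0] -= g * dx
            f[i, 1] -= g * dy
            f[i, 2] -= g * dz
            f[j, 0] += g * dx
            f[j, 1] += g * dy
            f[j, 2] += g * dz

    return f, e_bond, e_native, e_qc, e_el, e_ev


@njit(cache=True, fastmath=False)
def cc_value_grad(x, pairs, c_native, r0, g_exp, mp, mq):
    """Collective coordinate and gradient over a fixed pair support.

    The contact function is the factored rational form
    P(u^g)/Q(u^g), P = 1 + .. + x^(mp-1), Q = 1 + .. + x^(mq-1), u = r/r0.
    """
    n = x.shape[0]
    grad = np.zeros((n, 3))
    z = 0.0
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u = r / r0
        xg = u ** g_exp
        P = 0.0
        Q = 0.0
        t = 1.0
        for m in range(mq):
            if m < mp:
                P += t
            Q += t
            t *= xg
        dP = 0.0
        dQ = 0.0
        t = 1.0  # xg^(m-1)
        for m in range(1, mq):
            if m < mp:
                dP += m * t
            dQ += m * t
            t *= xg
        C = P / Q
        dC_dx = (dP * Q - P * dQ) / (Q * Q)
        dC_dr = dC_dx * g_exp * u ** (g_exp - 1) / r0
        diff = C - c_native[k]
        z += diff * diff
        w = 2.0 * diff * dC_dr / r
        grad[i, 0] += w * dx
        grad[i, 1] += w * dy
        grad[i, 2] += w * dz
        grad[j, 0] -= w * dx
        grad[j, 1] -= w * dy
        grad[j, 2] -= w * dz
    return z, grad
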