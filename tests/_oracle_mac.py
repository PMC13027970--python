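"""Independent staggered-grid (MAC) Stokes oracle.

A deliberately separate discretisation of the same physical problem:
cell-centred pressure, face-centred velocities, half-cell no-slip ghosts.
It shares no code with the package solver and serves as the independent
cross-check for the collocated scheme on coarse fixtures.  Slow (Python
loops) — use only on small grids.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from poreflow.geometry import DomainSpec


def mac_solve(
    spec: DomainSpec,
    mu: float = 3e-4,
    rho: float = 1000.0,
    u_mean: float = 1.0,
    sealed: bool = False,
):
    """Solve steady Stokes on the cell-based MAC grid; returns (u, v, p, fluid).

    u has shape (Nyc, Nxc+1) on vertical faces, v is (Nyc+1, Nxc) on
    horizontal faces, p is (Nyc, Nxc) at cell centres.
    """
    dx = spec.dx_m
    Nxc = spec.length_steps
    hlo, hm = spec.h_lower_steps, spec.h_membrane_steps
    Nyc = spec.height_steps
    fluid = np.ones((Nyc, Nxc), bool)
    i = np.arange(Nxc)
    wallcol = (i % spec.pitch_steps) < spec.wall_steps
    band = slice(hlo, hlo + hm)
    if sealed:
        fluid[band, :] = False
    else:
        fluid[band, wallcol] = False
    nu = mu / rho

    nu_faces = Nyc * (Nxc + 1)
    nv_faces = (Nyc + 1) * Nxc

    def uid(j, i):
        return j * (Nxc + 1) + i

    def vid(j, i):
        return nu_faces + j * Nxc + i

    def pid(j, i):
        return nu_faces + nv_faces + j * Nxc + i

    ntot = nu_faces + nv_faces + Nyc * Nxc
    rows, cols, vals = [], [], []
    b = np.zeros(ntot)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    lower = np.zeros(Nyc, bool)
    lower[:hlo] = True
    upper = np.zeros(Nyc, bool)
    upper[hlo + hm :] = True

    u_dir = {}
    for j in range(Nyc):
        if lower[j]:
            yc, h = (j + 0.5) * dx, hlo * dx
            u_dir[(j, 0)] = 6 * u_mean * (yc / h) * (1 - yc / h)
        if upper[j]:
            yc, h = (j - (hlo + hm) + 0.5) * dx, (Nyc - hlo - hm) * dx
            u_dir[(j, Nxc)] = -6 * u_mean * (yc / h) * (1 - yc / h)

    def ucells(j, i):
        left = fluid[j, i - 1] if i - 1 >= 0 else None
        right = fluid[j, i] if i < Nxc else None
        return left, right

    # u-momentum
    for j in range(Nyc):
        for i in range(Nxc + 1):
            r = uid(j, i)
            if (j, i) in u_dir:
                add(r, r, 1.0)
                b[r] = u_dir[(j, i)]
                continue
            left, right = ucells(j, i)
            if i == 0 or i == Nxc:
                adj = right if i == 0 else left
                if adj:  # outlet: du/dx = 0
                    i2 = 1 if i == 0 else Nxc - 1
                    add(r, r, 1.0)
                    add(r, uid(j, i2), -1.0)
                else:
                    add(r, r, 1.0)
                continue
            if not (left and right):
                add(r, r, 1.0)
                continue
            diag = 4.0
            for jj, ii in ((j, i - 1), (j, i + 1)):
                if (jj, ii) in u_dir:
                    b[r] += nu / dx**2 * u_dir[(jj, ii)]
                elif ii == 0 or ii == Nxc:
                    add(r, uid(jj, ii), -nu / dx**2)
                else:
                    ll, rr = ucells(jj, ii)
                    if ll and rr:
                        add(r, uid(jj, ii), -nu / dx**2)
                    # else: solid face carries zero
            for jj, ii in ((j - 1, i), (j + 1, i)):
                handled = False
                if 0 <= jj < Nyc:
                    if (jj, ii) in u_dir:
                        b[r] += nu / dx**2 * u_dir[(jj, ii)]
                        handled = True
                    else:
                        ll, rr = ucells(jj, ii)
                        if ll and rr:
                            add(r, uid(jj, ii), -nu / dx**2)
                            handled = True
                if not handled:
                    diag += 1.0  # wall half a cell away: ghost = -centre
            add(r, r, diag * nu / dx**2)
            add(r, pid(j, i), 1.0 / (rho * dx))
            add(r, pid(j, i - 1), -1.0 / (rho * dx))

    def vcells(j, i):
        below = fluid[j - 1, i] if j - 1 >= 0 else None
        above = fluid[j, i] if j < Nyc else None
        return below, above

    # v-momentum
    for j in range(Nyc + 1):
        for i in range(Nxc):
            r = vid(j, i)
            below, above = vcells(j, i)
            if j == 0 or j == Nyc or not (below and above):
                add(r, r, 1.0)
                continue
            diag = 4.0
            for jj, ii in ((j - 1, i), (j + 1, i)):
                bb, tt = vcells(jj, ii)
                if 0 < jj < Nyc and bb and tt:
                    add(r, vid(jj, ii), -nu / dx**2)
            for jj, ii in ((j, i - 1), (j, i + 1)):
                if 0 <= ii < Nxc:
                    bb, tt = vcells(jj, ii)
                    if bb and tt:
                        add(r, vid(jj, ii), -nu / dx**2)
                    else:
                        diag += 1.0
                else:
                    # domain edge: inlet (v = 0, ghost = -v) or outlet (dv/dx = 0)
                    is_lower = j <= hlo
                    inlet_side = is_lower if ii < 0 else not is_lower
                    diag += 1.0 if inlet_side else -1.0
            add(r, r, diag * nu / dx**2)
            add(r, pid(j, i), 1.0 / (rho * dx))
            add(r, pid(j - 1, i), -1.0 / (rho * dx))

    # continuity per fluid cell
    for j in range(Nyc):
        for i in range(Nxc):
            r = pid(j, i)
            if not fluid[j, i]:
                add(r, r, 1.0)
                continue
            add(r, uid(j, i + 1), 1.0 / dx)
            add(r, uid(j, i), -1.0 / dx)
            add(r, vid(j + 1, i), 1.0 / dx)
            add(r, vid(j, i), -1.0 / dx)

    system = sp.csr_matrix((vals, (rows, cols)), shape=(ntot, ntot)).tolil()
    # pin pressure at the outlet-adjacent cell of each channel
    for jsel, isel in ((0, Nxc - 1), (Nyc - 1, 0)):
        r = pid(jsel, isel)
        system.rows[r] = [pid(jsel, isel)]
        system.data[r] = [1.0]
        b[r] = 0.0

    x = spsolve(system.tocsc(), b)
    u = x[:nu_faces].reshape(Nyc, Nxc + 1)
    v = x[nu_faces : nu_faces + nv_faces].reshape(Nyc + 1, Nxc)
    p = x[nu_faces + nv_faces :].reshape(Nyc, Nxc)
    return u, v, p, fluid


def mac_inlet_pressure(spec: DomainSpec, p: np.ndarray) -> float:
    """Max inlet pressure of the lower channel, extrapolated to x = 0.

    The MAC pressure is pinned at the outlet-adjacent cell centre
    (x = L - dx/2) rather than at x = L, so the extrapolated inlet value is
    rescaled by L / (L - dx/2) to the zero-at-outlet reference.
    """
    hlo = spec.h_lower_steps
    col = 1.5 * p[:hlo, 0] - 0.5 * p[:hlo, 1]
    scale = spec.length_m / (spec.length_m - spec.dx_m / 2.0)
    return float(col.max()) * scale
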