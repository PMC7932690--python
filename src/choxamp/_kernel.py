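"""Numba kernel for the explicit finite-difference update of the coating PDE.

The radial grid spans [re, re + R] with spacing dr; Ch, O2 and H2O2 diffuse
(spherical Laplacian in conservative half-node flux form), the six enzyme
states react in place.  Boundary conditions per time step:

* outer node: Dirichlet at bulk for Ch and O2, H2O2 = 0 (washed away),
* inner node (electrode): zero flux for Ch and O2 (ghost-node reflection),
  H2O2 = 0 (instantly oxidised).

All concentrations in uM, lengths in um, time in s.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def advance(ch, o2, h2, enz, rp2, rm2, inv_r2dr2, dt, n_sub,
            d_ch, d_o2, d_h2,
            kf, kr, k1, k2, k3, k4, k5,
            ch_bulk, o2_bulk, neg_tol):  # pragma: no cover - jit
    """Advance the state by ``n_sub`` explicit Euler steps (in place).

    Returns 0 on success, 1 if any concentration dropped below -neg_tol
    (unusable numerics).  ``rp2``/``rm2`` are the squared half-node radii
    r_{i+1/2}^2 and r_{i-1/2}^2, ``inv_r2dr2`` is 1/(r_i^2 dr^2).
    """
    n = ch.shape[0]
    dch = np.empty(n)
    do2 = np.empty(n)
    dh2 = np.empty(n)
    den = np.empty((6, n))

    ch[n - 1] = ch_bulk
    o2[n - 1] = o2_bulk
    h2[0] = 0.0
    h2[n - 1] = 0.0

    for _ in range(n_sub):
        for i in range(n):
            e = enz[0, i]
            ech = enz[1, i]
            erba = enz[2, i]
            eoba = enz[3, i]
            ergb = enz[4, i]
            eogb = enz[5, i]
            c = ch[i]
            o = o2[i]

            bind = kf * e * c
            unbind = kr * ech
            r1 = k1 * ech
            r2 = k2 * erba * o
            r3 = k3 * eoba
            r4 = k4 * ergb * o
            r5 = k5 * eogb

            den[0, i] = -bind + unbind + r5
            den[1, i] = bind - unbind - r1
            den[2, i] = r1 - r2
            den[3, i] = r2 - r3
            den[4, i] = r3 - r4
            den[5, i] = r4 - r5

            if i == 0:
                lch = rp2[0] * (ch[1] - c) * inv_r2dr2[0]
                lo2 = rp2[0] * (o2[1] - o) * inv_r2dr2[0]
                lh2 = 0.0
            elif i == n - 1:
                lch = 0.0
                lo2 = 0.0
                lh2 = 0.0
            else:
                lch = (rp2[i] * (ch[i + 1] - c) - rm2[i] * (c - ch[i - 1])) * inv_r2dr2[i]
                lo2 = (rp2[i] * (o2[i + 1] - o) - rm2[i] * (o - o2[i - 1])) * inv_r2dr2[i]
                lh2 = (rp2[i] * (h2[i + 1] - h2[i]) - rm2[i] * (h2[i] - h2[i - 1])) * inv_r2dr2[i]

            dch[i] = d_ch * lch - bind + unbind
            do2[i] = d_o2 * lo2 - r2 - r4
            dh2[i] = d_h2 * lh2 + r2 + r4

        for i in range(n):
            ch[i] += dt * dch[i]
            o2[i] += dt * do2[i]
            h2[i] += dt * dh2[i]
            for j in range(6):
                enz[j, i] += dt * den[j, i]

        ch[n - 1] = ch_bulk
        o2[n - 1] = o2_bulk
        h2[0] = 0.0
        h2[n - 1] = 0.0

        for i in range(n):
            if ch[i] < -neg_tol or o2[i] < -neg_tol or h2[i] < -neg_tol:
                return 1
            for j in range(6):
                if enz[j, i] < -neg_tol:
                    return 1
    return 0
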