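"""Numba-jitted inner loops for the video descriptor.

The Horn-Schunck Jacobi sweep and the shrunken-window median dominate the
pipeline runtime; both have straightforward numpy counterparts in
:mod:`harkit.optflow` that the tests cross-check against these kernels.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def hs_jacobi(ex, ey, et, alpha2, n_iter):  # pragma: no cover - exercised via optflow
    h, w = ex.shape
    u = np.zeros((h, w))
    v = np.zeros((h, w))
    un = np.zeros((h, w))
    vn = np.zeros((h, w))
    for _ in range(n_iter):
        for i in range(h):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < h - 1 else h - 1
            for j in range(w):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < w - 1 else w - 1
                ub = ((u[im, j] + u[ip, j] + u[i, jm] + u[i, jp]) / 6.0
                      + (u[im, jm] + u[im, jp] + u[ip, jm] + u[ip, jp]) / 12.0)
                vb = ((v[im, j] + v[ip, j] + v[i, jm] + v[i, jp]) / 6.0
                      + (v[im, jm] + v[im, jp] + v[ip, jm] + v[ip, jp]) / 12.0)
                exv = ex[i, j]
                eyv = ey[i, j]
                t = (exv * ub + eyv * vb + et[i, j]) / (alpha2 + exv * exv + eyv * eyv)
                un[i, j] = ub - exv * t
                vn[i, j] = vb - eyv * t
        u, un = un, u
        v, vn = vn, v
    return u, v


@njit(cache=False)
def median_shrink(a, size):  # pragma: no cover - exercised via optflow
    h, w = a.shape
    r = size // 2
    out = np.empty_like(a)
    buf = np.empty(size * size)
    for i in range(h):
        i0 = i - r if i - r > 0 else 0
        i1 = i + r + 1 if i + r + 1 < h else h
        for j in range(w):
            j0 = j - r if j - r > 0 else 0
            j1 = j + r + 1 if j + r + 1 < w else w
            n = 0
            for di in range(i0, i1):
                for dj in range(j0, j1):
                    buf[n] = a[di, dj]
                    n += 1
            for p in range(1, n):
                key = buf[p]
                q = p - 1
                while q >= 0 and buf[q] > key:
                    buf[q + 1] = buf[q]
                    q -= 1
                buf[q + 1] = key
            if n % 2 == 1:
                out[i, j] = buf[n // 2]
            else:
                out[i, j] = 0.5 * (buf[n // 2 - 1] + buf[n // 2])
    return out
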