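"""Numba kernels for axon-map percept rendering and batched model evaluation.

The axon-map intensity at a pixel is a *max* over candidate points ``j`` on
the pixel's axon path of ``exp(-(g2_j * u + s2_j * v))`` with
``u = 1/(2 rho^2)``, ``v = 1/(2 lambda^2)``, ``g2_j`` the squared distance
from path point ``j`` to the electrode and ``s2_j`` the squared arclength
from the soma to ``j``.  Equivalently the *exponent* is a minimum of linear
functions of ``(u, v)``, so for each pixel only the lower-left convex hull
of the ``(g2, s2)`` candidate set can ever attain the minimum.  These hulls
("fronts") are independent of ``rho`` and ``lambda``: they are prebuilt once
per electrode and make parameter sweeps (particle swarms) cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def build_fronts(vidx, bundle_of, ptr, pts, arclen, ex, ey, offsets, g2f, s2f, counts):
    """Per-pixel lower convex hulls of (electrode-dist², soma-arclength²).

    For pixel ``p`` with nearest bundle vertex ``k = vidx[p]``, candidates
    are the disc-ward vertices ``j >= k`` of that bundle.  Candidates are
    first reduced to running minima of ``g2`` (the Pareto set, since the
    arclength ``s2`` increases with ``j``), then to their lower convex hull.
    Results are written into flat arrays at ``offsets[p]``; ``counts[p]``
    receives the hull size.
    """
    n_pix = vidx.size
    for p in range(n_pix):
        k = vidx[p]
        b = bundle_of[k]
        end = ptr[b + 1]
        base = offsets[p]
        lk = arclen[k]
        m = 0
        gmin = np.inf
        for j in range(k, end):
            dx = pts[j, 0] - ex
            dy = pts[j, 1] - ey
            g2 = dx * dx + dy * dy
            if g2 >= gmin:
                continue
            gmin = g2
            dl = lk - arclen[j]
            s2 = dl * dl
            while m >= 2:
                sa = s2f[base + m - 2]
                ga = g2f[base + m - 2]
                sb = s2f[base + m - 1]
                gb = g2f[base + m - 1]
                # pop b when it lies on/above the chord a-c (not convex)
                if (sb - sa) * (g2 - ga) - (gb - ga) * (s2 - sa) <= 0.0:
                    m -= 1
                else:
                    break
            g2f[base + m] = g2
            s2f[base + m] = s2
            m += 1
        counts[p] = m


@njit(cache=True)
def min_exponent(fptr, fg2, fs2, u, v, out):
    """Per-pixel minimum of ``g2 * u + s2 * v`` over the pixel's front."""
    n_pix = fptr.size - 1
    for p in range(n_pix):
        best = np.inf
        for q in range(fptr[p], fptr[p + 1]):
            e = fg2[q] * u + fs2[q] * v
            if e < best:
                best = e
        out[p] = best


@njit(cache=True)
def batched_moments(fptr, fg2, fs2, us, vs, log_inv_thresh, ix, iy, scratch, out):
    """Binary-percept raw moments for a batch of (rho, lambda) particles.

    For each particle the intensity image is normalized to peak 1 and
    thresholded; in exponent space a pixel is set iff its minimum exponent
    is within ``log(1/threshold)`` of the global minimum (no exp needed).
    ``out[i] = (m00, sum x, sum y, sum x², sum xy, sum y²)`` in pixel units.
    """
    n_pix = fptr.size - 1
    for i in range(us.size):
        u = us[i]
        v = vs[i]
        m0 = np.inf
        for p in range(n_pix):
            best = np.inf
            for q in range(fptr[p], fptr[p + 1]):
                e = fg2[q] * u + fs2[q] * v
                if e < best:
                    best = e
            scratch[p] = best
            if best < m0:
                m0 = best
        cut = m0 + log_inv_thresh
        c0 = 0.0
        sx = 0.0
        sy = 0.0
        sxx = 0.0
        sxy = 0.0
        syy = 0.0
        for p in range(n_pix):
            if scratch[p] <= cut:
                x = ix[p]
                y = iy[p]
                c0 += 1.0
                sx += x
                sy += y
                sxx += x * x
                sxy += x * y
                syy += y * y
        out[i, 0] = c0
        out[i, 1] = sx
        out[i, 2] = sy
        out[i, 3] = sxx
        out[i, 4] = sxy
        out[i, 5] = syy
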