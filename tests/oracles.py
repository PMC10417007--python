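"""Independent brute-force oracles used to validate the implementation.

These deliberately share no resampling/smoothing code with the package:
the tortuosity oracle works on dense analytic samples and applies the
index definition directly; the Fisher oracle enumerates the
hypergeometric distribution.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_vti(xf, yf, t0: float, t1: float, n_dense: int = 100_000,
                    spacing: float = 1.0) -> dict:
    """Direct evaluation of VTI = 0.1*M*N*SD_theta*(L_A/L_C).

    The curve ``(xf(t), yf(t))`` is sampled at ``n_dense`` parameter
    values; tangent angles are taken between points picked at ``spacing``
    arc-length intervals out of the dense sample (nearest dense sample to
    each target arc length), with no smoothing and no shared code.
    """
    t = np.linspace(t0, t1, n_dense)
    pts = np.column_stack([xf(t), yf(t)])
    p0 = pts[0]
    chord_vec = pts[-1] - p0
    clen = math.hypot(*chord_vec)
    c, s = chord_vec / clen
    rot = np.array([[c, s], [-s, c]])
    q = (pts - p0) @ rot.T
    seg = np.hypot(np.diff(q[:, 0]), np.diff(q[:, 1]))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    la, lc = float(arc[-1]), float(math.hypot(*(q[-1] - q[0])))

    n = int(round(la / spacing))
    targets = np.linspace(0.0, la, n + 1)
    idx = np.clip(np.searchsorted(arc, targets), 0, len(arc) - 1)
    sel = q[idx]

    d = np.diff(sel, axis=0)
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    sd = float(np.degrees(np.std(np.diff(theta))))

    dydx = np.gradient(sel[:, 1], sel[:, 0])
    signs = np.sign(dydx[1:-1])
    nz = signs[signs != 0]
    n_crit = int(np.sum(nz[:-1] * nz[1:] < 0))
    cross_idx = (np.flatnonzero(np.sign(dydx[1:-1])[:-1] * np.sign(dydx[1:-1])[1:] < 0) + 1).tolist()

    if n_crit == 0:
        m = la / lc
    else:
        bounds = [0, *cross_idx, len(sel) - 1]
        ratios = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            piece = sel[a : b + 1]
            if len(piece) < 2:
                continue
            parc = float(np.hypot(*np.diff(piece, axis=0).T).sum())
            pch = float(math.hypot(*(piece[-1] - piece[0])))
            if pch > 0:
                ratios.append(parc / pch)
        m = float(np.mean(ratios))
    return {
        "L_A": la,
        "L_C": lc,
        "N": n_crit,
        "SD_theta": sd,
        "M": m,
        "VTI": 0.1 * m * n_crit * sd * (la / lc),
    }


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(nn, kk):
        return math.lgamma(nn + 1) - math.lgamma(kk + 1) - math.lgamma(nn - kk + 1)

    def prob(x):
        return math.exp(
            log_comb(r1, x) + log_comb(r2, c1 - x) - log_comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
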