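"""Independent oracles used by the unit and acceptance suites.

The plane-fit oracle minimises the RMS orthogonal distance directly over
the normal's spherical angles (the offset is optimal in closed form for a
fixed normal), refined from several starts — no SVD anywhere, so it is an
independent check of the total-least-squares fit.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def _rms_for_normal(theta_phi, pts):
    t, p = theta_phi
    n = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
    d = pts @ n
    d = d - d.mean()  # optimal offset for a fixed normal
    return float(np.sqrt(np.mean(d * d)))


def brute_force_plane(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """(unit normal, RMS residual) minimising orthogonal distance.

    Coarse spherical grid followed by Nelder-Mead refinement from the
    best grid cells.
    """
    pts = np.asarray(pts, dtype=float)
    thetas = np.linspace(0.0, np.pi, 25)
    phis = np.linspace(0.0, 2 * np.pi, 49, endpoint=False)
    grid = [(t, p) for t in thetas for p in phis]
    vals = [_rms_for_normal(x, pts) for x in grid]
    starts = [grid[i] for i in np.argsort(vals)[:4]]
    best = None
    for x0 in starts:
        r = minimize(_rms_for_normal, x0, args=(pts,), method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 4000})
        if best is None or r.fun < best.fun:
            best = r
    t, p = best.x
    n = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
    return n, float(best.fun)
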