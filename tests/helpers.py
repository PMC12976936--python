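"""Independent numeric oracles shared by the test modules."""

import numpy as np


def fit_circle_radius(points_2d):
    """Kasa least-squares circle fit; returns the radius."""
    x, y = points_2d[:, 0], points_2d[:, 1]
    a = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    cx, cy, c = np.linalg.lstsq(a, b, rcond=None)[0]
    return np.sqrt(c + cx ** 2 + cy ** 2)


def brute_force_hausdorff(a_points, b_points):
    """All-pairs directed/symmetric Hausdorff and mean distances."""
    d = np.linalg.norm(a_points[:, None, :] - b_points[None, :, :], axis=2)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    return {
        "hausdorff": max(d_ab.max(), d_ba.max()),
        "mean": 0.5 * (d_ab.mean() + d_ba.mean()),
        "directed_max_ab": d_ab.max(),
        "directed_max_ba": d_ba.max(),
    }


def brute_force_pairing(graft_pts, native_pts):
    """Minimal-total-angle cyclic pairing by exhaustive search.

    Returns (cost, offset, orientation) over all cyclic offsets and both
    winding orientations, matching loop-centroid direction vectors.
    """
    def dirs(p):
        d = p - p.mean(axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    gd, nd = dirs(graft_pts), dirs(native_pts)
    best = None
    k = len(gd)
    for orientation in (1, -1):
        nn = nd if orientation == 1 else nd[::-1]
        for off in range(k):
            rolled = np.roll(nn, -off, axis=0)
            cost = np.arccos(np.clip((gd * rolled).sum(axis=1),
                                     -1.0, 1.0)).sum()
            if best is None or cost < best[0] - 1e-12:
                best = (cost, off, orientation)
    return best
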