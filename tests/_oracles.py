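"""Independent reference implementations used only to cross-check the
package (kept deliberately naive)."""

import numpy as np


def python_mean(values) -> float:
    """Mean by explicit Python accumulation (independent of numpy.mean)."""
    total = 0.0
    count = 0
    for v in np.asarray(values).ravel().tolist():
        total += v
        count += 1
    return total / count


def pairwise_max_distance(points) -> float:
    """O(n^2) max pairwise distance via explicit loops."""
    pts = np.asarray(points, dtype=float)
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = float(np.sqrt(((pts[i] - pts[j]) ** 2).sum()))
            best = max(best, d)
    return best


def angular_scan_min_width(points, axis, step_deg=1.0) -> float:
    """Minimum directional width orthogonal to ``axis`` by brute-force
    angular scan (Gram-Schmidt basis, ``step_deg`` grid).  Overestimates the
    true minimum by at most the grid resolution effect."""
    pts = np.asarray(points, dtype=float)
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    v0 = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = v0 - (v0 @ a) * a
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    p2 = np.stack([pts @ u, pts @ v], axis=1)
    theta = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    proj = p2 @ dirs.T
    return float((proj.max(axis=0) - proj.min(axis=0)).min())
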