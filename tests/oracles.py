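"""Independent closed-form oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: Horn's
quaternion eigenvector method vs. Kabsch SVD, the midpoint of the common
perpendicular vs. linear least squares triangulation, and the analytic
Butterworth magnitude response vs. the filtered signal.
"""

from __future__ import annotations

import numpy as np


def horn_fit(source: np.ndarray, target: np.ndarray):
    """Horn (1987) closed-form absolute orientation via the quaternion
    eigenvector of the 4x4 cross-covariance matrix."""
    a = np.asarray(source, float)
    b = np.asarray(target, float)
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    m = ca.T @ cb
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(n)
    q = v[:, -1]  # eigenvector of the largest eigenvalue, (w, x, y, z)
    w0, x, y, z = q
    r = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w0), 2 * (x * z + y * w0)],
            [2 * (x * y + z * w0), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w0)],
            [2 * (x * z - y * w0), 2 * (y * z + x * w0), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = b.mean(axis=0) - r @ a.mean(axis=0)
    resid = a @ r.T + t - b
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return r, t, rms


def closest_point_between_rays(s1, d1, s2, d2):
    """Midpoint of the common perpendicular segment between two skew rays."""
    s1, d1, s2, d2 = (np.asarray(v, float) for v in (s1, d1, s2, d2))
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2)
    w0 = s1 - s2
    a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
    d, e = d1 @ w0, d2 @ w0
    denom = a * c - b * b
    t1 = (b * e - c * d) / denom
    t2 = (a * e - b * d) / denom
    p1 = s1 + t1 * d1
    p2 = s2 + t2 * d2
    return (p1 + p2) / 2.0


def butterworth_gain(f_hz, cutoff_hz, fs_hz=250.0, order=2, passes=2):
    """Analytic |H| of a digital (bilinear-transform) order-n Butterworth.

    The closed-form magnitude is 1 / sqrt(1 + (tan(pi f/fs)/tan(pi fc/fs))^2n)
    — the frequency-warped analog response — raised to the pass count, with
    the dual-pass cutoff correction applied when passes == 2.
    """
    fc = cutoff_hz
    if passes == 2:
        fc = cutoff_hz / (np.sqrt(2.0) - 1.0) ** 0.25
    ratio = np.tan(np.pi * f_hz / fs_hz) / np.tan(np.pi * fc / fs_hz)
    single = 1.0 / np.sqrt(1.0 + ratio ** (2 * order))
    return single**passes
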