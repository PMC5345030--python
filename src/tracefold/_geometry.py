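"""Idealized helix and arc geometry shared by the engine and the fixture builders.

The duplex template is a regular double helix whose constants are solved in closed
form so that consecutive intra-strand phosphates sit exactly ``BOND`` apart and
paired cross-strand phosphates sit exactly ``PAIR`` apart.  The engine refines
structures toward these same two ideals, so structures built from this template
are fixed points of the refinement terms.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

#: Ideal consecutive phosphate-phosphate virtual bond length (angstrom).
BOND = 6.0
#: Ideal paired cross-strand phosphate-phosphate separation (angstrom).
PAIR = 17.0
#: Helical rise per base pair (angstrom); steeper than A-form so that loop
#: take-offs clear the stem body at the 10 angstrom repulsion threshold.
RISE = 3.2
#: Helical twist per base pair (radians); 11 bp per turn.
TWIST = 2.0 * np.pi / 11.0

# Radius from the intra-strand bond constraint:
#   2 r^2 (1 - cos TWIST) + RISE^2 = BOND^2
RADIUS = float(np.sqrt((BOND**2 - RISE**2) / (2.0 * (1.0 - np.cos(TWIST)))))

# Cross-strand phase from the paired-distance constraint (same z level):
#   2 r^2 (1 - cos PHASE) = PAIR^2
PHASE = float(np.arccos(1.0 - PAIR**2 / (2.0 * RADIUS**2)))


def ideal_duplex(n_bp: int) -> np.ndarray:
    """Coordinates of an ideal ``n_bp`` duplex phosphate trace.

    Returns an ``(2 n_bp, 3)`` array.  Indices ``0 .. n_bp-1`` are the ascending
    (5' to 3') strand, indices ``n_bp .. 2 n_bp - 1`` the descending complementary
    strand; index ``t`` pairs with index ``2 n_bp - 1 - t`` at the same rise level.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    k = np.arange(n_bp)
    theta_a = k * TWIST
    theta_b = k * TWIST + PHASE
    z = k * RISE
    strand_a = np.column_stack(
        [RADIUS * np.cos(theta_a), RADIUS * np.sin(theta_a), z]
    )
    paired_b = np.column_stack(
        [RADIUS * np.cos(theta_b), RADIUS * np.sin(theta_b), z]
    )
    # paired_b[k] is the partner of strand_a[k]; as chain indices it sits at
    # 2 n_bp - 1 - k, i.e. strand B in ascending chain order is paired_b reversed.
    return np.vstack([strand_a, paired_b[::-1]])


def _hermite(
    p0: np.ndarray, m0: np.ndarray, p1: np.ndarray, m1: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Cubic Hermite curve samples at parameters ``t`` in [0, 1]."""
    t = t[:, None]
    h00 = 2 * t**3 - 3 * t**2 + 1
    h10 = t**3 - 2 * t**2 + t
    h01 = -2 * t**3 + 3 * t**2
    h11 = t**3 - t**2
    return h00 * p0 + h10 * m0 + h01 * p1 + h11 * m1


def _resample(samples: np.ndarray, n: int) -> np.ndarray:
    """``n`` interior points at equal arc length along a sampled curve."""
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = s[-1] * np.arange(1, n + 1) / (n + 1)
    out = np.empty((n, 3))
    for k, dim in enumerate(samples.T):
        out[:, k] = np.interp(targets, s, dim)
    return out


def _arc_length(p0, m0, p1, m1, dense: int = 400) -> float:
    t = np.linspace(0.0, 1.0, dense)
    pts = _hermite(p0, m0, p1, m1, t)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def hermite_points(
    p0: np.ndarray,
    t0: np.ndarray,
    p1: np.ndarray,
    t1: np.ndarray,
    n: int,
    spacing: float = BOND,
) -> np.ndarray:
    """``n`` interior points on a smooth curve from ``p0`` to ``p1``.

    The curve is a cubic Hermite spline whose start and end tangents point
    along ``t0`` and ``t1`` (chain directions), so the junction bond angles at
    both anchors stay wide.  The tangent magnitude is solved so the curve's
    arc length is ``spacing * (n + 1)``, then the interior points are placed
    at equal arc length, giving consecutive spacings close to ``spacing``.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t0 = t0 / np.linalg.norm(t0)
    t1 = t1 / np.linalg.norm(t1)
    chord = float(np.linalg.norm(p1 - p0))
    target = spacing * (n + 1)
    if target < chord:
        raise ValueError(
            f"cannot fit {n} points at {spacing} A spacing across a {chord:.1f} A gap"
        )
    lo, hi = 1e-3 * chord, 6.0 * chord

    def length_err(scale: float) -> float:
        return _arc_length(p0, scale * t0, p1, scale * t1) - target

    if length_err(lo) > 0.0:
        scale = lo  # even limp tangents overshoot; accept the slight stretch
    else:
        while length_err(hi) < 0.0 and hi < 60.0 * chord:
            hi *= 2.0
        scale = brentq(length_err, lo, hi)
    t = np.linspace(0.0, 1.0, 400)
    dense = _hermite(p0, scale * t0, p1, scale * t1, t)
    return _resample(dense, n)


def auto_points(chord: float, spacing: float = BOND) -> int:
    """Interior point count bridging ``chord`` at roughly ``spacing``."""
    return max(1, int(round(chord / spacing)))


def _arc_spacing(alpha: float, chord: float, n_points: int) -> float:
    """Chord step between consecutive points on an arc of angle ``alpha``."""
    return chord * np.sin(alpha / (2.0 * (n_points + 1))) / np.sin(alpha / 2.0)


def arc_points(
    a: np.ndarray,
    b: np.ndarray,
    n: int,
    bulge: np.ndarray,
    spacing: float = BOND,
) -> np.ndarray:
    """``n`` interior points on a circular arc from ``a`` to ``b``.

    The arc lies in the plane spanned by the chord and ``bulge`` and bows toward
    ``bulge``.  The arc angle is solved so consecutive points (anchors included)
    sit ``spacing`` apart; if the chord is already too long for that spacing the
    points fall back to a straight line.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    chord_vec = b - a
    chord = float(np.linalg.norm(chord_vec))
    if chord == 0.0:
        raise ValueError("arc anchors are coincident")
    if n < 1:
        return np.empty((0, 3))
    e_x = chord_vec / chord
    # orthogonalize the bulge direction against the chord
    e_y = np.asarray(bulge, dtype=float)
    e_y = e_y - np.dot(e_y, e_x) * e_x
    ny = np.linalg.norm(e_y)
    if ny < 1e-9:
        raise ValueError("bulge direction is parallel to the chord")
    e_y = e_y / ny

    if chord >= spacing * (n + 1) * (1.0 - 1e-9):
        # chord too long to bow: evenly spaced straight line
        t = np.arange(1, n + 1) / (n + 1)
        return a[None, :] + t[:, None] * chord_vec[None, :]

    alpha = brentq(
        lambda al: _arc_spacing(al, chord, n) - spacing, 1e-6, 2.0 * np.pi - 1e-6
    )
    radius = chord / (2.0 * np.sin(alpha / 2.0))
    mid = 0.5 * (a + b)
    centre = mid - radius * np.cos(alpha / 2.0) * e_y
    # anchors at angles pi/2 +- alpha/2 around the centre (local frame), the
    # arc apex at pi/2 pointing along e_y
    i = np.arange(1, n + 1)
    theta = np.pi / 2.0 + alpha / 2.0 - alpha * i / (n + 1)
    local_x = radius * np.cos(theta)
    local_y = radius * np.sin(theta)
    return centre[None, :] + local_x[:, None] * e_x[None, :] + local_y[:, None] * e_y[None, :]


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a (normalized) axis by ``angle`` radians."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )
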