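"""Vessel tortuosity index (VTI) for centerline segments.

The index combines a distance measure (arc/chord ratio) with curvature
measures along a vessel centerline:

    VTI = 0.1 * M * N * SD_theta * (L_A / L_C)

where ``L_A`` is the centerline arc length, ``L_C`` the chord length between
the segment endpoints, ``N`` the number of critical points at which the
first derivative of the chord-framed centerline vanishes, ``SD_theta`` the
standard deviation of the differences between consecutive tangent angles,
and ``M`` the mean arc/chord ratio of the pieces between consecutive
critical points.  The index is zero for an ideal straight vessel and grows
without bound as a vessel acquires more twists.

All geometry is computed in pixel units.  Angles are measured on a
centerline resampled to uniform arc-length spacing (default 1 px), so the
index is tied to the pixel grid of the source image; curves rendered at a
different resolution should be compared at a proportionally scaled
``spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TortuosityMetrics",
    "arc_chord",
    "chord_frame",
    "resample_polyline",
    "smooth_polyline",
    "critical_points",
    "tangent_angle_sd",
    "inter_inflection_ratio",
    "compute_vti",
    "image_mean_vti",
]


@dataclass(frozen=True)
class TortuosityMetrics:
    """Per-segment tortuosity measurements.

    Attributes
    ----------
    arc_length : float
        Centerline length ``L_A`` in pixels.
    chord_length : float
        Endpoint-to-endpoint distance ``L_C`` in pixels.
    n_critical : int
        ``N`` — number of interior critical points of the chord-framed
        centerline.
    sd_theta : float
        ``SD_theta`` — standard deviation of consecutive tangent-angle
        differences (degrees by default).
    mean_piece_ratio : float
        ``M`` — mean arc/chord ratio of inter-critical-point pieces.
    vti : float
        The tortuosity index ``0.1 * M * N * SD_theta * (L_A/L_C)``.
    n_points : int
        Number of resampled points the metrics were computed from.
    """

    arc_length: float
    chord_length: float
    n_critical: int
    sd_theta: float
    mean_piece_ratio: float
    vti: float
    n_points: int


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y) coordinates")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


def arc_chord(points) -> tuple[float, float]:
    """Arc length and chord length of a polyline.

    Returns ``(L_A, L_C)`` where ``L_A`` is the sum of consecutive
    Euclidean distances and ``L_C`` the distance from first to last point.

    Raises
    ------
    ValueError
        If fewer than two points are given or the endpoints coincide
        (a closed loop must be cut before measuring tortuosity).
    """
    pts = _as_points(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = float(steps.sum())
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord <= 1e-9 * max(arc, 1.0):
        raise ValueError(
            "segment endpoints coincide (closed loop); cut the loop before "
            "computing tortuosity"
        )
    return arc, chord


def chord_frame(points) -> np.ndarray:
    """Rigidly transform a polyline so its chord lies along +x.

    The first point maps to the origin and the last point to
    ``(L_C, 0)``.  The transform is an isometry; all tortuosity metrics
    are invariant under it.
    """
    pts = _as_points(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    origin = pts[0]
    chord_vec = pts[-1] - origin
    norm = np.linalg.norm(chord_vec)
    if norm == 0.0:
        raise ValueError("segment endpoints coincide; cannot define a chord frame")
    c, s = chord_vec / norm
    rot = np.array([[c, s], [-s, c]])
    return (pts - origin) @ rot.T


def resample_polyline(points, spacing: float = 1.0) -> np.ndarray:
    """Resample a polyline at (near-)uniform arc-length spacing.

    The endpoints are preserved exactly; the actual spacing is
    ``L_A / round(L_A / spacing)`` so that the samples divide the arc
    evenly.
    """
    pts = _as_points(points)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    total = s[-1]
    if total == 0.0:
        raise ValueError("polyline has zero length")
    n = max(int(round(total / spacing)), 1) + 1
    targets = np.linspace(0.0, total, n)
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return np.column_stack([x, y])


def smooth_polyline(points, window: int = 5) -> np.ndarray:
    """Centered moving-average smoothing with fixed endpoints.

    Near the ends the window shrinks symmetrically, so the first and last
    points are returned unchanged.  ``window=1`` is the identity.
    """
    pts = _as_points(points)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1 or len(pts) < 3:
        return pts.copy()
    half = window // 2
    n = len(pts)
    cum = np.concatenate([np.zeros((1, 2)), np.cumsum(pts, axis=0)])
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h
    return (cum[hi + 1] - cum[lo]) / (hi - lo + 1)[:, None]


def _merge_crossings(crossings: np.ndarray, min_separation: int) -> list[int]:
    """Merge runs of nearby sign changes, keeping crossing parity.

    Derivative jitter around a single zero produces clusters of sign
    changes; a cluster with an even count has no net crossing, an odd one
    has exactly one (placed at the cluster median, ties toward the lower
    index).
    """
    if len(crossings) == 0:
        return []
    merged: list[int] = []
    cluster = [int(crossings[0])]
    for c in crossings[1:]:
        if int(c) - cluster[-1] < min_separation:
            cluster.append(int(c))
        else:
            if len(cluster) % 2 == 1:
                merged.append(cluster[(len(cluster) - 1) // 2])
            cluster = [int(c)]
    if len(cluster) % 2 == 1:
        merged.append(cluster[(len(cluster) - 1) // 2])
    return merged


def critical_points(points, min_separation: int = 5) -> tuple[list[int], int]:
    """Locate critical points of a chord-framed centerline.

    The first derivative ``dy/dx`` is estimated by central finite
    differences; a critical point is a sign change of the derivative
    (the derivative vanishes between the two samples).  Endpoints are
    never counted.  When the projected ``x`` is not monotone (strongly
    convoluted segments) the sign changes of the signed curvature along
    arc length are used instead.

    Parameters
    ----------
    points : array-like
        Chord-framed, resampled (and typically smoothed) polyline.
    min_separation : int
        Sign changes closer than this many samples are treated as jitter
        around a single zero and merged by parity.

    Returns
    -------
    indices : list of int
        Sample index of each crossing (lower index of the bracketing pair).
    n : int
        ``N``, the number of critical points.
    """
    pts = _as_points(points)
    if len(pts) < 5:
        raise ValueError("need at least 5 points to locate critical points")
    x, y = pts[:, 0], pts[:, 1]
    dx = x[2:] - x[:-2]
    if np.all(dx > 0):
        deriv = (y[2:] - y[:-2]) / dx
    else:
        # curvature fallback for non-monotone projections
        d1 = np.gradient(pts, axis=0)
        d2 = np.gradient(d1, axis=0)
        deriv = (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])[1:-1]
    signs = np.sign(deriv)
    nz = np.flatnonzero(signs != 0)
    if len(nz) < 2:
        return [], 0
    sub = signs[nz]
    change = np.flatnonzero(sub[:-1] * sub[1:] < 0)
    # +1: deriv[i] straddles points i and i+2, attribute to center sample i+1
    crossings = nz[change] + 1
    merged = _merge_crossings(np.asarray(crossings), min_separation)
    return merged, len(merged)


def tangent_angle_sd(points, angle_unit: str = "deg") -> float:
    """Standard deviation of consecutive tangent-angle differences.

    Tangent angles ``theta_i = atan2(dy_i, dx_i)`` are taken between
    consecutive resampled points and unwrapped; the statistic is the
    population standard deviation of ``theta_{i+1} - theta_i``.

    Parameters
    ----------
    angle_unit : {"deg", "rad"}
        Unit in which the standard deviation is reported.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for tangent angles")
    if angle_unit not in ("deg", "rad"):
        raise ValueError("angle_unit must be 'deg' or 'rad'")
    d = np.diff(pts, axis=0)
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    dtheta = np.diff(theta)
    sd = float(np.std(dtheta))
    return float(np.degrees(sd)) if angle_unit == "deg" else sd


def inter_inflection_ratio(points, indices) -> float:
    """Mean arc/chord ratio of the pieces between critical points.

    The polyline is split at the critical-point sample indices; the
    leading and trailing pieces are included.  With no critical points
    the whole-segment arc/chord ratio is returned.
    """
    pts = _as_points(points)
    if len(indices) == 0:
        la, lc = arc_chord(pts)
        return la / lc
    bounds = [0, *sorted(int(i) for i in indices), len(pts) - 1]
    ratios = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        piece = pts[a : b + 1]
        if len(piece) < 2:
            continue
        chord = np.linalg.norm(piece[-1] - piece[0])
        if chord == 0.0:
            continue
        steps = np.linalg.norm(np.diff(piece, axis=0), axis=1)
        ratios.append(float(steps.sum()) / float(chord))
    if not ratios:
        la, lc = arc_chord(pts)
        return la / lc
    return float(np.mean(ratios))


def compute_vti(
    points,
    spacing: float = 1.0,
    smooth_window: int = 1,
    angle_unit: str = "deg",
    min_separation: int = 5,
) -> TortuosityMetrics:
    """Compute the full tortuosity metric set for one centerline segment.

    Pipeline: chord-frame the polyline, resample it to uniform arc-length
    spacing, optionally apply moving-average smoothing, then evaluate
    ``N``, ``SD_theta``, ``M`` and the arc/chord ratio on the same
    resampled points and combine them into the index.

    Smoothing defaults to off: centerlines extracted from images are
    already smoothed at the graph stage, and the endpoint-pinned moving
    average slightly distorts the turning profile near the segment ends
    (visible on constant-curvature arcs, whose angle-difference spread
    should vanish).
    """
    pts = _as_points(points)
    framed = chord_frame(pts)
    res = resample_polyline(framed, spacing=spacing)
    sm = smooth_polyline(res, window=smooth_window)
    la, lc = arc_chord(sm)
    if len(sm) < 5:
        # too short to carry curvature information: straight for our purposes
        return TortuosityMetrics(la, lc, 0, 0.0, la / lc, 0.0, len(sm))
    indices, n_crit = critical_points(sm, min_separation=min_separation)
    sd = tangent_angle_sd(sm, angle_unit=angle_unit)
    m = inter_inflection_ratio(sm, indices)
    vti = 0.1 * m * n_crit * sd * (la / lc)
    return TortuosityMetrics(la, lc, n_crit, sd, m, vti, len(sm))


def image_mean_vti(metrics_list) -> float:
    """Unweighted mean VTI over the segments of one image."""
    values = [m.vti for m in metrics_list]
    if not values:
        raise ValueError("no measurable segments")
    return float(np.mean(values))
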