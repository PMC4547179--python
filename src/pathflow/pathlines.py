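"""Per-atom pathline splines.

An atom's pathline is the curve it traces through space over the pose series.
We interpolate it with a natural cubic spline through the atom's position at
every pose, parameterized uniformly by pose index (poses are uniformly spaced
in simulation time, so no chord-length reweighting is applied).  "Natural"
means the second derivative vanishes at both ends; the interior second
derivatives (the "moments") come from the classical tridiagonal system

    m[i-1] + 4 m[i] + m[i+1] = 6 (y[i-1] - 2 y[i] + y[i+1]),   i = 1..M-2

with m[0] = m[M-1] = 0 and unit knot spacing.  For M = 2 the spline degenerates
to the straight segment between the two points.

Smooth interpolation can rarely overshoot the pose coordinates between knots,
producing loop ("flower-petal") artifacts; :func:`detect_excursions` flags
knot intervals whose maximum chord deviation is large relative to the chord.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "PathlineSpline",
    "ExcursionReport",
    "fit_natural_cubic",
    "detect_excursions",
]

#: chord-length guard for excursion ratios of (nearly) stationary atoms
CHORD_EPSILON = 1e-12

#: default flag threshold: excursion twice the chord length
DEFAULT_EXCURSION_THRESHOLD = 2.0


@dataclass(frozen=True)
class ExcursionReport:
    """Chord-deviation diagnostics for one knot interval."""

    interval_index: int
    excursion_ratio: float
    flagged: bool


class PathlineSpline:
    """Natural cubic spline through M control points at knots 0..M-1.

    Attributes
    ----------
    control_points : (M, 3) array
        The atom's position at each pose, Angstrom.
    second_derivatives : (M, 3) array
        The tridiagonal-solve moments; exactly zero at both end knots.
    """

    def __init__(self, control_points: np.ndarray, second_derivatives: np.ndarray):
        self.control_points = np.asarray(control_points, dtype=float)
        self.second_derivatives = np.asarray(second_derivatives, dtype=float)
        if self.control_points.shape != self.second_derivatives.shape:
            raise ValueError("control point / moment shape mismatch")

    @property
    def n_knots(self) -> int:
        return self.control_points.shape[0]

    @property
    def t_max(self) -> float:
        return float(self.n_knots - 1)

    def _check_domain(self, t: np.ndarray) -> None:
        if np.any(t < 0) or np.any(t > self.t_max):
            raise ValueError(
                f"parameter outside spline domain [0, {self.t_max:g}] (no extrapolation)"
            )

    def evaluate(self, t) -> np.ndarray:
        """Evaluate the pathline at parameter t (scalar or array) in [0, M-1].

        At integer t this returns the control point exactly.
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_domain(t_arr)
        i = np.clip(np.floor(t_arr).astype(int), 0, self.n_knots - 2)
        u = t_arr - i  # in [0, 1]
        y, m = self.control_points, self.second_derivatives
        # unit-spacing piecewise-cubic in moment form
        a = (1.0 - u)[:, None]
        b = u[:, None]
        out = (
            a * y[i]
            + b * y[i + 1]
            + ((a**3 - a) / 6.0) * m[i]
            + ((b**3 - b) / 6.0) * m[i + 1]
        )
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out

    def derivative(self, t) -> np.ndarray:
        """First derivative dS/dt (tangent, Angstrom per pose index)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_domain(t_arr)
        i = np.clip(np.floor(t_arr).astype(int), 0, self.n_knots - 2)
        u = t_arr - i
        y, m = self.control_points, self.second_derivatives
        a = (1.0 - u)[:, None]
        b = u[:, None]
        out = (
            (y[i + 1] - y[i])
            + ((3.0 * b**2 - 1.0) / 6.0) * m[i + 1]
            - ((3.0 * a**2 - 1.0) / 6.0) * m[i]
        )
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out

    def sample(self, segments_per_interval: int = 8) -> tuple[np.ndarray, np.ndarray]:
        """Uniformly sample the whole pathline for tessellation.

        Returns (params, points): (M-1)*s + 1 parameter values spanning
        [0, M-1] with endpoints included, and the evaluated positions.  The
        parameter values double as color-lookup coordinates.
        """
        s = int(segments_per_interval)
        if s < 1:
            raise ValueError("segments_per_interval must be >= 1")
        n = (self.n_knots - 1) * s
        params = np.linspace(0.0, self.t_max, n + 1)
        return params, self.evaluate(params)

    def arc_length(self, t0: float, t1: float) -> float:
        """Arc length of the pathline between parameters t0 <= t1, Angstrom.

        Gauss-Legendre quadrature of |dS/dt| per knot-interval piece; additive
        over adjacent intervals and monotone in t1.
        """
        if not (0 <= t0 <= t1 <= self.t_max):
            raise ValueError(f"arc-length range [{t0}, {t1}] outside [0, {self.t_max:g}]")
        if t0 == t1:
            return 0.0
        # split [t0, t1] at knot boundaries so each piece is one polynomial
        cuts = np.unique(np.concatenate(
            [[t0, t1], np.arange(np.ceil(t0), np.floor(t1) + 1)]
        ))
        cuts = cuts[(cuts >= t0) & (cuts <= t1)]
        nodes, weights = np.polynomial.legendre.leggauss(16)
        total = 0.0
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            half = 0.5 * (hi - lo)
            ts = 0.5 * (hi + lo) + half * nodes
            speed = np.linalg.norm(self.derivative(ts), axis=1)
            total += half * float(np.dot(weights, speed))
        return total


def fit_natural_cubic(points: np.ndarray) -> PathlineSpline:
    """Fit a natural cubic spline through M >= 2 ordered positions.

    Points are (M, 3) (or (M, d) for any d >= 1); knots are the pose indices
    0..M-1.  The moment system is solved per axis with a banded tridiagonal
    solver.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 2:
        raise ValueError("pathline fitting needs at least 2 poses")
    if not np.all(np.isfinite(pts)):
        raise ValueError("control points contain non-finite values")
    M = pts.shape[0]
    moments = np.zeros_like(pts)
    if M > 2:
        n = M - 2
        rhs = 6.0 * (pts[:-2] - 2.0 * pts[1:-1] + pts[2:])
        ab = np.zeros((3, n))
        ab[0, 1:] = 1.0   # superdiagonal
        ab[1, :] = 4.0    # diagonal
        ab[2, :-1] = 1.0  # subdiagonal
        moments[1:-1] = solve_banded((1, 1), ab, rhs)
    return PathlineSpline(pts, moments)


def detect_excursions(
    spline: PathlineSpline,
    threshold: float = DEFAULT_EXCURSION_THRESHOLD,
    samples_per_interval: int = 64,
) -> list[ExcursionReport]:
    """Flag knot intervals where the spline swings far off its chord.

    For each interval the excursion ratio is the maximum distance of the curve
    from the straight chord between the interval's two control points, divided
    by max(chord length, epsilon).  Benign thermal wander (displacements of a
    couple of atomic radii per pose) stays well below the default threshold of
    2.0; loop artifacts exceed it.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    reports = []
    u = np.linspace(0.0, 1.0, samples_per_interval + 1)
    for i in range(spline.n_knots - 1):
        p0 = spline.control_points[i]
        p1 = spline.control_points[i + 1]
        chord = np.linalg.norm(p1 - p0)
        pts = spline.evaluate(i + u)
        # distance from each sample to the chord segment
        if chord > 0:
            d = p1 - p0
            proj = np.clip((pts - p0) @ d / (chord * chord), 0.0, 1.0)
            nearest = p0[None, :] + proj[:, None] * d[None, :]
            dist = np.linalg.norm(pts - nearest, axis=1)
        else:
            dist = np.linalg.norm(pts - p0[None, :], axis=1)
        ratio = float(dist.max() / max(chord, CHORD_EPSILON))
        reports.append(
            ExcursionReport(interval_index=i, excursion_ratio=ratio, flagged=ratio > threshold)
        )
    return reports
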