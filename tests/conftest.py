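"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately separate from the production code paths:
the natural-spline oracle assembles and solves the full dense moment system
with numpy and evaluates the textbook piecewise-cubic formula; the rigid-
rotation oracle uses scipy's Rotation.align_vectors (Kabsch/Procrustes).
"""

from __future__ import annotations

import numpy as np
import pytest

from pathflow import RenderConfig, generate_hinge_motion, select_atoms


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def dense_natural_moments(y: np.ndarray) -> np.ndarray:
    """Solve the full (M x M) natural-spline moment system densely.

    Unit knot spacing; rows 0 and M-1 pin the end moments to zero, interior
    rows are m[i-1] + 4 m[i] + m[i+1] = 6 (y[i-1] - 2 y[i] + y[i+1]).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    M = len(y)
    A = np.zeros((M, M))
    b = np.zeros_like(y)
    A[0, 0] = 1.0
    A[-1, -1] = 1.0
    for i in range(1, M - 1):
        A[i, i - 1] = 1.0
        A[i, i] = 4.0
        A[i, i + 1] = 1.0
        b[i] = 6.0 * (y[i - 1] - 2.0 * y[i] + y[i + 1])
    return np.linalg.solve(A, b)


def dense_natural_eval(y: np.ndarray, moments: np.ndarray, t: float) -> np.ndarray:
    """Standard piecewise-cubic evaluation in moment form, unit spacing."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    i = min(int(np.floor(t)), len(y) - 2)
    u = t - i
    a = 1.0 - u
    return (
        a * y[i]
        + u * y[i + 1]
        + (a**3 - a) / 6.0 * moments[i]
        + (u**3 - u) / 6.0 * moments[i + 1]
    )


def procrustes_rotation_angle_deg(first: np.ndarray, last: np.ndarray) -> float:
    """Best-fit rigid rotation angle between two centered point sets, degrees."""
    from scipy.spatial.transform import Rotation

    a = first - first.mean(axis=0)
    b = last - last.mean(axis=0)
    rot, _ = Rotation.align_vectors(b, a)
    return float(np.degrees(rot.magnitude()))


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------

@pytest.fixture
def hinge_structure():
    """6-atom (3 fixed + 3 arm), 10-pose hinge trajectory."""
    return generate_hinge_motion(n_fixed=3, n_arm=3, n_poses=10,
                                 total_angle=90.0, seed=0)


@pytest.fixture
def hinge_trajectory(hinge_structure):
    return select_atoms(hinge_structure)


@pytest.fixture
def census_config():
    """The geometry-census configuration: s=4 segments, r=8 ring vertices."""
    return RenderConfig(segments_per_interval=4, ring_vertices=8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
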