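"""Color gradients and ribbon transparency.

Two gradients drive the visualization: a temporal gradient along each pathline
(blue at the start of the trajectory, through red, to yellow at the end) and a
sequential gradient along the imposed backbone (red through green to blue, so
the backbone palette overlaps the pathline palette only at the endpoints).
Interpolation between stops is linear in RGB, which keeps exporter output
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ColorGradient",
    "TEMPORAL_DEFAULT",
    "SEQUENTIAL_DEFAULT",
    "temporal_color",
    "sequential_color",
    "fade_alpha",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColorGradient:
    """Ordered color stops (u, rgb) with u strictly increasing from 0 to 1."""

    stops: tuple[tuple[float, tuple[float, float, float]], ...]

    def __post_init__(self) -> None:
        us = [u for u, _ in self.stops]
        if len(us) < 2 or us[0] != 0.0 or us[-1] != 1.0:
            raise ValueError("gradient stops must start at 0 and end at 1")
        if any(b <= a for a, b in zip(us, us[1:])):
            raise ValueError("gradient stop positions must be strictly increasing")
        for _, rgb in self.stops:
            if len(rgb) != 3 or any(not (0.0 <= c <= 1.0) for c in rgb):
                raise ValueError("rgb components must be in [0, 1]")

    def __call__(self, u: float) -> tuple[float, float, float]:
        """Piecewise-linear lookup; out-of-range u is clamped with a warning."""
        if u < 0.0 or u > 1.0:
            logger.warning("gradient parameter %g outside [0, 1]; clamping", u)
            u = min(max(u, 0.0), 1.0)
        us = np.array([s[0] for s in self.stops])
        i = int(np.searchsorted(us, u, side="right")) - 1
        i = min(max(i, 0), len(self.stops) - 2)
        u0, c0 = self.stops[i]
        u1, c1 = self.stops[i + 1]
        w = (u - u0) / (u1 - u0)
        return tuple(float(a + w * (b - a)) for a, b in zip(c0, c1))


#: trajectory-time gradient: blue (start) through red to yellow (end)
TEMPORAL_DEFAULT = ColorGradient((
    (0.0, (0.0, 0.0, 1.0)),
    (0.5, (1.0, 0.0, 0.0)),
    (1.0, (1.0, 1.0, 0.0)),
))

#: backbone sequence gradient: red through green to blue
SEQUENTIAL_DEFAULT = ColorGradient((
    (0.0, (1.0, 0.0, 0.0)),
    (0.5, (0.0, 1.0, 0.0)),
    (1.0, (0.0, 0.0, 1.0)),
))


def temporal_color(u: float, gradient: ColorGradient = TEMPORAL_DEFAULT):
    """Color of a pathline point at normalized trajectory time u in [0, 1]."""
    return gradient(u)


def sequential_color(u: float, gradient: ColorGradient = SEQUENTIAL_DEFAULT):
    """Color of a backbone atom at normalized sequence position u in [0, 1]."""
    return gradient(u)


def fade_alpha(delta_t: float, fade_length: float, alpha_max: float = 0.6) -> float:
    """Opacity of the trailing ribbon ``delta_t`` pose-indices behind the backbone.

    Linear fade: alpha_max at the backbone edge, zero at ``fade_length`` and
    beyond.  ``fade_length`` is in pose-index units and must be positive.
    """
    if fade_length <= 0:
        raise ValueError("fade_length must be positive")
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    return max(0.0, 1.0 - delta_t / fade_length) * alpha_max
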