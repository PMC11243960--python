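"""Small numeric helpers used by several modules."""
from __future__ import annotations

import numpy as np

from .errors import ValidationError


def log_time_grid(t_min: float = 1e-5, t_max: float = 2.0, n: int = 120) -> np.ndarray:
    """Logarithmically spaced acquisition grid, mimicking a fast-fluorometer export.

    Defaults span 10 µs to 2 s in 120 points.
    """
    if not (0.0 < t_min < t_max):
        raise ValidationError("time grid must satisfy 0 < t_min < t_max")
    return np.geomspace(t_min, t_max, n)


def interp_log_time(t: np.ndarray, y: np.ndarray, t_query) -> np.ndarray | float:
    """Interpolate y(t) linearly in log(t).

    Fluorescence transients are sampled on log-spaced grids, so piecewise-linear
    interpolation in log-time tracks the curve far better than in linear time.
    Queries outside [t[0], t[-1]] raise rather than extrapolate.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tq = np.asarray(t_query, dtype=float)
    if np.any(tq < t[0]) or np.any(tq > t[-1]):
        raise ValidationError(
            f"query time outside the recorded range [{t[0]:g}, {t[-1]:g}] s"
        )
    out = np.interp(np.log(tq), np.log(t), y)
    return float(out) if np.isscalar(t_query) or tq.ndim == 0 else out


def check_strictly_increasing(x: np.ndarray, name: str = "values") -> None:
    if np.any(np.diff(np.asarray(x, dtype=float)) <= 0):
        raise ValidationError(f"{name} must be strictly increasing")
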