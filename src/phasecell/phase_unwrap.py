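"""2D phase unwrapping.

Two methods are exposed behind one entry point:

* ``itoh`` — classical line-scan integration of wrapped differences (first
  column, then each row).  Exact whenever the true phase changes by less
  than π between neighbouring pixels; it refuses to run when wrapped-gradient
  residues reveal that path-following would be inconsistent (aliasing).
* ``quality`` (default) — quality-guided unwrapping via the Herráez
  reliability-sorting algorithm (scikit-image implementation), robust to
  moderate noise.

Both return a map whose difference from the wrapped input is an integer
multiple of 2π at every pixel; the global 2π·k offset is fixed by forcing
the median phase of a 5-pixel background border to zero.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from skimage.restoration import unwrap_phase as _herraez_unwrap

from .phase_forward import PhaseMap

__all__ = ["unwrap2d", "ResidueError"]


class ResidueError(RuntimeError):
    """Raised when wrapped-gradient residues make path unwrapping inconsistent."""


def _wrap_to_pi(d: np.ndarray) -> np.ndarray:
    return d - 2 * np.pi * np.round(d / (2 * np.pi))


def _residues(w: np.ndarray) -> np.ndarray:
    """Sum of wrapped gradients around each elementary 2×2 loop (≈ 0 or ±2π)."""
    d1 = _wrap_to_pi(w[:-1, 1:] - w[:-1, :-1])
    d2 = _wrap_to_pi(w[1:, 1:] - w[:-1, 1:])
    d3 = _wrap_to_pi(w[1:, :-1] - w[1:, 1:])
    d4 = _wrap_to_pi(w[:-1, :-1] - w[1:, :-1])
    return d1 + d2 + d3 + d4


def _itoh(w: np.ndarray) -> np.ndarray:
    res = _residues(w)
    if np.any(np.abs(res) > 1e-6):
        n_bad = int(np.sum(np.abs(res) > 1e-6))
        raise ResidueError(
            f"{n_bad} non-zero residues detected; the wrapped map is aliased "
            "and path-following unwrapping is inconsistent"
        )
    u = np.unwrap(w, axis=1)
    col0 = np.unwrap(w[:, 0])
    u += (col0 - u[:, 0])[:, None]
    return u


def _fix_offset(u: np.ndarray, border: int = 5) -> np.ndarray:
    b = np.concatenate(
        [u[:border].ravel(), u[-border:].ravel(),
         u[:, :border].ravel(), u[:, -border:].ravel()]
    )
    k = np.round(np.median(b) / (2 * np.pi))
    return u - 2 * np.pi * k


def unwrap2d(pm: PhaseMap, method: str = "quality") -> PhaseMap:
    """Recover the continuous phase field from a wrapped map.

    The output minus the input is an integer multiple of 2π at every pixel
    (up to a single global 2π·k offset fixed by the zero background border).
    """
    if not pm.wrapped:
        raise ValueError("unwrap2d expects a wrapped map")
    w = pm.values
    if method == "itoh":
        u = _itoh(w)
    elif method == "quality":
        u = np.asarray(_herraez_unwrap(w, wrap_around=False))
    else:
        raise ValueError(f"unknown unwrap method {method!r}")
    # snap to exact 2π multiples of the wrapped input to kill float drift
    k = np.round((u - w) / (2 * np.pi))
    u = w + 2 * np.pi * k
    u = _fix_offset(u)
    return replace(pm, values=u, wrapped=False)
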