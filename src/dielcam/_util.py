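"""Shared helpers: time conventions, RNG plumbing, rounding."""

from __future__ import annotations

import zlib

import numpy as np

TWO_PI = 2.0 * np.pi
HOURS_PER_CYCLE = 24.0
#: radians per hour on the 24-h circle
RAD_PER_HOUR = TWO_PI / HOURS_PER_CYCLE


def hours_to_radians(hours):
    """Map clock hours (0-24) to angles on [0, 2*pi); midnight = 0."""
    return (np.asarray(hours, dtype=float) % HOURS_PER_CYCLE) * RAD_PER_HOUR


def radians_to_hours(theta):
    """Map angles on the circle back to clock hours in [0, 24)."""
    return (np.asarray(theta, dtype=float) % TWO_PI) / RAD_PER_HOUR


def as_rng(seed=None) -> np.random.Generator:
    """Coerce None / int / Generator into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rng(root_seed: int, name: str) -> np.random.Generator:
    """Named substream of a root seed.

    Each (root_seed, name) pair maps deterministically to an independent
    stream, so module-level reruns reproduce pipeline-level results.
    """
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, tag]))


def round_half_up(x, ndigits: int = 0):
    """Decimal-style rounding (0.5 always rounds up), as in reported tables."""
    scale = 10.0 ** ndigits
    return np.floor(np.asarray(x, dtype=float) * scale + 0.5) / scale


def circular_trapezoid(grid: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal integral of a periodic function over one full cycle.

    ``grid`` must be sorted angles in [0, 2*pi); the wraparound segment from
    grid[-1] back to grid[0]+2*pi is included.
    """
    x = np.append(grid, grid[0] + TWO_PI)
    y = np.append(values, values[0])
    return float(np.trapezoid(y, x))
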