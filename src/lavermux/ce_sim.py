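"""Capillary-electrophoresis simulation and peak calling on a bp size axis.

On-chip electrophoresis instruments report a size-calibrated trace of
fluorescence intensity versus fragment size, so the simulation works directly
in the size domain: each amplicon contributes a Gaussian peak whose width
grows with fragment size (sigma = max(0.5 bp, 0.4% of size), a configurable
stand-in for the resolution of a DNA 1000-class chip), and additive Gaussian
baseline noise is clipped at zero. The peak caller thresholds local maxima
relative to the tallest feature and an absolute noise floor, then refines
each apex by parabolic interpolation — enough to resolve this assay's
tightest spacing, the 117/127 bp neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .panel_model import PanelValidationError

__all__ = [
    "Electropherogram",
    "Peak",
    "simulate_trace",
    "call_peaks",
    "sigma_bp",
    "write_trace",
    "write_peaks",
]

DEFAULT_AXIS_MIN_BP = 50.0
DEFAULT_AXIS_MAX_BP = 400.0
DEFAULT_AXIS_STEP_BP = 0.25
DEFAULT_MIN_HEIGHT_FRACTION = 0.05
SIGMA_FRACTION = 0.004
SIGMA_FLOOR_BP = 0.5
NOISE_FLOOR_MULTIPLIER = 5.0


@dataclass(frozen=True)
class Electropherogram:
    """A simulated trace: intensity on a strictly increasing bp grid."""

    size_axis: np.ndarray
    intensity: np.ndarray
    noise_sd: float
    seed: int | None

    def __post_init__(self) -> None:
        axis = np.asarray(self.size_axis, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if axis.ndim != 1 or len(axis) < 3 or np.any(np.diff(axis) <= 0):
            raise PanelValidationError("size axis must be strictly increasing, length >= 3")
        if inten.shape != axis.shape:
            raise PanelValidationError("intensity and size axis length mismatch")
        if not np.all(np.isfinite(inten)) or np.any(inten < 0):
            raise PanelValidationError("intensity must be finite and non-negative")
        object.__setattr__(self, "size_axis", axis)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class Peak:
    """A called peak: interpolated apex position, height and integrated area."""

    size_bp: float
    height: float
    area: float


def sigma_bp(length_bp: float) -> float:
    """Peak width model: 0.4% of the fragment size with a 0.5 bp floor."""
    return max(SIGMA_FLOOR_BP, SIGMA_FRACTION * float(length_bp))


def default_axis(
    lo: float = DEFAULT_AXIS_MIN_BP,
    hi: float = DEFAULT_AXIS_MAX_BP,
    step: float = DEFAULT_AXIS_STEP_BP,
) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def simulate_trace(
    amplicons: Iterable[tuple[float, float]],
    noise_sd: float = 0.0,
    seed: int | None = None,
    size_axis: np.ndarray | None = None,
) -> Electropherogram:
    """Simulate an electropherogram from (length_bp, relative_amount) pairs.

    Peak height is proportional to ``relative_amount`` (equal for equal
    amounts); noise is additive Gaussian with the given sd, drawn from a
    generator seeded with ``seed``, and the trace is clipped at zero.
    """
    axis = default_axis() if size_axis is None else np.asarray(size_axis, dtype=float)
    trace = np.zeros_like(axis)
    for length, amount in amplicons:
        if amount < 0:
            raise PanelValidationError(f"negative amplicon amount {amount}")
        if not (axis[0] <= length <= axis[-1]):
            raise PanelValidationError(
                f"amplicon length {length} bp outside the size axis "
                f"[{axis[0]}, {axis[-1]}]"
            )
        s = sigma_bp(length)
        trace += amount * np.exp(-0.5 * ((axis - length) / s) ** 2)
    if noise_sd < 0:
        raise PanelValidationError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=axis.shape)
    return Electropherogram(axis, np.clip(trace, 0.0, None), float(noise_sd), seed)


def _parabolic_apex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a grid maximum at index i by fitting a parabola through its
    three-point neighbourhood; returns (position, height)."""
    if i == 0 or i == len(y) - 1:
        return float(x[i]), float(y[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:  # flat or non-concave; keep the grid point
        return float(x[i]), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = x[i + 1] - x[i]
    height = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return float(x[i] + delta * step), float(height)


def call_peaks(
    trace: Electropherogram,
    min_height_fraction: float = DEFAULT_MIN_HEIGHT_FRACTION,
) -> list[Peak]:
    """Detect and size peaks in a trace.

    A local maximum is called when it exceeds ``min_height_fraction`` of the
    trace maximum and an absolute floor of 5 x noise_sd. The apex is refined
    by parabolic interpolation; area is the trapezoidal integral between the
    peak's base points. Peaks are returned sorted by size.
    """
    y = trace.intensity
    top = float(y.max(initial=0.0))
    if top <= 0:
        return []
    floor = max(min_height_fraction * top, NOISE_FLOOR_MULTIPLIER * trace.noise_sd)
    idx, props = signal.find_peaks(y, height=floor, prominence=0.5 * floor)
    bases_l = props["left_bases"]
    bases_r = props["right_bases"]
    peaks = []
    for i, lb, rb in zip(idx, bases_l, bases_r):
        pos, height = _parabolic_apex(trace.size_axis, y, int(i))
        area = float(np.trapezoid(y[lb:rb + 1], trace.size_axis[lb:rb + 1]))
        peaks.append(Peak(size_bp=pos, height=height, area=area))
    peaks.sort(key=lambda p: p.size_bp)
    return peaks


def write_trace(trace: Electropherogram, path: str | Path) -> None:
    """Export a trace as two-column TSV (size_bp, intensity)."""
    pd.DataFrame(
        {"size_bp": trace.size_axis, "intensity": trace.intensity}
    ).to_csv(path, sep="\t", index=False)


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Export called peaks as TSV (size_bp, height, area)."""
    pd.DataFrame(
        [{"size_bp": p.size_bp, "height": p.height, "area": p.area} for p in peaks]
    ).to_csv(path, sep="\t", index=False)
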