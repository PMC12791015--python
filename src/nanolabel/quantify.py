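"""Copy-number and probe-dose arithmetic.

Fluorescence calibration regression, Avogadro conversion, subvolume-to-cell
extrapolation, and gold size-distribution statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AVOGADRO",
    "CalibrationCurve",
    "GroupStats",
    "molecules_from_concentration",
    "fit_calibration",
    "invert_calibration",
    "extrapolate_copies",
    "size_distribution_stats",
]

AVOGADRO = 6.02214076e23


@dataclass
class CalibrationCurve:
    """Linear fluorescence calibration: intensity = slope * molecules + intercept."""

    slope: float
    intercept: float
    r_squared: float
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero for inversion")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must be in [0, 1]")


@dataclass
class GroupStats:
    mean: float
    sd: float
    n: int


def molecules_from_concentration(molar: float, volume: float) -> float:
    """Molecule count from molar concentration (mol/L) and volume (L)."""
    return AVOGADRO * molar * volume


def fit_calibration(points) -> CalibrationCurve:
    """Ordinary least squares fit of intensity against molecule count.

    ``points`` is an iterable of ``(molecule_count, intensity)`` pairs with
    at least two distinct abscissae.
    """
    pts = np.atleast_2d(np.asarray(list(points), dtype=float))
    if pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need >= 2 (count, intensity) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct molecule counts")
    result = stats.linregress(x, y)
    return CalibrationCurve(
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue**2),
    )


def invert_calibration(curve: CalibrationCurve, measured_intensity: float,
                       background: float, n_cells: int) -> float:
    """Molecules per cell from a measured bulk intensity.

    Background is subtracted, the calibration is inverted, and the count is
    normalized to ``n_cells``.  Negative estimates are clipped to 0 with a
    warning (counts are non-negative).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    total = ((measured_intensity - background) - curve.intercept) / curve.slope
    per_cell = total / n_cells
    if per_cell < 0:
        warnings.warn(
            f"negative inverted count ({per_cell:.3g}); clipping to 0",
            stacklevel=2,
        )
        return 0.0
    return float(per_cell)


def extrapolate_copies(count_in_subvolume: float, subvolume: float,
                       cell_volume: float) -> float:
    """Scale a count from a sampled subvolume to the whole cell volume.

    Units of the two volumes must match (they cancel).
    """
    if not (subvolume > 0) or not (cell_volume > 0):
        raise ValueError("volumes must be > 0")
    return float(count_in_subvolume) * cell_volume / subvolume


def size_distribution_stats(diameters, labels):
    """Per-group sample mean/SD of diameters, plus a separability flag.

    The flag is computed only for exactly two groups:
    ``|mean1 - mean2| > 2 * (sd1 + sd2)``; otherwise it is None.

    Returns ``(stats_by_group, separable)`` where ``stats_by_group`` maps
    each label to a :class:`GroupStats`.
    """
    diameters = np.asarray(diameters, dtype=float).reshape(-1)
    labels = np.asarray(labels).reshape(-1)
    if diameters.size != labels.size:
        raise ValueError("diameters and labels must have the same length")
    if diameters.size == 0:
        raise ValueError("empty diameter vector")
    by_group: dict = {}
    for label in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        values = diameters[labels == label]
        sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
        by_group[label] = GroupStats(mean=float(values.mean()), sd=sd,
                                     n=int(values.size))
    separable = None
    if len(by_group) == 2:
        (g1, g2) = by_group.values()
        separable = bool(abs(g1.mean - g2.mean) > 2.0 * (g1.sd + g2.sd))
    return by_group, separable
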