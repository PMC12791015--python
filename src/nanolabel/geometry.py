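"""Gold-to-target distance geometry and the labeling-efficiency statistic.

Positions are handled in Å internally; distances cross the API boundary
in nm (divide by 10 exactly once, here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core_io import EfficiencyResult, ParticleTable, TetherModel

__all__ = [
    "DistanceSummary",
    "recenter_to_tag_site",
    "min_pairwise_distances",
    "wlc_rms_end_to_end",
    "max_tether_distance",
    "classify_bound",
    "labeling_efficiency",
    "distance_summary",
    "efficiency_pipeline",
]

A_PER_NM = 10.0


@dataclass
class DistanceSummary:
    """Per-particle minimum distances (nm) with sample mean and SD."""

    per_particle_min_distance: np.ndarray
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        self.per_particle_min_distance = np.asarray(
            self.per_particle_min_distance, dtype=float
        ).reshape(-1)
        if self.n != self.per_particle_min_distance.size:
            raise ValueError("n must equal the number of distances")


def recenter_to_tag_site(particles: ParticleTable, offset) -> ParticleTable:
    """Shift each particle position by its rotated tag-site offset.

    ``offset`` is an ``(x, y, z)`` vector in Å expressed in the particle
    frame; each new position is ``position + R(rot, tilt, psi) @ offset``
    with ``R`` the intrinsic ZYZ rotation.  Orientations are unchanged, and
    the displacement norm equals ``|offset|`` for every record.
    """
    offset = np.asarray(offset, dtype=float).reshape(3)
    if len(particles) == 0:
        raise ValueError("empty particle table")
    eulers = particles.eulers
    if not np.all(np.isfinite(eulers)):
        raise ValueError("particle orientations contain non-finite angles")
    rot = Rotation.from_euler("ZYZ", eulers, degrees=True)
    new_positions = particles.positions + rot.apply(offset)
    return ParticleTable.from_arrays(
        new_positions,
        eulers,
        particles.ids,
        pixel_size_of_source=particles.pixel_size_of_source,
        provenance=particles.provenance + " | recentered to tag site",
    )


def min_pairwise_distances(sites: np.ndarray, golds: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance (nm) from each site to any gold.

    ``sites`` and ``golds`` are ``(n, 3)`` / ``(m, 3)`` arrays in Å.  The
    result equals the row-minimum of the exhaustive pairwise distance
    matrix (computed here with a k-d tree).
    """
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    golds = np.atleast_2d(np.asarray(golds, dtype=float))
    if sites.size == 0:
        raise ValueError("empty site set")
    if golds.size == 0:
        raise ValueError("empty gold set: minimum distances are undefined")
    dist_A, _ = cKDTree(golds).query(sites, k=1)
    return np.asarray(dist_A, dtype=float) / A_PER_NM


def wlc_rms_end_to_end(contour: float, persistence: float) -> float:
    """Root-mean-square end-to-end distance of a worm-like chain (Å).

    ``sqrt(2 * l_p * L * (1 - (l_p / L) * (1 - exp(-L / l_p))))`` with
    contour length ``L`` and persistence length ``l_p``; ``L -> 0`` gives 0.
    """
    if contour < 0 or not (persistence > 0):
        raise ValueError("contour must be >= 0 and persistence > 0")
    if contour == 0:
        return 0.0
    ratio = persistence / contour
    msq = 2.0 * persistence * contour * (1.0 - ratio * (1.0 - np.exp(-1.0 / ratio)))
    return float(np.sqrt(msq))


def max_tether_distance(model: TetherModel) -> float:
    """Upper bound on the tag-to-gold distance (Å).

    Returns ``model.max_distance`` when set (the adopted 100 Å bound);
    otherwise the full-extension estimate
    ``n_flexible_residues * contour_per_residue + rigid_extension``.
    """
    if model.max_distance is not None:
        return float(model.max_distance)
    return float(model.n_flexible_residues * model.contour_per_residue
                 + model.rigid_extension)


def classify_bound(distances: np.ndarray, cutoff: float) -> np.ndarray:
    """Elementwise ``distance <= cutoff`` (both in nm)."""
    distances = np.asarray(distances, dtype=float)
    return distances <= cutoff


def labeling_efficiency(n_labeled: int, n_unlabeled: int) -> EfficiencyResult:
    """Labeled count over total: ``n_labeled / (n_labeled + n_unlabeled)``."""
    if n_labeled < 0 or n_unlabeled < 0:
        raise ValueError("counts must be non-negative")
    denom = n_labeled + n_unlabeled
    if denom == 0:
        raise ValueError("zero denominator: no particles")
    return EfficiencyResult(
        n_labeled=int(n_labeled),
        n_unlabeled=int(n_unlabeled),
        efficiency=n_labeled / denom,
    )


def distance_summary(distances: np.ndarray) -> DistanceSummary:
    """Sample mean and SD (n-1 denominator) of a distance vector (nm)."""
    distances = np.asarray(distances, dtype=float).reshape(-1)
    if distances.size < 2:
        raise ValueError("need at least 2 distances for a sample SD")
    return DistanceSummary(
        per_particle_min_distance=distances,
        mean=float(distances.mean()),
        sd=float(distances.std(ddof=1)),
        n=int(distances.size),
    )


def efficiency_pipeline(tag_sites: np.ndarray, golds: np.ndarray,
                        cutoff_nm: float = 10.0):
    """Site-to-gold distances, bound/unbound classification and efficiency.

    Parameters
    ----------
    tag_sites, golds
        ``(n, 3)`` / ``(m, 3)`` positions in Å.
    cutoff_nm
        Maximum tag-to-gold distance for a particle to count as labeled
        (default 10 nm, the adopted maximum extended tether).

    Returns
    -------
    summary : DistanceSummary or None
        Summary of the minimum distances of the *labeled* subset (None if
        fewer than two particles are labeled).
    efficiency : EfficiencyResult
    unbound_gold_fraction : float
        Fraction of golds with no tag site within the cutoff.
    """
    site_d = min_pairwise_distances(tag_sites, golds)
    flags = classify_bound(site_d, cutoff_nm)
    n_labeled = int(flags.sum())
    result = labeling_efficiency(n_labeled, int(flags.size - n_labeled))
    summary = distance_summary(site_d[flags]) if n_labeled >= 2 else None
    gold_d = min_pairwise_distances(golds, tag_sites)
    unbound_fraction = float(np.mean(gold_d > cutoff_nm))
    return summary, result, unbound_fraction
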