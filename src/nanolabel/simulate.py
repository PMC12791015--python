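"""Synthetic tomogram generator with ground truth.

The simulator emulates the statistical structure the analysis assumes:
globular particles at random positions/orientations, a gold sphere tethered
at a stochastic distance from a tag site fixed in each labeled particle's
frame, a configurable number of unbound golds, and additive white Gaussian
noise.  Output volumes use ``density_bright`` contrast (gold = high values).

Tether lengths are drawn from a Gaussian truncated to ``(0, tether_max]``
with an isotropic random direction.  Spheres are rasterized by
center-in-sphere membership (a voxel belongs to the sphere when its center
lies within the radius), so voxel-count gates downstream see counts close
to the volume-ratio prediction.

:func:`simulate_truth` produces coordinates only — useful for large,
geometry-level experiments where rendering a volume at realistic dilution
would be prohibitive; :func:`simulate_tomogram` additionally rasterizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .core_io import Contrast, ParticleTable, VolumeGrid

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "Subtomogram",
    "simulate_truth",
    "simulate_tomogram",
    "extract_subtomograms",
    "truncated_tether_mean",
]

_MAX_PLACEMENT_TRIES = 200


@dataclass
class SimulationConfig:
    """Parameters of the synthetic tomogram.

    ``dims`` is ``(nx, ny, nz)`` in voxels.  ``tag_offset`` is the tag-site
    position in the particle frame (Å); the default 129 Å z-offset mirrors a
    ribosome-center-to-tag distance of 12.9 nm.  ``margin`` keeps particle
    centers away from the faces; when None it is derived so that every tag
    site and tethered gold stays inside the volume.
    """

    dims: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 3.0
    n_particles: int = 10
    particle_radius: float = 30.0
    particle_amplitude: float = 0.2
    tag_offset: tuple[float, float, float] = (0.0, 0.0, 129.0)
    labeled_fraction: float = 1.0
    tether_mean: float = 51.0
    tether_sd: float = 19.0
    tether_max: float = 100.0
    gold_radius: float = 7.0
    gold_amplitude: float = 1.0
    n_unbound_gold: int = 0
    noise_sd: float = 0.0
    min_separation: float = 0.0
    margin: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.labeled_fraction <= 1.0):
            raise ValueError("labeled_fraction must be in [0, 1]")
        if not (self.gold_amplitude > self.particle_amplitude > 0):
            raise ValueError("require gold_amplitude > particle_amplitude > 0")
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0")
        if self.n_particles < 0 or self.n_unbound_gold < 0:
            raise ValueError("counts must be non-negative")
        if not (self.tether_max > 0) or not (self.tether_sd > 0):
            raise ValueError("tether_max and tether_sd must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def extent(self) -> np.ndarray:
        """Physical edge lengths ``(x, y, z)``, Å."""
        return np.asarray(self.dims, dtype=float) * self.voxel_size

    @property
    def n_bound(self) -> int:
        return int(round(self.labeled_fraction * self.n_particles))

    def effective_margin(self) -> float:
        if self.margin is not None:
            return float(self.margin)
        reach = float(np.linalg.norm(self.tag_offset)) + self.tether_max + self.gold_radius
        return max(self.particle_radius, reach)


@dataclass
class SimulationTruth:
    """Ground truth emitted by the simulator.

    ``gold_positions`` lists bound golds first (in bound-particle order),
    then unbound golds.  ``bound_particle_ids`` is -1 for unbound golds.
    ``tether_lengths`` holds the drawn tag-to-gold distance per bound gold
    (NaN for unbound); it equals the realized Euclidean distance exactly,
    pre-rasterization.
    """

    particles: ParticleTable
    tag_sites: np.ndarray
    gold_positions: np.ndarray
    bound_flags: np.ndarray
    bound_particle_ids: np.ndarray
    tether_lengths: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _random_eulers(rng: np.random.Generator, n: int) -> np.ndarray:
    """Orientation-uniform intrinsic ZYZ angles (degrees)."""
    rot = rng.uniform(-180.0, 180.0, n)
    tilt = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, n)))
    psi = rng.uniform(-180.0, 180.0, n)
    return np.column_stack([rot, tilt, psi])


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _place_centers(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    lo = np.full(3, config.effective_margin())
    hi = config.extent - config.effective_margin()
    if np.any(hi <= lo):
        raise ValueError(
            "volume too small: margin leaves no interior for particle centers"
        )
    centers: list[np.ndarray] = []
    for _ in range(config.n_particles):
        for _ in range(_MAX_PLACEMENT_TRIES):
            cand = rng.uniform(lo, hi)
            if not centers:
                break
            d = np.linalg.norm(np.asarray(centers) - cand, axis=1)
            if d.min() >= config.min_separation:
                break
        else:
            raise RuntimeError(
                f"could not place {config.n_particles} particles with "
                f"min_separation {config.min_separation} after "
                f"{_MAX_PLACEMENT_TRIES} tries each"
            )
        centers.append(cand)
    return np.asarray(centers).reshape(config.n_particles, 3)


def _draw_tether_lengths(rng: np.random.Generator, config: SimulationConfig,
                         n: int) -> np.ndarray:
    a = (0.0 - config.tether_mean) / config.tether_sd
    b = (config.tether_max - config.tether_mean) / config.tether_sd
    return stats.truncnorm.rvs(a, b, loc=config.tether_mean,
                               scale=config.tether_sd, size=n, random_state=rng)


def truncated_tether_mean(config: SimulationConfig) -> float:
    """Mean of the truncated tether-length distribution (Å, closed form)."""
    a = (0.0 - config.tether_mean) / config.tether_sd
    b = (config.tether_max - config.tether_mean) / config.tether_sd
    return float(stats.truncnorm.mean(a, b, loc=config.tether_mean,
                                      scale=config.tether_sd))


def simulate_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw ground-truth coordinates without rasterizing a volume.

    Gold positions are kept at least ``4 * gold_radius`` apart (directions
    are redrawn at fixed tether length on the rare collision) so that blobs
    remain individually resolvable by the detector.
    """
    rng = np.random.default_rng(config.seed)
    centers = _place_centers(rng, config)
    eulers = _random_eulers(rng, config.n_particles)
    particles = ParticleTable.from_arrays(centers, eulers,
                                          provenance="simulate_truth")
    offset = np.asarray(config.tag_offset, dtype=float)
    tag_sites = centers + Rotation.from_euler("ZYZ", eulers, degrees=True).apply(offset)

    n_bound = config.n_bound
    bound_ids = np.sort(rng.choice(config.n_particles, size=n_bound, replace=False)) \
        if n_bound else np.zeros(0, dtype=int)
    lengths = _draw_tether_lengths(rng, config, n_bound)
    gold_sep = 4.0 * config.gold_radius

    golds: list[np.ndarray] = []
    for pid, length in zip(bound_ids, lengths):
        site = tag_sites[pid]
        for _ in range(_MAX_PLACEMENT_TRIES):
            pos = site + length * _random_unit_vectors(rng, 1)[0]
            if not golds:
                break
            if np.linalg.norm(np.asarray(golds) - pos, axis=1).min() >= gold_sep:
                break
        else:
            raise RuntimeError("could not separate bound golds; volume too crowded")
        golds.append(pos)

    lo = np.full(3, config.gold_radius)
    hi = config.extent - config.gold_radius
    clearance = config.particle_radius + 2.0 * config.gold_radius
    for _ in range(config.n_unbound_gold):
        for _ in range(_MAX_PLACEMENT_TRIES):
            pos = rng.uniform(lo, hi)
            ok = True
            if golds and np.linalg.norm(np.asarray(golds) - pos, axis=1).min() < gold_sep:
                ok = False
            if ok and config.n_particles and \
                    np.linalg.norm(centers - pos, axis=1).min() < clearance:
                ok = False
            if ok:
                break
        else:
            raise RuntimeError("could not place unbound golds; volume too crowded")
        golds.append(pos)

    n_gold = len(golds)
    gold_positions = np.asarray(golds).reshape(n_gold, 3)
    bound_flags = np.zeros(n_gold, dtype=bool)
    bound_flags[:n_bound] = True
    bound_particle_ids = np.full(n_gold, -1, dtype=int)
    bound_particle_ids[:n_bound] = bound_ids
    tether_lengths = np.full(n_gold, np.nan)
    tether_lengths[:n_bound] = lengths
    return SimulationTruth(
        particles=particles,
        tag_sites=tag_sites,
        gold_positions=gold_positions,
        bound_flags=bound_flags,
        bound_particle_ids=bound_particle_ids,
        tether_lengths=tether_lengths,
    )


def _paint_sphere(data: np.ndarray, center_xyz: np.ndarray, radius: float,
                  amplitude: float, voxel: float) -> None:
    """Set voxels whose centers fall inside the sphere to >= amplitude."""
    nz, ny, nx = data.shape
    dims = (nx, ny, nz)
    lo = [max(0, int(np.floor((c - radius) / voxel - 0.5))) for c in center_xyz]
    hi = [min(n - 1, int(np.ceil((c + radius) / voxel - 0.5)))
          for c, n in zip(center_xyz, dims)]
    if any(l > h for l, h in zip(lo, hi)):
        return
    ax = [(np.arange(l, h + 1) + 0.5) * voxel - c
          for l, h, c in zip(lo, hi, center_xyz)]
    dx, dy, dz = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
    inside = (dx**2 + dy**2 + dz**2 <= radius**2).transpose(2, 1, 0)  # -> z,y,x
    view = data[lo[2]:hi[2] + 1, lo[1]:hi[1] + 1, lo[0]:hi[0] + 1]
    view[inside] = np.maximum(view[inside], amplitude)


def simulate_tomogram(config: SimulationConfig) -> tuple[VolumeGrid, SimulationTruth]:
    """Render the configured scene into a noisy ``density_bright`` volume.

    Identical configs (including seed) give bit-identical volumes.
    """
    truth = simulate_truth(config)
    nx, ny, nz = config.dims
    data = np.zeros((nz, ny, nx), dtype=np.float32)
    for center in truth.particles.positions:
        _paint_sphere(data, center, config.particle_radius,
                      config.particle_amplitude, config.voxel_size)
    for pos in truth.gold_positions:
        _paint_sphere(data, pos, config.gold_radius, config.gold_amplitude,
                      config.voxel_size)
    if config.noise_sd > 0:
        noise_rng = np.random.default_rng([config.seed, 0xA0])
        data = data + noise_rng.normal(0.0, config.noise_sd,
                                       size=data.shape).astype(np.float32)
    vol = VolumeGrid(data=data, voxel_size=config.voxel_size,
                     contrast=Contrast.DENSITY_BRIGHT)
    return vol, truth


@dataclass
class Subtomogram:
    """A particle-centered box, flagged when edge padding was required."""

    grid: VolumeGrid
    particle_id: int
    padded: bool


def extract_subtomograms(vol: VolumeGrid, particles: ParticleTable,
                         box: int) -> list[Subtomogram]:
    """Cut a ``box``-voxel cube around each particle position.

    ``box`` must be even.  Out-of-bounds regions are padded with the volume
    mean and the subtomogram is flagged as padded.
    """
    if box < 2 or box % 2:
        raise ValueError("box must be an even integer >= 2")
    half = box // 2
    fill = float(vol.data.mean())
    nz, ny, nx = vol.data.shape
    out: list[Subtomogram] = []
    for record in particles.records:
        # voxel index whose center is nearest the particle position
        idx_xyz = np.round((record.position - vol.origin) / vol.voxel_size - 0.5)
        cz, cy, cx = int(idx_xyz[2]), int(idx_xyz[1]), int(idx_xyz[0])
        lo = np.array([cz - half, cy - half, cx - half])
        hi = lo + box
        src_lo = np.maximum(lo, 0)
        src_hi = np.minimum(hi, [nz, ny, nx])
        padded = bool(np.any(lo < 0) or np.any(hi > [nz, ny, nx]))
        cube = np.full((box, box, box), fill, dtype=vol.data.dtype)
        if np.all(src_lo < src_hi):
            dst_lo = src_lo - lo
            dst_hi = dst_lo + (src_hi - src_lo)
            cube[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
                vol.data[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
        origin = vol.origin + (lo[::-1]) * vol.voxel_size
        out.append(Subtomogram(
            grid=VolumeGrid(cube, vol.voxel_size, vol.contrast, origin),
            particle_id=record.id,
            padded=padded,
        ))
    return out
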