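"""Per-subtomogram suppression of gold signal before alignment.

Voxels brighter than ``mean + k_sd * SD`` of their own subtomogram are
replaced by draws within one SD of that mean, so subsequent alignment is
driven by the macromolecule rather than the much denser gold.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .core_io import VolumeGrid

__all__ = ["randomize_gold_signal", "randomize_stack"]


def randomize_gold_signal(sub: VolumeGrid, k_sd: float = 3.3, seed: int = 0,
                          distribution: str = "uniform") -> VolumeGrid:
    """Replace supra-threshold voxels with draws within one SD of the mean.

    The mean and SD are computed from the input subtomogram itself
    ("per-particle" statistics, never pooled).  Each voxel with value
    above ``mean + k_sd * SD`` receives an independent draw on
    ``[mean - SD, mean + SD]``; all other voxels are returned bit-identical.

    ``distribution`` selects the replacement law: ``"uniform"`` (default,
    the least-assuming reading of "within one standard deviation") or
    ``"truncnorm"`` (a Gaussian truncated to the same interval).

    A degenerate subtomogram (SD == 0) cannot contain supra-threshold
    voxels, so it is returned unchanged with a warning rather than raising;
    this lets all-padding boxes survive batch runs.
    """
    sub.require_bright("randomize_gold_signal")
    if distribution not in ("uniform", "truncnorm"):
        raise ValueError(f"unknown replacement distribution {distribution!r}")
    mu = float(sub.data.mean())
    sd = float(sub.data.std())
    if sd == 0:
        warnings.warn("subtomogram has zero SD; returned unchanged", stacklevel=2)
        return sub.with_data(sub.data.copy())
    mask = sub.data > mu + k_sd * sd
    out = sub.data.copy()
    n = int(mask.sum())
    if n:
        rng = np.random.default_rng(seed)
        if distribution == "uniform":
            draws = rng.uniform(mu - sd, mu + sd, size=n)
        else:
            draws = stats.truncnorm.rvs(-1.0, 1.0, loc=mu, scale=sd, size=n,
                                        random_state=rng)
        out[mask] = draws.astype(out.dtype, copy=False)
    return sub.with_data(out)


def randomize_stack(subs: list[VolumeGrid], k_sd: float = 3.3,
                    master_seed: int = 0,
                    distribution: str = "uniform") -> list[VolumeGrid]:
    """Randomize a stack of subtomograms with per-item statistics and seeds.

    Item ``i`` is processed with seed ``master_seed + i``, so its output
    depends only on its own contents, the master seed and its position —
    never on the other items.
    """
    if not subs:
        raise ValueError("empty subtomogram stack")
    return [
        randomize_gold_signal(sub, k_sd=k_sd, seed=master_seed + i,
                              distribution=distribution)
        for i, sub in enumerate(subs)
    ]
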