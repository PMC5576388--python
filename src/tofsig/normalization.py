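"""Z-score normalization of raw MR signal intensity.

TOF-MRA signal intensity is recorded in arbitrary scanner units; to make
wall-gradient values comparable across scanners the raw intensities phi are
mapped to Phi = (phi - mu) / sigma, where mu and sigma are the mean and
*population* standard deviation over a statistics region (the whole volume
by default, or an optional mask, e.g. a brain/neck region excluding air).
An affine change of the raw scale, a*phi + b with a > 0, leaves the
normalized volume unchanged, which is exactly the scanner offset/scale
invariance the z-score is meant to provide.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateInputError
from .volume_io import Volume

__all__ = ["NormalizationStats", "normalize_volume"]


@dataclasses.dataclass(frozen=True)
class NormalizationStats:
    """Mean/SD used for z-scoring, plus where they came from."""

    mean: float
    std: float  # population (divide-by-n) standard deviation
    n_voxels: int
    mask_tag: str

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise DegenerateInputError("normalization needs >= 2 voxels")
        if not self.std > 0:
            raise DegenerateInputError("normalization needs std > 0")

    def apply(self, value):
        """Map a raw-scale SI value onto the normalized scale."""
        return (np.asarray(value, dtype=float) - self.mean) / self.std

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def normalize_volume(
    v: Volume, mask: np.ndarray | None = None
) -> tuple[Volume, NormalizationStats]:
    """Z-score a volume: Phi = (phi - mu) / sigma.

    Statistics are computed over ``mask`` when given (a boolean grid of the
    volume's shape), otherwise over the whole volume; the transform itself
    is always applied to every voxel.  Spacing is unchanged.

    Raises
    ------
    DegenerateInputError
        Fewer than 2 statistics voxels, or zero variance.
    """
    if mask is None:
        sample = v.data.ravel()
        tag = "whole_volume"
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != v.shape:
            raise DegenerateInputError(
                f"mask shape {mask.shape} != volume shape {v.shape}"
            )
        sample = v.data[mask]
        tag = "mask"
    if sample.size < 2:
        raise DegenerateInputError("normalization region has < 2 voxels")
    mu = float(np.mean(sample))
    sigma = float(np.std(sample))  # population SD (ddof=0)
    if sigma == 0.0 or not np.isfinite(sigma):
        raise DegenerateInputError("zero variance: volume cannot be z-scored")
    stats = NormalizationStats(mean=mu, std=sigma, n_voxels=int(sample.size), mask_tag=tag)
    out = Volume(data=(v.data - mu) / sigma, spacing=v.spacing, frame=v.frame)
    return out, stats
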