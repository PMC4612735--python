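"""Reference (average ablation-zone) intensity estimation.

The per-node costs of the segmentation graph compare each sampled gray value
against one fixed reference intensity for the ablation zone.  Rather than
taking the single voxel under the seed — which may sit on a bright needle
voxel — the reference is pooled over a small neighborhood of about 1 cm³
around the seed.  The region is an axis-aligned cube whose physical volume is
``region_volume_mm3``; its edge length is converted per axis into voxel
counts via the spacing, so the cube stays ~1 cm³ regardless of anisotropy.

``mode="mean"`` integrates over the cube; ``mode="median"`` additionally
rejects outliers such as needle voxels instead of merely diluting them.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateRegionError, InvalidParameterError
from .volume import ImageVolume, SeedPoint

__all__ = ["estimate_reference_value"]


def estimate_reference_value(
    volume: ImageVolume,
    seed: SeedPoint,
    region_volume_mm3: float = 1000.0,
    mode: str = "mean",
) -> float:
    """Estimate the average ablation-zone intensity near the seed.

    Parameters
    ----------
    volume : ImageVolume
        The image to sample.
    seed : SeedPoint
        Seed inside the ablation zone (world mm or voxel frame).
    region_volume_mm3 : float
        Physical volume of the sampling cube, default 1000 mm³ (1 cm³).
    mode : {"mean", "median"}
        Pooling statistic over the cube.

    Returns
    -------
    float
        The pooled intensity.

    Raises
    ------
    OutOfBoundsError
        If the seed lies outside the volume.
    DegenerateRegionError
        If the cube clipped to the volume contains no voxels.
    """
    if mode not in ("mean", "median"):
        raise InvalidParameterError(f"mode must be 'mean' or 'median', got {mode!r}")
    if not region_volume_mm3 > 0:
        raise InvalidParameterError(
            f"region_volume_mm3 must be positive, got {region_volume_mm3}"
        )
    center = seed.to_world(volume)
    center_vox = volume.world_to_voxel(center)
    edge_mm = float(region_volume_mm3) ** (1.0 / 3.0)

    slices = []
    for ax in range(3):
        # at least one voxel per axis even when spacing > edge length;
        # the epsilon makes knife-edge alignments inclusive on both sides,
        # so integer-voxel translations cannot change the cube size
        half = max(edge_mm / (2.0 * volume.spacing[ax]), 0.5)
        lo = int(np.ceil(center_vox[ax] - half - 1e-9))
        hi = int(np.floor(center_vox[ax] + half + 1e-9))
        if hi < lo:  # degenerate rounding: fall back to nearest voxel
            lo = hi = int(round(center_vox[ax]))
        lo = max(lo, 0)
        hi = min(hi, volume.shape[ax] - 1)
        if hi < lo:
            raise DegenerateRegionError(
                f"reference region empty after clipping on axis {ax}"
            )
        slices.append(slice(lo, hi + 1))

    block = volume.values[tuple(slices)]
    if block.size == 0:
        raise DegenerateRegionError("reference region contains no voxels")
    if mode == "mean":
        return float(block.mean())
    return float(np.median(block))
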