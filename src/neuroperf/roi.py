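"""Region-of-interest masking and statistics on labeled volumes."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import WHOLE_BRAIN, LabelAtlas, Volume3D


def atlas_region_mask(atlas: LabelAtlas, region: str) -> np.ndarray:
    """Boolean mask of one named region (or ``whole_brain`` = any label)."""
    if region == WHOLE_BRAIN:
        return atlas.labels > 0
    return atlas.labels == atlas.label_of(region)


def roi_mean(
    volume: Volume3D | np.ndarray,
    atlas: LabelAtlas,
    regions: tuple[str, ...] | None = None,
    include_whole_brain: bool = False,
) -> pd.DataFrame:
    """Per-region mean, sample SD and finite-voxel count of a scalar map.

    Non-finite voxels are dropped from each region before averaging; a
    region left empty after masking is omitted with a warning.
    """
    values = volume.values if isinstance(volume, Volume3D) else np.asarray(volume)
    if values.shape != atlas.shape:
        raise ValueError(f"map shape {values.shape} != atlas shape {atlas.shape}")
    if regions is None:
        regions = atlas.names
    if include_whole_brain:
        regions = tuple(regions) + (WHOLE_BRAIN,)
    rows = []
    for region in regions:
        inside = values[atlas_region_mask(atlas, region)]
        inside = inside[np.isfinite(inside)]
        if inside.size == 0:
            warnings.warn(f"region {region!r} empty after masking non-finite voxels")
            continue
        sd = float(np.std(inside, ddof=1)) if inside.size > 1 else 0.0
        rows.append(
            {
                "region": region,
                "mean": float(np.mean(inside)),
                "sd": sd,
                "n_voxels": int(inside.size),
            }
        )
    return pd.DataFrame(rows, columns=["region", "mean", "sd", "n_voxels"])


def region_signal_series(
    volumes: list[Volume3D],
    atlas: LabelAtlas,
    regions: tuple[str, ...],
    include_whole_brain: bool = True,
) -> pd.DataFrame:
    """ROI-mean signal for each volume of a series.

    Returns one column per region (rows = series index).  The ROI mean is
    taken before any log transform downstream ("ROI-mean-then-log").
    """
    names = tuple(regions) + ((WHOLE_BRAIN,) if include_whole_brain else ())
    masks = {r: atlas_region_mask(atlas, r) for r in names}
    data = np.stack([v.values for v in volumes])  # (n_vol, x, y, z)
    out = {r: data[:, m].mean(axis=1) for r, m in masks.items()}
    return pd.DataFrame(out)
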