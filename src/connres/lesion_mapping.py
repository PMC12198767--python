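"""Map voxel-level lesion masks onto atlas regions via the 50%-overlap rule.

An atlas label volume assigns each voxel to a region (0 = background). A
binary lesion mask on the same grid marks lesioned voxels. A region counts
as lesioned when at least half of its voxels fall inside the mask (the
boundary-inclusive reading; a strict ``>`` variant is available since the
source conventions for primary lesions and virtual attacks differ in
wording). Inputs must already share one grid — no resampling is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .core import region_name

__all__ = [
    "AtlasVolume",
    "LesionRegionSet",
    "region_overlap_fractions",
    "lesioned_regions",
    "load_atlas",
    "load_mask",
    "save_atlas",
    "save_mask",
]


@dataclass(frozen=True)
class AtlasVolume:
    """3-D integer label volume (0 = background) with voxel dimensions in mm."""

    labels: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("atlas labels must be a 3-D array")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if lab.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        object.__setattr__(self, "labels", lab)

    @property
    def region_labels(self) -> tuple[int, ...]:
        present = np.unique(self.labels)
        return tuple(int(v) for v in present if v != 0)


@dataclass(frozen=True)
class LesionRegionSet:
    """Regions deemed lesioned by one mask, with per-region overlap fractions."""

    mask_id: str
    regions: frozenset[str]
    overlap_fraction: Mapping[str, float] = field(default_factory=dict)
    source: str = "clinical_mask"  # or "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", frozenset(self.regions))
        for frac in self.overlap_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("overlap fractions must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def region_overlap_fractions(
    atlas: AtlasVolume,
    mask: np.ndarray,
    naming: Callable[[int], str] = region_name,
) -> dict[str, float]:
    """Fraction of each region's voxels covered by the binary mask.

    ``fraction[r] = |voxels of r inside mask| / |voxels of r|``; regions the
    mask never touches get 0. Raises on a grid-shape mismatch (masks must be
    co-registered to the atlas upstream).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != atlas.labels.shape:
        raise ValueError(
            f"mask shape {mask.shape} != atlas shape {atlas.labels.shape}"
        )
    labels = atlas.labels
    n_labels = int(labels.max()) + 1
    totals = np.bincount(labels.ravel(), minlength=n_labels)
    inside = np.bincount(labels.ravel()[mask.ravel()], minlength=n_labels)
    out: dict[str, float] = {}
    for lab in atlas.region_labels:
        out[naming(lab)] = float(inside[lab]) / float(totals[lab])
    return out


def lesioned_regions(
    fractions: Mapping[str, float],
    threshold: float = 0.5,
    mask_id: str = "mask",
    strict_greater: bool = False,
    source: str = "clinical_mask",
) -> LesionRegionSet:
    """Regions whose overlap fraction reaches the threshold.

    Default is boundary-inclusive (fraction >= threshold, "at least 50%");
    ``strict_greater=True`` requires fraction > threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    for region, frac in fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction for {region} outside [0, 1]: {frac}")
    if strict_greater:
        hit = {r for r, f in fractions.items() if f > threshold}
    else:
        hit = {r for r, f in fractions.items() if f >= threshold}
    return LesionRegionSet(
        mask_id=mask_id,
        regions=frozenset(hit),
        overlap_fraction=dict(fractions),
        source=source,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O (thin nibabel wrappers)

def load_atlas(path: str | Path) -> AtlasVolume:
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).round().astype(np.int32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return AtlasVolume(labels=labels, voxel_dims=zooms)


def load_mask(path: str | Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5


def save_atlas(atlas: AtlasVolume, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(atlas.voxel_dims) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), affine), str(path))


def save_mask(mask: np.ndarray, path: str | Path,
              voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    affine = np.diag(list(voxel_dims) + [1.0])
    nib.save(
        nib.Nifti1Image(np.asarray(mask).astype(np.uint8), affine), str(path)
    )
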