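"""VOI delineation and lesion bookkeeping.

Lesion VOIs are segmented by fixed thresholding at a percentage of the
lesion SUVmax on the full-statistics image, then copied unchanged to every
reduced-count image; background VOIs are 3 cm spheres in liver and normal
lung; the lesion background for CNR is a 2-voxel morphological shell
around the lesion mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "VOIMask",
    "background_shell",
    "ball_structuring_element",
    "filter_lesions",
    "sphere_voi",
    "split_by_volume",
    "threshold_voi",
]


@dataclass
class VOIMask:
    """Boolean voxel mask with a role label and physical volume."""

    mask: np.ndarray
    label: str
    voxel_size: tuple[float, ...]
    threshold_pct: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("VOI mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * float(np.prod(self.voxel_size)) / 1000.0


def _hill_climb(image: np.ndarray, seed_voxel: tuple[int, ...]) -> tuple[int, ...]:
    """Move from the seed to a local maximum over the full neighborhood."""
    pos = tuple(int(v) for v in seed_voxel)
    shape = image.shape
    while True:
        lo = [max(0, p - 1) for p in pos]
        hi = [min(n, p + 2) for p, n in zip(pos, shape)]
        window = image[tuple(slice(l, h) for l, h in zip(lo, hi))]
        local = np.unravel_index(int(np.argmax(window)), window.shape)
        new = tuple(l + o for l, o in zip(lo, local))
        if image[new] <= image[pos]:
            return pos
        pos = new


def threshold_voi(image: np.ndarray, seed_voxel: tuple[int, ...], pct: float,
                  voxel_size: tuple[float, ...] = (4.0, 4.0, 4.0)) -> VOIMask:
    """Segment the lesion around a seed at ``pct`` % of its SUVmax.

    The seed is hill-climbed to the lesion maximum; the mask is all voxels
    >= pct/100 x SUVmax restricted to the connected component (full
    26-neighborhood connectivity in 3D) containing that maximum.
    """
    if not 0.0 < pct <= 100.0:
        raise ValueError(f"pct must be in (0, 100], got {pct}")
    img = np.asarray(image, dtype=np.float64)
    peak = _hill_climb(img, seed_voxel)
    suvmax = img[peak]
    if suvmax <= 0:
        raise ValueError("no uptake at or around the seed voxel")
    above = img >= (pct / 100.0) * suvmax
    structure = np.ones((3,) * img.ndim, dtype=bool)
    labels, _ = ndimage.label(above, structure=structure)
    mask = labels == labels[peak]
    if not mask.any():
        raise ValueError("thresholding produced an empty mask")
    return VOIMask(mask=mask, label="lesion", voxel_size=tuple(voxel_size), threshold_pct=pct)


def sphere_voi(grid_shape: tuple[int, ...], center: tuple[float, ...],
               voxel_size: tuple[float, ...], diameter_mm: float = 30.0,
               label: str = "background") -> VOIMask:
    """Spherical VOI of voxels whose centers lie within diameter/2 of center."""
    radius = diameter_mm / 2.0
    for c, n, s in zip(center, grid_shape, voxel_size):
        if c * s - radius < -0.5 * s or c * s + radius > (n - 0.5) * s:
            raise ValueError("sphere is clipped by the grid boundary")
    axes = [(np.arange(n) - c) * s for n, c, s in zip(grid_shape, center, voxel_size)]
    grids = np.meshgrid(*axes, indexing="ij")
    d2 = sum(g ** 2 for g in grids)
    mask = d2 <= radius ** 2
    return VOIMask(mask=mask, label=label, voxel_size=tuple(voxel_size))


def ball_structuring_element(radius_voxels: int, ndim: int = 3, chebyshev: bool = False) -> np.ndarray:
    """Structuring element for dilation by ``radius_voxels``.

    Default is the Euclidean ball (offsets with squared norm <= r^2); the
    Chebyshev cube alternative dilates by r in every axis direction.
    """
    r = int(radius_voxels)
    if r < 0:
        raise ValueError("radius must be >= 0")
    if chebyshev:
        return np.ones((2 * r + 1,) * ndim, dtype=bool)
    grids = np.meshgrid(*([np.arange(-r, r + 1)] * ndim), indexing="ij")
    return sum(g ** 2 for g in grids) <= r * r


def background_shell(lesion: VOIMask, radius_voxels: int = 2, chebyshev: bool = False) -> VOIMask:
    """Background mask: dilation of the lesion by ``radius_voxels``, minus the lesion."""
    if radius_voxels == 0:
        raise ValueError("radius 0 yields an empty shell")
    se = ball_structuring_element(radius_voxels, lesion.mask.ndim, chebyshev)
    # The shell must not be clipped: the dilated mask has to stay inside.
    idx = np.argwhere(lesion.mask)
    if (idx.min(axis=0) < radius_voxels).any() or \
       (idx.max(axis=0) + radius_voxels >= np.array(lesion.mask.shape)).any():
        raise ValueError("background shell would be clipped at the grid boundary")
    dilated = ndimage.binary_dilation(lesion.mask, structure=se)
    return VOIMask(mask=dilated & ~lesion.mask, label="background_shell",
                   voxel_size=lesion.voxel_size)


def filter_lesions(records: list, max_volume_ml: float = 20.0, min_cnr: float = 2.0) -> list:
    """Keep lesions with volume <= ``max_volume_ml`` and CNR >= ``min_cnr``.

    ``records`` are any objects exposing ``volume_ml`` and ``cnr``
    attributes or ``(lesion, volume_ml, cnr)`` tuples; order is preserved.
    """
    def fields(r):
        if hasattr(r, "volume_ml"):
            return r.volume_ml, r.cnr
        return r[1], r[2]

    return [r for r in records if fields(r)[0] <= max_volume_ml and fields(r)[1] >= min_cnr]


def split_by_volume(records: list, threshold_ml: float = 5.0) -> tuple[list, list]:
    """Split lesion records into small (< threshold) and large (>= threshold).

    A lesion of exactly the threshold volume goes to the large group.
    """
    def vol(r):
        return r.volume_ml if hasattr(r, "volume_ml") else r[1]

    small = [r for r in records if vol(r) < threshold_ml]
    large = [r for r in records if vol(r) >= threshold_ml]
    return small, large
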