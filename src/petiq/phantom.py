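"""Digital thorax phantoms and full-statistics list-mode event streams.

Synthetic subjects emulate a small FDG PET cohort imaged over the lung and
upper liver: a body compartment filled with low-uptake lung tissue, a
uniform liver sphere, and one or more spherical lesions.  Cohort statistics
(weight, liver and lesion SUV, lesion volume, net true counts) follow the
distributions of a published tuberculosis PET/MR cohort so that every
downstream stage — thinning, reconstruction, metrics, count-response models
— can be exercised without any external data.

Event generation uses a fixed-total multinomial convention: the stream
contains exactly ``total_true_counts`` true events distributed over voxels
with probability proportional to the activity (SUV) map.  This makes
"counts in the scan", the x-axis of every count-response analysis, exact;
per-voxel counts remain asymptotically Poisson-like.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EFFECTIVE_DOSE_MSV_PER_MBQ",
    "ActivityPhantom",
    "EventStream",
    "LesionSpec",
    "PhantomSpec",
    "build_phantom",
    "effective_dose",
    "generate_events",
    "sample_cohort",
    "thorax_masks",
]

#: ICRP effective-dose coefficient for 18F-FDG in an adult, mSv per MBq.
EFFECTIVE_DOSE_MSV_PER_MBQ = 0.019

# Cohort distribution parameters (16-subject TB PET/MR cohort).
WEIGHT_RANGE_KG = (45.0, 79.0)
LIVER_SUV_MEAN, LIVER_SUV_SD = 1.57, 0.40
LESION_SUV_MEAN, LESION_SUV_SD = 1.92, 0.95
LESION_SUV_MIN = 0.5
LESION_VOLUME_RANGE_ML = (1.2, 17.58)
TRUE_COUNTS_MEAN, TRUE_COUNTS_SD = 1.32e8, 3.91e7
INJECTED_DOSE_MEAN, INJECTED_DOSE_SD = 168.6, 50.0
INJECTED_DOSE_RANGE = (118.0, 260.5)
SCAN_TIME_S = 900.0

#: Attenuation grows with body mass; a(m) = exp(c * m) with c per kg.
ATTENUATION_PER_KG = 0.02

DEFAULT_GRID_SHAPE = (48, 48, 32)
DEFAULT_VOXEL_SIZE = (4.0, 4.0, 4.0)
DEFAULT_LUNG_SUV = 0.5


@dataclass(frozen=True)
class LesionSpec:
    """One spherical lesion: center in voxel coordinates, volume, uptake."""

    center: tuple[float, float, float]
    volume_ml: float
    suv: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError(f"lesion volume must be positive, got {self.volume_ml}")
        if self.suv < 0:
            raise ValueError(f"lesion SUV must be nonnegative, got {self.suv}")

    @property
    def radius_mm(self) -> float:
        return float((3.0 * self.volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``sensitivity`` is the composite scanner factor (proportionality
    constant x reconstruction noise-reduction x scanner sensitivity);
    together with ``attenuation_factor`` it determines the subject's
    theoretical count sensitivity, but the per-subject factor used in the
    count-response models is always estimated empirically downstream.
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    weight: float = 58.53
    injected_dose: float = INJECTED_DOSE_MEAN
    scan_time: float = SCAN_TIME_S
    liver_suv: float = LIVER_SUV_MEAN
    lung_suv: float = DEFAULT_LUNG_SUV
    lesions: tuple[LesionSpec, ...] = ()
    attenuation_factor: float = 1.0
    sensitivity: float = 1.0
    total_true_counts: int = 0
    randoms_fraction: float = 0.0
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        if min(self.liver_suv, self.lung_suv) < 0:
            raise ValueError("SUV values must be nonnegative")
        if self.total_true_counts < 0:
            raise ValueError("total_true_counts must be >= 0")
        if self.attenuation_factor < 1.0:
            raise ValueError("attenuation_factor must be >= 1")
        if not 0.0 <= self.randoms_fraction < 1.0:
            raise ValueError("randoms_fraction must be in [0, 1)")
        if len(self.grid_shape) != 3 or any(n < 4 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes of >= 4 voxels, got {self.grid_shape}")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lesions"] = [dataclasses.asdict(l) for l in self.lesions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["lesions"] = tuple(LesionSpec(tuple(l["center"]), l["volume_ml"], l["suv"]) for l in d["lesions"])
        for key in ("grid_shape", "voxel_size"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ActivityPhantom:
    """Voxelized activity (SUV) map with a compartment label map.

    Labels: 0 = air, 1 = lung background, 2 = liver, 3+ = lesions in the
    order given in ``spec.lesions``.
    """

    suv_map: np.ndarray
    label_map: np.ndarray
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if self.suv_map.shape != self.label_map.shape:
            raise ValueError("suv_map and label_map must share a grid")
        if np.any(self.suv_map < 0):
            raise ValueError("suv_map must be nonnegative")


@dataclass
class EventStream:
    """Ordered list of coincidence events.

    ``bin_index`` addresses either flattened image voxels or flattened
    sinogram bins depending on ``domain``.  True and random (delayed)
    events are interleaved in randomized order; ``is_random`` flags the
    randoms.
    """

    bin_index: np.ndarray
    is_random: np.ndarray
    domain: str = "image"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_index = np.asarray(self.bin_index)
        self.is_random = np.asarray(self.is_random, dtype=bool)
        if self.bin_index.shape != self.is_random.shape:
            raise ValueError("bin_index and is_random must have equal length")
        if self.domain not in ("image", "sinogram"):
            raise ValueError(f"unknown domain {self.domain!r}")

    def __len__(self) -> int:
        return int(self.bin_index.size)

    @property
    def n_events(self) -> int:
        return len(self)

    @property
    def n_random(self) -> int:
        return int(self.is_random.sum())

    @property
    def n_true(self) -> int:
        return len(self) - self.n_random


def effective_dose(activity_mbq: float) -> float:
    """Effective dose in mSv for an injected 18F-FDG activity in MBq.

    Uses the ICRP adult coefficient of 0.019 mSv/MBq, so a typical 370 MBq
    (10 mCi) administration maps to about 7 mSv.
    """
    if activity_mbq < 0:
        raise ValueError(f"activity must be nonnegative, got {activity_mbq}")
    return activity_mbq * EFFECTIVE_DOSE_MSV_PER_MBQ


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float,
                      high: float = np.inf, size: int | None = None) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds far out in the tail here)."""
    n = 1 if size is None else size
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        ok = draw[(draw > low) & (draw < high)]
        out[filled:filled + ok.size] = ok
        filled += ok.size
    return out[0] if size is None else out


def thorax_masks(grid_shape: Sequence[int], voxel_size: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Body and liver masks for the default thorax layout.

    The body is an elliptical cylinder spanning all axial slices; the liver
    is a sphere in the lower-posterior part of the body.  Returns
    ``(body, liver)`` boolean arrays; lung tissue is ``body & ~liver``.
    """
    nx, ny, nz = grid_shape
    dx, dy, dz = voxel_size
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    ax, ay = 0.42 * nx * dx, 0.42 * ny * dy
    body = (X / ax) ** 2 + (Y / ay) ** 2 <= 1.0

    r_liver = 0.125 * min(nx * dx, ny * dy)
    cy = 0.22 * ny * dy
    cz = -0.20 * nz * dz
    liver = (X ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) <= r_liver ** 2
    liver &= body
    return body, liver


def _rasterize_sphere(grid_shape: Sequence[int], voxel_size: Sequence[float],
                      center: Sequence[float], volume_ml: float) -> np.ndarray:
    """Sphere mask holding the nearest round(volume / voxel_volume) voxels.

    Taking exactly the k voxel centers closest to the sphere center keeps
    the rasterized volume within half a voxel volume of the request, for
    any radius.  Ties are broken by flat voxel index for determinism.
    """
    voxel_volume_ml = float(np.prod(voxel_size)) / 1000.0
    k = max(1, round(volume_ml / voxel_volume_ml))
    radius_mm = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    # Restrict the candidate search to a bounding box around the sphere.
    lo = [max(0, int(np.floor(c - 2 - radius_mm / s))) for c, s in zip(center, voxel_size)]
    hi = [min(n, int(np.ceil(c + 3 + radius_mm / s))) for c, s, n in zip(center, voxel_size, grid_shape)]
    axes = [np.arange(l, h) for l, h in zip(lo, hi)]
    II, JJ, KK = np.meshgrid(*axes, indexing="ij")
    d2 = ((II - center[0]) * voxel_size[0]) ** 2 + \
         ((JJ - center[1]) * voxel_size[1]) ** 2 + \
         ((KK - center[2]) * voxel_size[2]) ** 2
    flat = np.ravel_multi_index((II.ravel(), JJ.ravel(), KK.ravel()), tuple(grid_shape))
    order = np.lexsort((flat, d2.ravel()))
    if k > order.size:
        raise ValueError("lesion does not fit inside the grid")
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    mask.ravel()[flat[order[:k]]] = True
    return mask


def build_phantom(spec: PhantomSpec) -> ActivityPhantom:
    """Rasterize a PhantomSpec into SUV and label maps.

    Raises ``ValueError`` if a lesion leaves the lung compartment or
    overlaps the liver or another lesion.
    """
    body, liver = thorax_masks(spec.grid_shape, spec.voxel_size)
    label = np.zeros(spec.grid_shape, dtype=np.int32)
    label[body] = 1
    label[liver] = 2
    suv = np.zeros(spec.grid_shape, dtype=np.float64)
    suv[label == 1] = spec.lung_suv
    suv[label == 2] = spec.liver_suv

    for i, lesion in enumerate(spec.lesions):
        mask = _rasterize_sphere(spec.grid_shape, spec.voxel_size, lesion.center, lesion.volume_ml)
        if np.any(mask & ~body):
            raise ValueError(f"lesion {i} extends outside the body")
        if np.any(mask & (label >= 2)):
            raise ValueError(f"lesion {i} overlaps liver or another lesion")
        label[mask] = 3 + i
        suv[mask] = lesion.suv
    return ActivityPhantom(suv_map=suv, label_map=label, spec=spec)


def _lesion_sites(rng: np.random.Generator, spec_shape: Sequence[int], voxel_size: Sequence[float],
                  radii_mm: Sequence[float]) -> list[tuple[float, float, float]]:
    """Sample non-overlapping lesion centers inside the lung compartment."""
    from scipy import ndimage

    body, liver = thorax_masks(spec_shape, voxel_size)
    lung = body & ~liver
    # Distance (mm) from each lung voxel to anything that is not lung.
    dist = ndimage.distance_transform_edt(lung, sampling=voxel_size)
    centers: list[tuple[float, float, float]] = []
    for r in radii_mm:
        # 2-voxel margin keeps room for the dilated background shell.
        margin = r + 2.0 * max(voxel_size)
        candidates = np.argwhere(dist > margin)
        rng.shuffle(candidates)
        placed = False
        for cand in candidates[:500]:
            c = tuple(float(v) for v in cand)
            ok = all(
                np.sqrt(sum(((a - b) * s) ** 2 for a, b, s in zip(c, prev, voxel_size)))
                > r + rp + 2.0 * max(voxel_size)
                for prev, rp in zip(centers, radii_mm)
            )
            if ok:
                centers.append(c)
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place lesion inside the lung compartment")
    return centers


def sample_cohort(n_subjects: int, master_seed: int, scale: float = 1.0,
                  grid_shape: Sequence[int] = DEFAULT_GRID_SHAPE,
                  voxel_size: Sequence[float] = DEFAULT_VOXEL_SIZE,
                  lung_suv: float = DEFAULT_LUNG_SUV,
                  randoms_fraction: float = 0.0) -> list[PhantomSpec]:
    """Draw a synthetic cohort of PhantomSpecs.

    Weights are uniform over 45-79 kg; liver SUV normal(1.57, 0.40)
    truncated positive; lesion SUV normal(1.92, 0.95) truncated at 0.5;
    lesion volumes uniform over 1.2-17.58 ml; net true counts
    normal(1.32e8, 3.91e7) x ``scale``, truncated positive.  ``scale``
    shrinks the full-statistics count level for desk-scale runs without
    touching any other cohort parameter.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    rng = np.random.default_rng(master_seed)
    specs = []
    for i in range(n_subjects):
        weight = float(rng.uniform(*WEIGHT_RANGE_KG))
        liver_suv = float(_truncated_normal(rng, LIVER_SUV_MEAN, LIVER_SUV_SD, 0.0))
        dose = float(_truncated_normal(rng, INJECTED_DOSE_MEAN, INJECTED_DOSE_SD,
                                       INJECTED_DOSE_RANGE[0], INJECTED_DOSE_RANGE[1]))
        counts = float(_truncated_normal(rng, TRUE_COUNTS_MEAN, TRUE_COUNTS_SD, 0.0)) * scale
        n_lesions = 1 if rng.random() < 0.75 else 2
        volumes = rng.uniform(*LESION_VOLUME_RANGE_ML, size=n_lesions)
        suvs = _truncated_normal(rng, LESION_SUV_MEAN, LESION_SUV_SD, LESION_SUV_MIN, size=n_lesions)
        radii = [(3.0 * v * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0) for v in volumes]
        centers = _lesion_sites(rng, grid_shape, voxel_size, radii)
        lesions = tuple(LesionSpec(c, float(v), float(s)) for c, v, s in zip(centers, volumes, suvs))
        specs.append(PhantomSpec(
            grid_shape=tuple(grid_shape),
            voxel_size=tuple(voxel_size),
            weight=weight,
            injected_dose=dose,
            scan_time=SCAN_TIME_S,
            liver_suv=liver_suv,
            lung_suv=lung_suv,
            lesions=lesions,
            attenuation_factor=float(np.exp(ATTENUATION_PER_KG * weight)),
            sensitivity=1.0,
            total_true_counts=int(round(counts)),
            randoms_fraction=randoms_fraction,
            subject_id=f"s{i:03d}",
        ))
    return specs


def generate_events(phantom: ActivityPhantom, seed: int) -> EventStream:
    """Draw the full-statistics event stream for a phantom.

    Exactly ``total_true_counts`` true events are distributed over voxels
    multinomially with probability proportional to the SUV map (fixed-total
    convention).  Randoms, if requested, are drawn uniformly over the
    occupied field (body voxels) with
    ``n_random = round(randoms_fraction * n_true / (1 - randoms_fraction))``
    so that randoms_fraction = n_random / n_events.  Event order is
    randomized.
    """
    spec = phantom.spec
    n_true = spec.total_true_counts
    total = float(phantom.suv_map.sum())
    if n_true > 0 and total <= 0:
        raise ValueError("cannot draw events from an all-zero activity map")
    rng = np.random.default_rng(seed)
    if n_true > 0:
        p = (phantom.suv_map / total).ravel()
        counts = rng.multinomial(n_true, p)
        true_idx = np.repeat(np.arange(counts.size, dtype=np.int64), counts)
    else:
        true_idx = np.empty(0, dtype=np.int64)

    rf = spec.randoms_fraction
    n_random = int(round(rf * n_true / (1.0 - rf))) if rf > 0 else 0
    if n_random > 0:
        occupied = np.flatnonzero(phantom.label_map.ravel() > 0)
        random_idx = rng.choice(occupied, size=n_random, replace=True)
    else:
        random_idx = np.empty(0, dtype=np.int64)

    bin_index = np.concatenate([true_idx, random_idx])
    is_random = np.zeros(bin_index.size, dtype=bool)
    is_random[n_true:] = True
    order = rng.permutation(bin_index.size)
    return EventStream(
        bin_index=bin_index[order],
        is_random=is_random[order],
        domain="image",
        provenance={"subject": spec.subject_id, "fraction": 1.0,
                    "realization": None, "seed": int(seed)},
    )
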