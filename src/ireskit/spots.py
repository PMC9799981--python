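"""Nuclear RNA foci detection, per-cell counting, and two-channel colocalization.

Implements the quantification chain used for smFISH/FISH imaging of nuclear
bodies (e.g. Neat1-scaffolded paraspeckles): segment nuclei on the DAPI
channel, detect diffraction-limited spots as local maxima of a negated
Laplacian-of-Gaussian (LoG) response, count foci per segmented nucleus, and
call colocalization between two channels by inter-spot distance.

Coordinates are 0-based pixel indices in (z, y, x) / (y, x) order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

#: canonical channel names
DAPI, CY3, CY5 = "DAPI", "Cy3", "Cy5"

SPOT_COLUMNS = ["z", "y", "x", "channel", "response", "cell_label"]


@dataclass
class ImageStack:
    """Multi-channel fluorescence image, 2D (y, x) or 3D (z, y, x).

    Parameters
    ----------
    channels
        Mapping channel name -> pixel array.  All channels must share one
        shape and be non-negative.
    voxel_size
        Physical size of one voxel in µm, one entry per axis
        (e.g. ``(0.45, 0.1, 0.1)`` for a confocal stack with 0.45 µm z-step).
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"channel {ch!r} has negative intensities")
            self.channels[ch] = arr
        if self.voxel_size is not None:
            vs = tuple(float(v) for v in self.voxel_size)
            if len(vs) != self.ndim:
                raise ValueError("voxel_size length must match image dimensionality")
            if any(v <= 0 for v in vs):
                raise ValueError("voxel sizes must be positive")
            self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not in stack (have {sorted(self.channels)})")
        return self.channels[name]


@dataclass
class NucleusMask:
    """Integer label image: 0 = background, k = nucleus k (labels 1..n)."""

    labels: np.ndarray
    areas: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) and not np.array_equal(present, np.arange(1, len(present) + 1)):
            raise ValueError("labels must be contiguous 1..n")
        if self.areas.empty and len(present):
            self.areas = pd.Series(
                ndimage.sum_labels(np.ones_like(self.labels), self.labels, present),
                index=present,
            )

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())


def segment_nuclei(
    image: ImageStack,
    channel: str = DAPI,
    min_area: int = 50,
    smooth_sigma: float = 2.0,
    declump_min_distance: int | None = None,
) -> NucleusMask:
    """Segment nuclei on a nuclear-stain channel.

    Gaussian smoothing, Otsu threshold, hole filling, small-object removal,
    then distance-transform watershed to split touching nuclei.  A blank
    channel yields an empty mask with a warning rather than an error.
    """
    img = image.channel(channel)
    if image.ndim == 3:
        img = img.max(axis=0)  # segment nuclei on the projection
    if img.max() == img.min():
        warnings.warn("nuclear channel is constant; returning empty mask", stacklevel=2)
        return NucleusMask(np.zeros(img.shape, dtype=int))
    smoothed = ndimage.gaussian_filter(img, smooth_sigma)
    binary = smoothed > threshold_otsu(smoothed)
    binary = ndimage.binary_fill_holes(binary)
    binary = remove_small_objects(binary, max_size=min_area - 1)
    if not binary.any():
        warnings.warn("no nuclei above min_area; returning empty mask", stacklevel=2)
        return NucleusMask(np.zeros(img.shape, dtype=int))

    # declump: seeds = maxima of the distance transform
    dist = ndimage.distance_transform_edt(binary)
    if declump_min_distance is None:
        declump_min_distance = max(3, int(np.sqrt(min_area / np.pi)))
    coords = peak_local_max(
        dist, min_distance=declump_min_distance, labels=binary, exclude_border=False
    )
    seeds = np.zeros(dist.shape, dtype=int)
    for k, c in enumerate(coords, start=1):
        seeds[tuple(c)] = k
    if seeds.max() == 0:
        labels, _ = ndimage.label(binary)
    else:
        labels = watershed(-dist, seeds, mask=binary)
    # drop declumped fragments below min_area, then relabel contiguously
    sizes = np.bincount(labels.ravel())
    too_small = np.flatnonzero(sizes < min_area)
    labels[np.isin(labels, too_small)] = 0
    labels, _ = _relabel(labels)
    logger.info("segmented %d nuclei (min_area=%d)", int(labels.max()), min_area)
    return NucleusMask(labels)


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(labels.max() + 1, dtype=int)
    lut[present] = np.arange(1, len(present) + 1)
    return lut[labels], len(present)


def log_response(img: np.ndarray, sigma: float) -> np.ndarray:
    """Negated Laplacian-of-Gaussian response; bright blobs become positive peaks."""
    return -ndimage.gaussian_laplace(np.asarray(img, dtype=float), sigma)


def detect_spots(
    image: ImageStack,
    channel: str,
    log_sigma: float = 1.5,
    threshold: float | None = None,
    mask: NucleusMask | None = None,
    project: bool | None = None,
    threshold_nsigma: float = 5.0,
) -> pd.DataFrame:
    """Detect diffraction-limited spots as local maxima of the LoG response.

    Parameters
    ----------
    log_sigma
        Scale of the Laplacian-of-Gaussian filter in pixels (≈ PSF sd).
    threshold
        Minimum LoG response.  When ``None`` a robust automatic threshold
        ``median + threshold_nsigma · 1.4826·MAD`` of the response is used.
    mask
        Optional nucleus mask used to assign each spot a ``cell_label``
        (0 when outside every nucleus).
    project
        Maximum-intensity project 3D stacks before detection.  Default:
        analyze in 3D when voxel metadata is present, else project.

    Returns
    -------
    DataFrame with columns ``z, y, x, channel, response, cell_label``
    (z is 0 for 2D data).  Plateaus of equal response contribute their
    centroid once.
    """
    if log_sigma <= 0:
        raise ValueError("log_sigma must be positive")
    img = image.channel(channel)
    is3d = image.ndim == 3
    if is3d and project is None:
        project = image.voxel_size is None
    if is3d and project:
        img = img.max(axis=0)
        is3d = False

    resp = log_response(img, log_sigma)
    if threshold is None:
        med = np.median(resp)
        mad = np.median(np.abs(resp - med))
        threshold = med + threshold_nsigma * 1.4826 * mad

    footprint = np.ones((3,) * resp.ndim, dtype=bool)  # 8-/26-connectivity
    is_max = (resp == ndimage.maximum_filter(resp, footprint=footprint)) & (resp > threshold)
    # plateau handling: one spot per connected plateau, at its centroid
    plat, n_plat = ndimage.label(is_max, structure=footprint)
    rows: list[dict] = []
    if n_plat:
        centroids = ndimage.center_of_mass(is_max, plat, np.arange(1, n_plat + 1))
        peaks = ndimage.maximum(resp, plat, np.arange(1, n_plat + 1))
        for c, r in zip(np.atleast_2d(centroids), np.atleast_1d(peaks)):
            coord = tuple(float(v) for v in c)
            if is3d:
                z, y, x = coord
            else:
                z, (y, x) = 0.0, coord
            rows.append({"z": z, "y": y, "x": x, "channel": channel, "response": float(r)})
    spots = pd.DataFrame(rows, columns=SPOT_COLUMNS[:-1])
    spots["cell_label"] = _assign_nuclei(spots, mask)
    return spots.reset_index(drop=True)


def _assign_nuclei(spots: pd.DataFrame, mask: NucleusMask | None) -> np.ndarray:
    if mask is None or spots.empty:
        return np.zeros(len(spots), dtype=int)
    yy = np.clip(np.rint(spots["y"]).astype(int), 0, mask.labels.shape[-2] - 1)
    xx = np.clip(np.rint(spots["x"]).astype(int), 0, mask.labels.shape[-1] - 1)
    if mask.labels.ndim == 3:
        zz = np.clip(np.rint(spots["z"]).astype(int), 0, mask.labels.shape[0] - 1)
        return mask.labels[zz, yy, xx]
    return mask.labels[yy, xx]


@dataclass
class FociSummary:
    """Per-cell focus counts, over all segmented cells including empty ones."""

    per_cell: pd.Series  # index = nucleus label, value = focus count
    mean_per_cell: float
    fraction_with_focus: float
    n_cells: int


def count_foci(spots: pd.DataFrame, mask: NucleusMask) -> FociSummary:
    """Count foci per segmented nucleus.

    Cytoplasmic spots (``cell_label == 0``) are excluded; zero-focus nuclei
    count toward the mean and the fraction of cells with ≥ 1 focus.
    """
    if mask.n_nuclei == 0:
        raise ValueError("empty nucleus mask: no cells to normalize by")
    labels = pd.RangeIndex(1, mask.n_nuclei + 1)
    assigned = spots.loc[spots["cell_label"] > 0, "cell_label"]
    per_cell = assigned.value_counts().reindex(labels, fill_value=0).sort_index()
    mean = float(per_cell.mean())
    frac = float((per_cell >= 1).mean())
    return FociSummary(per_cell, mean, frac, mask.n_nuclei)


@dataclass
class ColocResult:
    """One-to-one matched spot pairs within a distance threshold."""

    pairs: pd.DataFrame  # columns idA, idB, distance (µm)
    per_cell: pd.Series  # colocalized count per nucleus label of the A spots
    max_dist: float

    @property
    def n_colocalized(self) -> int:
        return len(self.pairs)


def colocalize(
    spots_a: pd.DataFrame,
    spots_b: pd.DataFrame,
    max_dist: float = 0.3,
    voxel_size: tuple[float, ...] | None = None,
) -> ColocResult:
    """Greedy one-to-one nearest-neighbour matching of two spot sets.

    Candidate pairs are visited in increasing distance; each spot joins at
    most one pair and pairs farther apart than ``max_dist`` (µm) are
    rejected, so the colocalized count is ≤ min(|A|, |B|).

    ``voxel_size`` converts pixel coordinates to µm (one factor per axis,
    (z,)y,x order).  When omitted, coordinates are assumed isotropic with
    unit pixel size and ``max_dist`` is interpreted in pixels.
    """
    axes = ["z", "y", "x"]
    a = spots_a[axes].to_numpy(dtype=float)
    b = spots_b[axes].to_numpy(dtype=float)
    if voxel_size is not None:
        scale = np.ones(3)
        scale[-len(voxel_size):] = voxel_size
        if len(voxel_size) == 2 and (a[:, 0].any() or b[:, 0].any()):
            raise ValueError("3D coordinates require a 3-axis voxel_size")
        a = a * scale
        b = b * scale
    pairs = []
    if len(a) and len(b):
        d = cdist(a, b)
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_a: set[int] = set()
        used_b: set[int] = set()
        for i, j in order:
            if d[i, j] > max_dist:
                break
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append((int(spots_a.index[i]), int(spots_b.index[j]), float(d[i, j])))
    pairs_df = pd.DataFrame(pairs, columns=["idA", "idB", "distance"])
    if len(pairs_df) and "cell_label" in spots_a:
        cells = spots_a.loc[pairs_df["idA"], "cell_label"]
        per_cell = cells[cells > 0].value_counts().sort_index()
    else:
        per_cell = pd.Series(dtype=int)
    return ColocResult(pairs_df, per_cell, float(max_dist))
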