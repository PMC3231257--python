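"""Local binary pattern (LBP) texture features for grayscale face images.

The LBP operator labels each pixel by thresholding a circular neighborhood
at the center intensity and reading the resulting bits as an integer.
Histograms of the labels over a grid of image regions, concatenated into a
single spatially enhanced histogram, describe both local texture and its
spatial layout.  With the 59-bin uniform (u2) operator and a 6x7 region
grid on a 110x150 face crop the descriptor has 59 * 42 = 2478 entries.

Conventions (frozen; raw label values depend on them):

* threshold: neighbor >= center sets the bit;
* bit order: sampling point p contributes bit p (p = 0 least significant);
* geometry: p = 0 lies straight "up" (decreasing row) and p increases
  counter-clockwise, i.e. sample p sits at
  (row - R*cos(2*pi*p/P), col - R*sin(2*pi*p/P));
* labels are computed only where the full neighborhood fits: a border of
  ceil(R) pixels is excluded, and region grids partition the labeled area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import SimilarityTransform, warp

__all__ = [
    "LbpParams",
    "RegionGrid",
    "EyePair",
    "basic_lbp",
    "circular_lbp",
    "is_uniform",
    "count_transitions",
    "build_u2_mapping",
    "label_histogram",
    "partition_grid",
    "extract_lbp_features",
    "normalize_face",
    "FACE_SHAPE",
    "EYE_DISTANCE",
]

#: Output geometry of :func:`normalize_face`: (rows, cols) and eye distance in px.
FACE_SHAPE = (150, 110)
EYE_DISTANCE = 55.0


@dataclass(frozen=True)
class LbpParams:
    """Circular LBP operator settings.

    P is the number of equally spaced sampling points on a circle of
    radius R (pixels).  ``uniform`` selects the u2 mapping: each pattern
    with at most two circular 0/1 transitions gets its own histogram bin
    and all remaining patterns share one bin (59 bins for P = 8).
    """

    P: int = 8
    R: float = 2.0
    uniform: bool = True

    def __post_init__(self) -> None:
        if self.P < 4:
            raise ValueError(f"P must be >= 4, got {self.P}")
        if self.R <= 0:
            raise ValueError(f"R must be > 0, got {self.R}")

    @property
    def n_labels(self) -> int:
        """Number of distinct labels the operator produces."""
        if self.uniform:
            # P*(P-1) rotations of uniform blocks + two constant patterns + 1 shared
            return self.P * (self.P - 1) + 3
        return 2**self.P


@dataclass(frozen=True)
class RegionGrid:
    """Exact tiling of a labeled area into near-equal rectangular regions."""

    row_edges: tuple[int, ...]
    col_edges: tuple[int, ...]

    @property
    def n_rows(self) -> int:
        return len(self.row_edges) - 1

    @property
    def n_cols(self) -> int:
        return len(self.col_edges) - 1

    @property
    def n_regions(self) -> int:
        return self.n_rows * self.n_cols

    def regions(self):
        """Yield (r0, r1, c0, c1) extents in row-major order."""
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                yield (
                    self.row_edges[i],
                    self.row_edges[i + 1],
                    self.col_edges[j],
                    self.col_edges[j + 1],
                )


@dataclass(frozen=True)
class EyePair:
    """Eye centers in (x, y) = (col, row) pixel coordinates, left.x < right.x."""

    left: tuple[float, float]
    right: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.left[0] < self.right[0]:
            raise ValueError("left eye must have smaller x than right eye")


def _as_image(img) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    return arr


def basic_lbp(img) -> np.ndarray:
    """Label an image with the basic 3x3 LBP operator.

    Returns an (H-2) x (W-2) integer array of labels in [0, 255]; a
    1-pixel border is excluded because the 3x3 neighborhood does not fit.
    """
    arr = _as_image(img)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got {arr.shape}")
    center = arr[1:-1, 1:-1]
    labels = np.zeros(center.shape, dtype=np.int64)
    # 3x3 ring in the circular convention: p=0 up, counter-clockwise
    offsets = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]
    h, w = center.shape
    for p, (dr, dc) in enumerate(offsets):
        neigh = arr[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        labels |= (neigh >= center).astype(np.int64) << p
    return labels


def _bilinear(arr: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at (r, c); exact when coordinates are integral."""
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    fr = r - r0
    fc = c - c0
    r1 = np.minimum(r0 + 1, arr.shape[0] - 1)
    c1 = np.minimum(c0 + 1, arr.shape[1] - 1)
    v00 = arr[r0, c0]
    v01 = arr[r0, c1]
    v10 = arr[r1, c0]
    v11 = arr[r1, c1]
    # incremental form: exact (no rounding drift) on constant neighborhoods
    top = v00 + fr * (v10 - v00)
    bot = v01 + fr * (v11 - v01)
    return top + fc * (bot - top)


def sampling_offsets(params: LbpParams) -> np.ndarray:
    """(P, 2) array of (d_row, d_col) sampling offsets for the operator."""
    p = np.arange(params.P)
    theta = 2.0 * np.pi * p / params.P
    dr = -params.R * np.cos(theta)
    dc = -params.R * np.sin(theta)
    # snap coordinates that are integral up to fp noise so that e.g. (8, 1)
    # hits the pixel grid exactly at the four axis-aligned samples
    dr = np.where(np.abs(dr - np.round(dr)) < 1e-9, np.round(dr), dr)
    dc = np.where(np.abs(dc - np.round(dc)) < 1e-9, np.round(dc), dc)
    return np.column_stack([dr, dc])


def circular_lbp(img, params: LbpParams, interpolation: str = "bilinear") -> np.ndarray:
    """Label an image with the circular (P, R) LBP operator.

    Non-integer sampling coordinates are bilinearly interpolated
    (``interpolation="nearest"`` rounds them to the pixel grid instead).
    The returned raw labels lie in [0, 2**P - 1]; apply
    :func:`build_u2_mapping` for the uniform-pattern binning.  A border of
    ceil(R) pixels is excluded.
    """
    arr = _as_image(img)
    b = math.ceil(params.R)
    h = arr.shape[0] - 2 * b
    w = arr.shape[1] - 2 * b
    if h <= 0 or w <= 0:
        raise ValueError(
            f"image {arr.shape} has no valid interior for radius {params.R}"
        )
    center = arr[b : b + h, b : b + w]
    rr, cc = np.meshgrid(
        np.arange(b, b + h, dtype=np.float64),
        np.arange(b, b + w, dtype=np.float64),
        indexing="ij",
    )
    labels = np.zeros(center.shape, dtype=np.int64)
    for p, (dr, dc) in enumerate(sampling_offsets(params)):
        r = rr + dr
        c = cc + dc
        if interpolation == "nearest":
            sample = arr[np.round(r).astype(np.int64), np.round(c).astype(np.int64)]
        elif interpolation == "bilinear":
            sample = _bilinear(arr, r, c)
        else:
            raise ValueError(f"unknown interpolation {interpolation!r}")
        labels |= (sample >= center).astype(np.int64) << p
    return labels


def count_transitions(pattern: int, P: int) -> int:
    """Number of 0/1 changes in the length-P circular bit string."""
    rotated = ((pattern >> 1) | ((pattern & 1) << (P - 1))) & ((1 << P) - 1)
    return int(bin(pattern ^ rotated).count("1"))


def is_uniform(pattern: int | str, P: int | None = None) -> bool:
    """True iff the circular bit string has at most two 0/1 transitions."""
    if isinstance(pattern, str):
        if not set(pattern) <= {"0", "1"}:
            raise ValueError(f"not a bit string: {pattern!r}")
        P = len(pattern)
        pattern = int(pattern, 2)
    if P is None:
        raise ValueError("P is required when pattern is given as an integer")
    return count_transitions(pattern, P) <= 2


def build_u2_mapping(P: int) -> np.ndarray:
    """Raw-label -> bin-index table for the u2 (uniform) operator.

    Each uniform pattern gets its own bin, in increasing raw-label order;
    every non-uniform pattern maps to one shared final bin.  For P = 8 the
    table has 59 distinct bins.
    """
    if P < 4:
        raise ValueError(f"P must be >= 4, got {P}")
    n_patterns = 1 << P
    uniform = np.fromiter(
        (count_transitions(x, P) <= 2 for x in range(n_patterns)),
        dtype=bool,
        count=n_patterns,
    )
    mapping = np.empty(n_patterns, dtype=np.int64)
    n_uniform = int(uniform.sum())
    mapping[uniform] = np.arange(n_uniform)
    mapping[~uniform] = n_uniform  # shared bin for all non-uniform patterns
    return mapping


def label_histogram(labels, region: tuple[int, int, int, int] | None, n_labels: int) -> np.ndarray:
    """Histogram of label counts over a (r0, r1, c0, c1) region.

    The histogram sums exactly to the number of labeled pixels in the
    region (integer conservation).
    """
    labels = np.asarray(labels)
    if region is not None:
        r0, r1, c0, c1 = region
        labels = labels[r0:r1, c0:c1]
    if labels.size == 0:
        raise ValueError("empty region")
    return np.bincount(labels.ravel(), minlength=n_labels)


def _edges(total: int, n_parts: int) -> tuple[int, ...]:
    if n_parts <= 0:
        raise ValueError(f"need at least one region, got {n_parts}")
    if n_parts > total:
        raise ValueError(f"cannot split {total} pixels into {n_parts} regions")
    base, rem = divmod(total, n_parts)
    sizes = [base + 1] * rem + [base] * (n_parts - rem)
    return tuple(np.concatenate([[0], np.cumsum(sizes)]).tolist())


def partition_grid(height: int, width: int, n_rows: int, n_cols: int) -> RegionGrid:
    """Tile a height x width area into n_rows x n_cols near-equal regions.

    Region heights (and widths) differ by at most one pixel and the
    regions tile the area exactly.  The default face grid is 7 rows x
    6 cols = 42 regions.
    """
    return RegionGrid(_edges(height, n_rows), _edges(width, n_cols))


def extract_lbp_features(
    img,
    params: LbpParams = LbpParams(),
    grid: RegionGrid | tuple[int, int] = (7, 6),
    normalize: bool = False,
) -> np.ndarray:
    """Spatially enhanced LBP histogram of an image.

    Labels the image with the circular operator (u2-mapped if
    ``params.uniform``), partitions the labeled area with ``grid``
    (either a RegionGrid or an (n_rows, n_cols) pair), histograms each
    region, and concatenates the per-region histograms row-major.  The
    result has length n_regions * n_labels: 42 * 59 = 2478 for the
    default settings on a 110x150 image.

    Histograms are raw counts unless ``normalize`` is set, in which case
    each region block is divided by its pixel count.
    """
    labels = circular_lbp(img, params)
    if params.uniform:
        labels = build_u2_mapping(params.P)[labels]
    n = params.n_labels
    if not isinstance(grid, RegionGrid):
        n_rows, n_cols = grid
        grid = partition_grid(labels.shape[0], labels.shape[1], n_rows, n_cols)
    else:
        if grid.row_edges[-1] != labels.shape[0] or grid.col_edges[-1] != labels.shape[1]:
            raise ValueError(
                f"grid {grid.row_edges[-1]}x{grid.col_edges[-1]} does not match "
                f"labeled area {labels.shape}"
            )
    blocks = []
    for r0, r1, c0, c1 in grid.regions():
        h = label_histogram(labels, (r0, r1, c0, c1), n).astype(np.float64)
        if normalize:
            h /= (r1 - r0) * (c1 - c0)
        blocks.append(h)
    return np.concatenate(blocks)


def normalize_face(img, eyes: EyePair) -> np.ndarray:
    """Geometrically normalize a face image from its eye centers.

    A similarity transform (rotation + uniform scale) brings the eye
    centers to a horizontal line 55 px apart, placed symmetrically about
    the vertical midline at one third of the output height, and a
    110-wide x 150-tall crop is taken — the crop geometry follows the
    rule of thumb that a face is about twice the inter-ocular distance
    wide and three times tall.  Bilinear resampling; regions falling
    outside the source are filled by edge replication with a warning.
    """
    arr = _as_image(img)
    lx, ly = eyes.left
    rx, ry = eyes.right
    if not (0 <= lx < arr.shape[1] and 0 <= rx < arr.shape[1]):
        raise ValueError("eye x-coordinates outside image")
    if not (0 <= ly < arr.shape[0] and 0 <= ry < arr.shape[0]):
        raise ValueError("eye y-coordinates outside image")
    dist = math.hypot(rx - lx, ry - ly)
    if dist < 1e-3:
        raise ValueError("degenerate eye pair: coincident centers")

    out_h, out_w = FACE_SHAPE
    eye_row = out_h / 3.0
    dst_left = np.array([(out_w - EYE_DISTANCE) / 2.0, eye_row])
    # closed-form two-point similarity: rotate the eye axis horizontal,
    # scale the inter-ocular distance to 55 px, translate the left eye
    scale = EYE_DISTANCE / dist
    rot = -math.atan2(ry - ly, rx - lx)
    tform = SimilarityTransform(scale=scale, rotation=rot)
    shift = dst_left - tform(np.array([[lx, ly]]))[0]
    tform = SimilarityTransform(scale=scale, rotation=rot, translation=shift)

    corners = np.array([[0, 0], [out_w - 1, 0], [0, out_h - 1], [out_w - 1, out_h - 1]])
    back = tform.inverse(corners)
    if (
        back[:, 0].min() < -0.5
        or back[:, 1].min() < -0.5
        or back[:, 0].max() > arr.shape[1] - 0.5
        or back[:, 1].max() > arr.shape[0] - 0.5
    ):
        warnings.warn(
            "crop extends beyond the source image; padding by edge replication",
            stacklevel=2,
        )
    out = warp(
        arr,
        tform.inverse,
        output_shape=FACE_SHAPE,
        order=1,
        mode="edge",
        preserve_range=True,
    )
    return out
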