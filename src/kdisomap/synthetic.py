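"""Deterministic synthetic data: swiss-roll benchmark and a labeled
expression-style image set.

The image generator emulates the statistical structure the embedding
pipeline assumes — several classes of textured 110x150 grayscale images,
each class tracing its own nonlinear manifold in pixel space, with
per-subject appearance variation — without attempting photorealism.
Each class is a procedural texture: an oriented sinusoidal grating whose
phase varies smoothly with a per-image latent parameter, plus a localized
Gaussian blob whose position moves along a class-specific circular path
with the same latent (so images of one class lie on a one-parameter
nonlinear curve in pixel space).  Each subject contributes a fixed smooth
low-frequency intensity field, and i.i.d. Gaussian pixel noise is added
before clipping to [0, 255].

``class_separation`` interpolates every class-specific parameter between
a common base value (0: all classes identically distributed) and its
fully distinct value (1, the default).  ``subject_variability`` scales
the subject fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SwissRollSample", "SyntheticExpressionSet", "make_swiss_roll",
           "make_expression_dataset"]


@dataclass
class SwissRollSample:
    """3-D swiss-roll points with their true unrolled 2-D coordinates.

    With zero noise the map from ``manifold_coords`` (arc length along the
    spiral, height) to ``points`` is an isometry, so true manifold
    distances are Euclidean distances in ``manifold_coords``.
    """

    points: np.ndarray  # (n, 3)
    manifold_coords: np.ndarray  # (n, 2)
    noise_sd: float
    seed: int


def make_swiss_roll(n: int, noise_sd: float = 0.0, seed: int = 0) -> SwissRollSample:
    """Sample n points from the classic swiss roll (t cos t, h, t sin t).

    t is uniform on [1.5*pi, 4.5*pi] and the height h uniform on [0, 10].
    The height range is chosen so that at the usual benchmark operating
    point (hundreds of points, 10 nearest neighbors) the neighborhood
    radius stays below half the 2*pi gap between adjacent windings even
    on the sparser outer winding — the neighborhood graph then follows
    the manifold instead of short-circuiting across windings.  The first
    manifold coordinate is the arc length along the spiral,
    s(t) = (t*sqrt(1+t^2) + asinh(t)) / 2, so the unrolled coordinates
    are exactly isometric to the noiseless roll.
    """
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    rng = np.random.default_rng(seed)
    t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, n)
    h = rng.uniform(0.0, 10.0, n)
    points = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    if noise_sd > 0:
        points = points + rng.normal(0.0, noise_sd, points.shape)
    s = 0.5 * (t * np.sqrt(1.0 + t**2) + np.arcsinh(t))
    return SwissRollSample(points, np.column_stack([s, h]), noise_sd, seed)


@dataclass
class SyntheticExpressionSet:
    """Labeled synthetic image set with per-subject structure."""

    images: list  # of (height, width) uint8 arrays
    labels: np.ndarray  # (n,) int class per image
    subjects: np.ndarray  # (n,) int subject per image
    latents: np.ndarray  # (n,) per-image manifold parameter in [0, 1)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)


def _subject_field(rng: np.random.Generator, shape: tuple[int, int],
                   amplitude: float) -> np.ndarray:
    """Smooth per-subject intensity surface: a few random low-freq cosines."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    out = np.zeros(shape)
    for _ in range(3):
        fx = rng.uniform(-1.0, 1.0) / w
        fy = rng.uniform(-1.0, 1.0) / h
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += np.cos(2.0 * np.pi * (fx * xx + fy * yy) + phase)
    return amplitude * out / 3.0


def make_expression_dataset(
    n_subjects: int = 20,
    images_per_subject_per_class: int = 2,
    n_classes: int = 7,
    class_separation: float = 1.0,
    subject_variability: float = 0.5,
    noise_sd: float = 4.0,
    height: int = 150,
    width: int = 110,
    seed: int = 0,
) -> SyntheticExpressionSet:
    """Generate a labeled, subject-structured synthetic image set.

    Every subject has ``images_per_subject_per_class`` images in every
    class (balanced, so subject-grouped CV folds are class-balanced in
    expectation).  Deterministic under ``seed``.
    """
    if n_subjects < 10:
        raise ValueError("need n_subjects >= 10 so 10-fold subject CV is possible")
    if images_per_subject_per_class < 1:
        raise ValueError("need at least one image per subject per class")
    if not 0.0 <= class_separation:
        raise ValueError(f"class_separation must be >= 0, got {class_separation}")
    if subject_variability < 0 or noise_sd < 0:
        raise ValueError("subject_variability and noise_sd must be >= 0")
    if n_classes < 2:
        raise ValueError("need at least two classes")

    rng = np.random.default_rng(seed)
    sep = float(class_separation)
    mid = (n_classes - 1) / 2.0

    # class texture parameters, interpolated toward a common base as sep -> 0
    base_theta = np.pi / 4.0
    base_freq = 0.09  # cycles per pixel
    thetas = base_theta + sep * (np.arange(n_classes) - mid) * (np.pi / n_classes)
    freqs = base_freq * (1.0 + sep * 0.20 * (np.arange(n_classes) - mid) / max(mid, 1.0))
    blob_phases = 2.0 * np.pi * np.arange(n_classes) / n_classes

    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0

    fields = [
        _subject_field(rng, (height, width), 25.0 * subject_variability)
        for _ in range(n_subjects)
    ]

    images, labels, subjects, latents = [], [], [], []
    for s in range(n_subjects):
        for c in range(n_classes):
            for _ in range(images_per_subject_per_class):
                u = rng.uniform(0.0, 1.0)  # per-image manifold latent
                grating = 55.0 * np.sin(
                    2.0 * np.pi * freqs[c] * (xx * np.cos(thetas[c]) + yy * np.sin(thetas[c]))
                    + 2.0 * np.pi * u
                )
                # blob center moves on a class-specific circular path with u
                ang = 2.0 * np.pi * u + sep * blob_phases[c]
                br = cy + sep * 30.0 * np.sin(ang)
                bc = cx + sep * 20.0 * np.cos(ang)
                blob = 45.0 * np.exp(-(((yy - br) ** 2) + ((xx - bc) ** 2)) / (2 * 12.0**2))
                img = 120.0 + grating + blob + fields[s]
                if noise_sd > 0:
                    img = img + rng.normal(0.0, noise_sd, img.shape)
                images.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
                labels.append(c)
                subjects.append(s)
                latents.append(u)

    return SyntheticExpressionSet(
        images=images,
        labels=np.asarray(labels),
        subjects=np.asarray(subjects),
        latents=np.asarray(latents),
        params=dict(
            n_subjects=n_subjects,
            images_per_subject_per_class=images_per_subject_per_class,
            n_classes=n_classes,
            class_separation=class_separation,
            subject_variability=subject_variability,
            noise_sd=noise_sd,
            height=height,
            width=width,
            seed=seed,
        ),
    )
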