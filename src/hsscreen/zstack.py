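"""Motion-based viability scoring of well image stacks.

The semi-automatic survival readout photographs a well 30 times at 0.5 s
intervals 24 h after the heat shock.  Dead worms are motionless, so their
silhouettes stay sharp across the stack; living worms move and blur.  This
module (a) renders synthetic stacks with known alive/dead worms so the
scorer can be validated end to end, and (b) scores viability by motion:

1. segment candidate worms on the first frame (intensity threshold via
   Otsu unless given, connected components, minimum-area filter);
2. per object, compute a motion score -- the mean absolute inter-frame
   intensity change within a dilated object mask, normalized by the
   object's contrast against the background;
3. objects at or below the motion threshold are dead, the rest alive;
   the survival rate is alive / detected.

Worms are rendered as dark ridges of Gaussian cross-section at floating
point coordinates, so sub-pixel motion changes pixel values smoothly.
Touching worms are not split; the synthetic generator keeps worms apart
and real images with merged objects should be treated with care.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: body-oscillation cycles of a living worm over one stack; an integer so
#: the net first-to-last displacement is exactly the drift
_WOBBLE_CYCLES = 5


@dataclass(frozen=True)
class WormSpec:
    """Ground truth for one rendered worm.

    ``points``: (n, 2) float array of centerline (row, col) coordinates.
    ``displacement``: net translation magnitude between the first and last
    frame, in pixels; exactly 0 for dead worms.
    ``heading``: direction (radians) of the translation.
    ``wobble``: amplitude in pixels of the perpendicular body oscillation
    of a living worm during the stack.
    """

    points: tuple[tuple[float, float], ...]
    alive: bool
    displacement: float = 0.0
    heading: float = 0.0
    wobble: float = 0.0

    def __post_init__(self) -> None:
        if not self.alive and self.displacement != 0.0:
            raise ValueError("dead worms must have zero displacement")
        if self.alive and self.displacement <= 0.0:
            raise ValueError("alive worms must have positive displacement")


@dataclass(frozen=True)
class ImageStackSpec:
    """Everything needed to render one synthetic well stack."""

    worms: tuple[WormSpec, ...]
    seed: int
    n_frames: int = 30
    interval_s: float = 0.5  # metadata only
    shape: tuple[int, int] = (256, 256)
    background: float = 0.85
    worm_intensity: float = 0.25
    worm_sigma: float = 1.6  # Gaussian half-width of the body cross-section
    noise_sd: float = 0.02

    @property
    def n_alive(self) -> int:
        return sum(w.alive for w in self.worms)


def _random_centerline(rng, shape, length: float, n_points: int = 40):
    # the walk starts at `start` and can extend a full body length away;
    # leave room for that plus the motion envelope
    margin = length + 14
    start = np.array(
        [
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        ]
    )
    heading = rng.uniform(0, 2 * math.pi)
    step = length / (n_points - 1)
    points = [start]
    for _ in range(n_points - 1):
        heading += rng.normal(0.0, 0.12)
        points.append(points[-1] + step * np.array([math.sin(heading), math.cos(heading)]))
    return np.array(points)


def random_stack_spec(
    seed: int,
    n_worms: int = 10,
    n_alive: int | None = None,
    shape: tuple[int, int] = (256, 256),
    worm_length: float = 40.0,
    min_separation: float = 40.0,
    displacement: float = 10.0,
    wobble: float = 2.5,
    **kwargs,
) -> ImageStackSpec:
    """Draw a random well: worm centerlines with enforced centroid
    separation, a random (or fixed) number of them alive.

    Alive worms receive a net translation of ``displacement`` pixels plus a
    perpendicular wobble; dead worms are static by construction.
    """
    rng = np.random.default_rng(seed)
    if n_alive is None:
        n_alive = int(rng.integers(0, n_worms + 1))
    if not 0 <= n_alive <= n_worms:
        raise ValueError("n_alive outside [0, n_worms]")
    centerlines = []
    centroids = []
    attempts = 0
    while len(centerlines) < n_worms:
        attempts += 1
        if attempts > 5000:
            raise ValueError(
                "cannot place worms with the requested separation; "
                "reduce n_worms or min_separation"
            )
        line = _random_centerline(rng, shape, worm_length)
        centroid = line.mean(axis=0)
        if all(np.linalg.norm(centroid - c) >= min_separation for c in centroids):
            centerlines.append(line)
            centroids.append(centroid)
    alive_flags = np.array([True] * n_alive + [False] * (n_worms - n_alive))
    rng.shuffle(alive_flags)
    worms = []
    for line, alive in zip(centerlines, alive_flags):
        worms.append(
            WormSpec(
                points=tuple(map(tuple, line)),
                alive=bool(alive),
                displacement=displacement if alive else 0.0,
                heading=float(rng.uniform(0, 2 * math.pi)) if alive else 0.0,
                wobble=wobble if alive else 0.0,
            )
        )
    return ImageStackSpec(worms=tuple(worms), seed=seed, shape=shape, **kwargs)


def _stamp_worm(depth: np.ndarray, points: np.ndarray, sigma: float) -> None:
    """Accumulate a worm body into a depth map via Gaussian stamps at float
    coordinates (max-combined so overlapping stamps do not over-darken)."""
    h, w = depth.shape
    r = int(math.ceil(3 * sigma))
    for row, col in points:
        r0, c0 = int(math.floor(row)), int(math.floor(col))
        rlo, rhi = max(r0 - r, 0), min(r0 + r + 2, h)
        clo, chi = max(c0 - r, 0), min(c0 + r + 2, w)
        if rlo >= rhi or clo >= chi:
            continue
        rr, cc = np.meshgrid(
            np.arange(rlo, rhi, dtype=float),
            np.arange(clo, chi, dtype=float),
            indexing="ij",
        )
        stamp = np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2))
        patch = depth[rlo:rhi, clo:chi]
        np.maximum(patch, stamp, out=patch)


def _worm_points_at(worm: WormSpec, t: int, n_frames: int) -> np.ndarray:
    points = np.asarray(worm.points, dtype=float)
    if not worm.alive:
        return points
    frac = t / (n_frames - 1)
    drift = worm.displacement * frac * np.array(
        [math.sin(worm.heading), math.cos(worm.heading)]
    )
    # perpendicular wobble, an integer number of cycles so the net
    # first-to-last displacement is exactly the drift
    perp = np.array([math.cos(worm.heading), -math.sin(worm.heading)])
    phase = np.linspace(0, 2 * math.pi, len(points))
    wobble = worm.wobble * math.sin(2 * math.pi * _WOBBLE_CYCLES * frac) * np.sin(phase)
    return points + drift + wobble[:, None] * perp


def render_stack(spec: ImageStackSpec) -> np.ndarray:
    """Render the stack: array of shape (n_frames, H, W), float in [0, 1].

    Deterministic for a given spec; dead worms are pixel-identical across
    frames before noise.
    """
    h, w = spec.shape
    for worm in spec.worms:
        points = np.asarray(worm.points)
        if (points < 0).any() or (points[:, 0] >= h).any() or (points[:, 1] >= w).any():
            raise ValueError("worm centerline outside frame bounds")
    _warn_if_crowded(spec)
    rng = np.random.default_rng(spec.seed)
    amplitude = spec.background - spec.worm_intensity
    frames = np.empty((spec.n_frames, h, w), dtype=float)
    for t in range(spec.n_frames):
        depth = np.zeros((h, w), dtype=float)
        for worm in spec.worms:
            _stamp_worm(depth, _worm_points_at(worm, t, spec.n_frames), spec.worm_sigma)
        frame = spec.background - amplitude * depth
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        frames[t] = np.clip(frame, 0.0, 1.0)
    return frames


def _warn_if_crowded(spec: ImageStackSpec) -> None:
    centroids = [np.asarray(w.points).mean(axis=0) for w in spec.worms]
    close = 0
    for i in range(len(centroids)):
        for j in range(i + 1, len(centroids)):
            if np.linalg.norm(centroids[i] - centroids[j]) < 4 * spec.worm_sigma + 6:
                close += 1
    if close:
        logger.warning(
            "%d worm pairs are close enough to overlap; segmentation may merge them",
            close,
        )


def zstack_project(frames: np.ndarray, mode: str = "min") -> np.ndarray:
    """Per-pixel projection of a stack into a single image.

    Minimum-intensity by default (dark worms on a light background: static
    worms stay sharp, movers smear into pale trails); ``mode="max"`` for
    inverted imagery.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("zstack_project requires >= 2 frames of equal dimensions")
    if mode == "min":
        return frames.min(axis=0)
    if mode == "max":
        return frames.max(axis=0)
    raise ValueError(f"unknown projection mode {mode!r}")


@dataclass
class ViabilityResult:
    """Outcome of scoring one well."""

    n_detected: int
    n_dead: int
    n_alive: int
    survival_rate: float  # nan when the well is empty
    motion_scores: tuple[float, ...] = ()
    empty_well: bool = False


def count_viability(
    frames: np.ndarray,
    segmentation_threshold: float | None = None,
    motion_threshold: float = 0.065,
    min_area: int = 30,
    dilation_radius: int = 3,
    min_contrast: float = 0.1,
) -> ViabilityResult:
    """Count dead and alive worms in a stack by per-object motion.

    ``segmentation_threshold`` defaults to Otsu's threshold of the first
    frame; thresholds and contrasts are all differences of intensities, so
    the whole procedure is invariant to a global intensity offset.
    ``min_contrast`` rejects candidate objects whose mean intensity sits
    less than that far below the background -- Otsu always splits an image
    somewhere, so a wormless noise-only well would otherwise segment into
    phantom objects.  ``motion_threshold`` is on the contrast-normalized
    motion score; at the default rendering noise the score of a static
    object is about 0.05 (pure sensor noise over the mask) while even
    slowly moving worms score above 0.08, so the default threshold sits in
    the gap.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("count_viability requires >= 2 frames")
    first = frames[0]
    if segmentation_threshold is None:
        from skimage.filters import threshold_otsu

        segmentation_threshold = float(threshold_otsu(first))
    mask = first < segmentation_threshold
    labels, n_labels = ndimage.label(mask)
    if n_labels == 0:
        return ViabilityResult(0, 0, 0, float("nan"), (), empty_well=True)
    areas = ndimage.sum_labels(np.ones_like(first), labels, index=range(1, n_labels + 1))
    keep = [i + 1 for i, a in enumerate(areas) if a >= min_area]
    background = float(np.median(first[~mask])) if (~mask).any() else float(first.max())
    keep = [
        lab
        for lab in keep
        if background - float(first[labels == lab].mean()) >= min_contrast
    ]
    if not keep:
        return ViabilityResult(0, 0, 0, float("nan"), (), empty_well=True)
    diffs = np.abs(np.diff(frames, axis=0)).mean(axis=0)
    structure = _disk_structure(dilation_radius)

    scores = []
    n_alive = 0
    for lab in keep:
        obj = labels == lab
        contrast = background - float(first[obj].mean())
        if contrast <= 0:
            logger.warning("object %d has non-positive contrast; scored as dead", lab)
            scores.append(0.0)
            continue
        dilated = ndimage.binary_dilation(obj, structure=structure)
        score = float(diffs[dilated].mean()) / contrast
        scores.append(score)
        if score > motion_threshold:
            n_alive += 1
    n_detected = len(keep)
    return ViabilityResult(
        n_detected=n_detected,
        n_dead=n_detected - n_alive,
        n_alive=n_alive,
        survival_rate=n_alive / n_detected,
        motion_scores=tuple(scores),
    )


def _disk_structure(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return (x**2 + y**2) <= radius**2


# ---------------------------------------------------------------------------
# stack I/O (multi-page TIFF or numbered PNG sequences)


def write_stack(frames: np.ndarray, path) -> None:
    """Write a stack as a multi-page 16-bit TIFF."""
    import tifffile

    data = np.clip(np.asarray(frames), 0.0, 1.0)
    tifffile.imwrite(str(path), (data * 65535).astype(np.uint16))


def read_stack(path) -> np.ndarray:
    """Read a stack from a multi-page TIFF or a directory of PNG frames,
    rescaled to floats in [0, 1]."""
    import os

    if os.path.isdir(path):
        import imageio.v3 as iio

        names = sorted(
            f for f in os.listdir(path) if f.lower().endswith((".png", ".tif", ".tiff"))
        )
        if len(names) < 2:
            raise ValueError(f"{path}: need at least 2 frames")
        frames = np.stack([iio.imread(os.path.join(path, n)) for n in names])
    else:
        import tifffile

        frames = tifffile.imread(str(path))
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        raise ValueError("a single frame is not a stack")
    if frames.max() > 1.0:
        frames = frames / (65535.0 if frames.max() > 255 else 255.0)
    return frames
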