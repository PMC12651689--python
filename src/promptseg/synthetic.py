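"""Seeded generators for prompt-conditioned synthetic scenes.

Two regimes emulate the benchmark settings the architecture targets:

* single-lesion "brain-like" scenes: one lesion per image drawn from
  three morphologies — irregular infiltrative blobs (glioma-like,
  low-order Fourier perturbation of a circle), smooth encapsulated discs
  (meningioma-like) and small compact ellipses (pituitary-like) — on a
  darker background, plus additive Gaussian noise;
* multi-organ "abdomen-like" scenes: four disjoint organ-like regions
  (one large lobed region, one mid-size disc, two small ellipses) with
  distinct intensities, placed by rejection sampling.

Multi-organ scenes always contain all four classes, so the correct mask
is unrecoverable from the image alone — the prompt carries the necessary
bit of information, which is exactly what makes the prompt-conditioning
experiments meaningful.

Images are generated on a [0, 1] intensity scale; the training
preprocessing maps them linearly to [-1, 1].  Everything is reproducible
from the seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

from .text import SynonymTable, build_prompt

DEFAULT_NOISE_SIGMA = 0.05


@dataclass
class ClassSpec:
    """One class of region: shape family, intensity range, size range (radius
    as a fraction of image size) and a horizontal placement band.

    The band (column range as fractions of width) lets organ classes be
    lateralized the way anatomy is — without it, two same-shaped organs
    would be distinguishable only by intensity, and under noise the class
    identity (hence the prompt) would be ill-posed."""

    name: str
    shape: str                      # irregular_blob | smooth_disc | small_ellipse | large_lobe
    intensity: tuple[float, float]
    size: tuple[float, float]
    band: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.size[0] > self.size[1] or self.size[0] <= 0:
            raise ValueError(f"degenerate size range for {self.name}: {self.size}")
        if not 0.0 <= self.band[0] < self.band[1] <= 1.0:
            raise ValueError(f"invalid placement band for {self.name}: {self.band}")


@dataclass
class SceneSpec:
    image_size: int = 128
    classes: list[ClassSpec] = field(default_factory=list)
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    background: float = 0.12

    def __post_init__(self):
        if self.image_size % 16 != 0:
            raise ValueError("image_size must be divisible by 16")
        names = [c.name for c in self.classes]
        if len(names) != len(set(names)):
            raise ValueError("class names must be unique")


def brain_spec(image_size: int = 128,
               noise_sigma: float = DEFAULT_NOISE_SIGMA) -> SceneSpec:
    """Single-lesion regime: three lesion morphologies."""
    return SceneSpec(image_size=image_size, noise_sigma=noise_sigma, classes=[
        ClassSpec("glioma", "irregular_blob", (0.55, 0.75), (0.10, 0.18)),
        ClassSpec("meningioma", "smooth_disc", (0.70, 0.90), (0.08, 0.14)),
        ClassSpec("pituitary", "small_ellipse", (0.60, 0.85), (0.04, 0.08)),
    ])


def organ_spec(image_size: int = 128,
               noise_sigma: float = DEFAULT_NOISE_SIGMA) -> SceneSpec:
    """Multi-organ regime: four disjoint regions of differing size/shape/intensity."""
    return SceneSpec(image_size=image_size, noise_sigma=noise_sigma, classes=[
        ClassSpec("liver", "large_lobe", (0.80, 0.92), (0.16, 0.22)),
        ClassSpec("spleen", "smooth_disc", (0.58, 0.68), (0.09, 0.13)),
        # kidneys are lateralized: same shape family, opposite sides
        ClassSpec("right_kidney", "small_ellipse", (0.42, 0.52), (0.06, 0.09),
                  band=(0.55, 1.0)),
        ClassSpec("left_kidney", "small_ellipse", (0.25, 0.35), (0.06, 0.09),
                  band=(0.0, 0.45)),
    ])


@dataclass
class ImageSample:
    """A grayscale image with per-class binary masks and (optionally) a prompt."""

    image: np.ndarray                 # (H, W) float in [0, 1]
    masks: dict[str, np.ndarray]      # class -> (H, W) uint8
    labels: list[str]
    prompt: str | None = None
    target_class: str | None = None   # class the prompt refers to

    @property
    def target_mask(self) -> np.ndarray:
        if self.target_class is None:
            raise ValueError("sample has no prompt target")
        return self.masks[self.target_class]


def _fourier_blob(rng: np.random.Generator, center, radius, shape,
                  roughness: float = 0.25, n_harmonics: int = 5,
                  aspect: float = 1.0, angle: float = 0.0) -> np.ndarray:
    """Rasterize a closed region whose radius is a low-order Fourier
    perturbation of a circle: r(t) = r0 (1 + sum_k a_k cos(k t + phi_k))."""
    t = np.linspace(0, 2 * np.pi, 180, endpoint=False)
    r = np.ones_like(t)
    for k in range(1, n_harmonics + 1):
        amp = roughness * rng.uniform(0, 1) / k
        r += amp * np.cos(k * t + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.3, None) * radius
    ys = r * np.sin(t) * aspect
    xs = r * np.cos(t)
    ca, sa = np.cos(angle), np.sin(angle)
    rows = center[0] + ys * ca - xs * sa
    cols = center[1] + ys * sa + xs * ca
    rr, cc = draw_polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def _draw_region(rng: np.random.Generator, cls: ClassSpec, size: int,
                 center) -> np.ndarray:
    radius = rng.uniform(*cls.size) * size
    shape = (size, size)
    if cls.shape == "irregular_blob":
        return _fourier_blob(rng, center, radius, shape, roughness=0.35)
    if cls.shape == "smooth_disc":
        return _fourier_blob(rng, center, radius, shape, roughness=0.04,
                             aspect=rng.uniform(0.9, 1.1))
    if cls.shape == "small_ellipse":
        return _fourier_blob(rng, center, radius, shape, roughness=0.03,
                             aspect=rng.uniform(0.55, 0.8),
                             angle=rng.uniform(0, np.pi))
    if cls.shape == "large_lobe":
        return _fourier_blob(rng, center, radius, shape, roughness=0.18,
                             n_harmonics=3, aspect=rng.uniform(0.7, 0.9),
                             angle=rng.uniform(0, np.pi))
    raise ValueError(f"unknown shape family {cls.shape!r}")


def _draw_center(rng: np.random.Generator, cls: ClassSpec,
                 size: int) -> tuple[float, float]:
    margin = int(cls.size[1] * size) + 2
    col_lo = max(margin, cls.band[0] * size)
    col_hi = min(size - margin, cls.band[1] * size)
    if col_lo >= col_hi:
        raise ValueError(f"placement band for {cls.name} leaves no room")
    return (rng.uniform(margin, size - margin), rng.uniform(col_lo, col_hi))


def _render(spec: SceneSpec, masks: dict[str, np.ndarray],
            intensities: dict[str, float],
            rng: np.random.Generator) -> np.ndarray:
    img = np.full((spec.image_size, spec.image_size), spec.background)
    for name, mask in masks.items():
        img[mask.astype(bool)] = intensities[name]
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_single_lesion(n: int, spec: SceneSpec | None = None,
                           seed: int = 0,
                           no_lesion_fraction: float = 0.0) -> list[ImageSample]:
    """Scenes with exactly one lesion of a seeded-random class (or none,
    with probability `no_lesion_fraction`); classes drawn uniformly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or brain_spec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51E]))
    size = spec.image_size
    samples = []
    for _ in range(n):
        if rng.random() < no_lesion_fraction:
            img = _render(spec, {}, {}, rng)
            samples.append(ImageSample(image=img, masks={}, labels=[]))
            continue
        cls = spec.classes[rng.integers(len(spec.classes))]
        center = _draw_center(rng, cls, size)
        mask = _draw_region(rng, cls, size, center)
        intensity = rng.uniform(*cls.intensity)
        img = _render(spec, {cls.name: mask}, {cls.name: intensity}, rng)
        samples.append(ImageSample(image=img, masks={cls.name: mask},
                                   labels=[cls.name]))
    return samples


def generate_multi_organ(n: int, spec: SceneSpec | None = None,
                         seed: int = 0, max_retries: int = 200,
                         coverage_cap: float = 0.6) -> list[ImageSample]:
    """Scenes containing all classes as pairwise-disjoint regions.

    Regions are placed by rejection sampling; if a region cannot be
    placed without overlap within `max_retries` attempts an error naming
    the offending class is raised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or organ_spec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0D6A]))
    size = spec.image_size
    samples = []
    for _ in range(n):
        occupied = np.zeros((size, size), dtype=bool)
        masks: dict[str, np.ndarray] = {}
        intensities: dict[str, float] = {}
        for cls in spec.classes:
            placed = False
            for _attempt in range(max_retries):
                center = _draw_center(rng, cls, size)
                mask = _draw_region(rng, cls, size, center)
                grown = np.pad(mask, 1)  # 1-px moat keeps regions separated
                grown = (grown[:-2, 1:-1] | grown[2:, 1:-1] | grown[1:-1, :-2]
                         | grown[1:-1, 2:] | grown[1:-1, 1:-1]).astype(bool)
                if mask.any() and not (grown & occupied).any():
                    occupied |= grown
                    masks[cls.name] = mask
                    intensities[cls.name] = rng.uniform(*cls.intensity)
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place class {cls.name!r} without overlap after "
                    f"{max_retries} attempts; relax SceneSpec size ranges")
        if occupied.mean() > coverage_cap:
            raise RuntimeError("generated scene exceeds the coverage cap; "
                               "shrink SceneSpec size ranges")
        img = _render(spec, masks, intensities, rng)
        samples.append(ImageSample(image=img, masks=masks,
                                   labels=[c.name for c in spec.classes]))
    return samples


def attach_prompts(samples: list[ImageSample], table: SynonymTable,
                   seed: int = 0) -> list[ImageSample]:
    """Assign each sample a prompt for one of its classes (chosen at random
    for multi-class scenes) and record the paired target mask."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9B0]))
    for s in samples:
        if not s.labels:
            continue
        missing = [c for c in s.labels if c not in table.synonyms]
        if missing:
            raise KeyError(f"classes missing from synonym table: {missing}")
        target = s.labels[rng.integers(len(s.labels))]
        s.target_class = target
        s.prompt = build_prompt(target, table, rng)
    return samples


def dataset_hash(samples: list[ImageSample]) -> str:
    """Stable content hash over images, masks and prompts."""
    h = hashlib.sha256()
    for s in samples:
        h.update(np.ascontiguousarray(s.image).tobytes())
        for name in sorted(s.masks):
            h.update(name.encode())
            h.update(np.ascontiguousarray(s.masks[name]).tobytes())
        h.update((s.prompt or "").encode())
        h.update((s.target_class or "").encode())
    return h.hexdigest()
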