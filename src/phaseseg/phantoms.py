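"""Seeded K-phase phantom generator with ground-truth label maps.

Phantoms are piecewise-constant intensity images (disks, stripes,
checkerboards, glyph-like stroke patterns) with optional additive Gaussian
noise, built so every pipeline stage can be tested without external data.

Default intensities are ``k/K`` for the interior phases and 1 for the top
phase.  Under the pipeline's affine normalization (which pins the minimum to
0 and the maximum to 1) and the initialization φ = K·I₀, this places the
plateau of phase k exactly at the well k (the top plateau lands at K and is
clipped into the top band), so each region starts strictly inside its own
half-integer band.  A uniform spacing k/(K−1) would instead put the middle
plateau of a 3-phase phantom exactly on the contour level 1.5 and push the
third plateau of a 4-phase phantom into the wrong band (K·2/3 = 2.67 is in
the basin of well 3), which no evolution can undo; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import GridSpec, ImageField

__all__ = ["PhantomSpec", "default_intensities", "generate_phantom", "generate_glyph"]

SHAPES = ("disk", "stripes", "checkerboard", "glyph")

#: default strokes of the glyph phantom (x0, y0, width, height) as fractions
#: of the image side: three horizontal bars and a spine, an "E"-like pattern
DEFAULT_GLYPH_STROKES = (
    (0.20, 0.15, 0.12, 0.70),
    (0.20, 0.15, 0.55, 0.12),
    (0.20, 0.44, 0.45, 0.12),
    (0.20, 0.73, 0.55, 0.12),
)


def default_intensities(k_phases: int) -> np.ndarray:
    """Intensities (0, 1/K, 2/K, ..., (K−2)/K, 1) — see the module docstring."""
    if k_phases < 1:
        raise ValueError("K must be >= 1")
    if k_phases == 1:
        return np.array([0.0])
    vals = np.arange(k_phases) / k_phases
    vals[-1] = 1.0
    return vals


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic phantom.

    ``intensities`` must be strictly increasing in [0, 1]; ``noise_sigma`` is
    the standard deviation of additive Gaussian noise (clipped back to [0, 1]
    after addition); ``seed`` is required whenever noise is requested.
    """

    shape: str = "disk"
    n: int = 256
    k_phases: int = 2
    intensities: tuple | None = None
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown phantom shape {self.shape!r}; choose from {SHAPES}")
        if self.n < 4:
            raise ValueError("image side must be at least 4 pixels")
        if self.k_phases < 1:
            raise ValueError("K must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.noise_sigma > 0 and self.seed is None:
            raise ValueError("a seed is required for noisy phantoms")
        if self.intensities is not None:
            vals = np.asarray(self.intensities, dtype=float)
            if vals.size != self.k_phases:
                raise ValueError("intensities must have exactly K entries")
            if np.any(np.diff(vals) <= 0):
                raise ValueError("intensities must be strictly increasing")
            if vals.min() < 0 or vals.max() > 1:
                raise ValueError("intensities must lie in [0, 1]")

    def resolved_intensities(self) -> np.ndarray:
        if self.intensities is not None:
            return np.asarray(self.intensities, dtype=float)
        return default_intensities(self.k_phases)


def _disk_labels(n: int, k: int) -> np.ndarray:
    """Concentric disks: background 0, nested disks of decreasing radius."""
    y, x = np.mgrid[0:n, 0:n]
    r = np.hypot(x - (n - 1) / 2.0, y - (n - 1) / 2.0)
    labels = np.zeros((n, n), dtype=int)
    r_max = 0.35 * n
    for j in range(1, k):
        radius = r_max * (k - j) / max(k - 1, 1)
        labels[r <= radius] = j
    return labels


def _stripe_labels(n: int, k: int) -> np.ndarray:
    x = np.arange(n)
    col = np.minimum((x * k) // n, k - 1).astype(int)
    return np.tile(col, (n, 1))


def _checkerboard_labels(n: int, k: int) -> np.ndarray:
    tile = max(n // 8, 1)
    y, x = np.mgrid[0:n, 0:n]
    return ((y // tile + x // tile) % k).astype(int)


def _glyph_label_map(n: int, strokes=DEFAULT_GLYPH_STROKES) -> np.ndarray:
    labels = np.zeros((n, n), dtype=int)
    for x0, y0, w, h in strokes:
        j0, j1 = int(round(x0 * n)), int(round((x0 + w) * n))
        i0, i1 = int(round(y0 * n)), int(round((y0 + h) * n))
        labels[i0:i1, j0:j1] = 1
    return labels


def _labels_for(spec: PhantomSpec) -> np.ndarray:
    if spec.shape == "disk":
        return _disk_labels(spec.n, spec.k_phases)
    if spec.shape == "stripes":
        return _stripe_labels(spec.n, spec.k_phases)
    if spec.shape == "checkerboard":
        return _checkerboard_labels(spec.n, spec.k_phases)
    if spec.k_phases != 2:
        raise ValueError("glyph phantoms are binary (K = 2)")
    return _glyph_label_map(spec.n)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageField, np.ndarray]:
    """Build the phantom image and its ground-truth label map.

    The noiseless image takes exactly the spec's intensity per region; noise
    is drawn from a seeded generator and the sum clipped to [0, 1] so the
    pipeline's normalization remains a no-op on noisy phantoms.
    """
    labels = _labels_for(spec)
    intensities = spec.resolved_intensities()
    values = intensities[labels]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values = np.clip(values + rng.normal(0.0, spec.noise_sigma, values.shape), 0.0, 1.0)
    grid = GridSpec.from_shape(values.shape)
    image = ImageField(values=values, grid=grid, source_min=0.0, source_max=1.0)
    return image, labels


def generate_glyph(
    strokes=DEFAULT_GLYPH_STROKES,
    n: int = 256,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[ImageField, np.ndarray]:
    """Binary stroke phantom (foreground 1, background 0) with its mask.

    ``strokes`` is a sequence of axis-aligned rectangles
    ``(x0, y0, width, height)`` in units of the image side; an empty sequence
    yields an all-background image.
    """
    labels = _glyph_label_map(n, tuple(strokes))
    values = labels.astype(float)
    if noise_sigma > 0:
        if seed is None:
            raise ValueError("a seed is required for noisy glyphs")
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sigma, values.shape), 0.0, 1.0)
    grid = GridSpec.from_shape(values.shape)
    return ImageField(values=values, grid=grid), labels
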