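"""Image loading, normalization, initialization and the pipeline entry point.

The pipeline is: read a single-channel raster → affine-normalize the
intensity to [0, 1] → initialize φ = K·I₀ → evolve → band φ into labels at
the half-integer levels → write the label map, per-phase masks, contour
overlay and energy trace.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .extraction import ContourSet, extract_contour, extract_phases
from .fields import GridSpec, ImageField, PhaseField
from .solver import SegmentationResult, SolverParams, evolve

__all__ = [
    "ConstantImageWarning",
    "load_image",
    "normalize_intensity",
    "init_phase",
    "run_segmentation",
    "write_outputs",
]

logger = logging.getLogger(__name__)

#: Rec. 601 luma weights for explicit color-to-gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


class ConstantImageWarning(UserWarning):
    """The input image is constant; normalization is undefined and yields 0."""


def load_image(path, *, to_gray: bool = False) -> np.ndarray:
    """Read a raster image (PNG/TIFF/PGM, integer or float) as a 2-D array.

    Multi-channel input is rejected unless ``to_gray`` is set, in which case
    it is converted with Rec. 601 luma weights (an alpha channel is dropped).
    """
    raw = np.asarray(iio.imread(Path(path)))
    if raw.ndim == 3:
        if not to_gray:
            raise ValueError(
                f"{path} has {raw.shape[-1]} channels; pass to_gray=True (CLI: --to-gray) "
                "to convert with Rec. 601 luma weights"
            )
        if raw.shape[-1] == 4:
            raw = raw[..., :3]
        raw = raw[..., :3].astype(float) @ _LUMA
    elif raw.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {raw.shape}")
    return raw.astype(float)


def normalize_intensity(raw: np.ndarray, grid: GridSpec | None = None) -> ImageField:
    """Affine normalization I₀ = (I − I_min)/(I_max − I_min) onto [0, 1].

    A constant image has no dynamic range; it maps to all zeros with a
    :class:`ConstantImageWarning`.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(raw)):
        raise ValueError("image contains non-finite values")
    lo, hi = float(raw.min()), float(raw.max())
    if grid is None:
        grid = GridSpec.from_shape(raw.shape)
    if hi == lo:
        warnings.warn(
            "constant image: normalization is undefined, returning all zeros",
            ConstantImageWarning,
            stacklevel=2,
        )
        return ImageField(values=np.zeros_like(raw), grid=grid, source_min=lo, source_max=hi)
    return ImageField(values=(raw - lo) / (hi - lo), grid=grid, source_min=lo, source_max=hi)


def init_phase(image: ImageField, k_phases: int) -> PhaseField:
    """Initialize the phase field as φ = K·I₀ (range [0, K])."""
    if k_phases < 1:
        raise ValueError("K must be >= 1")
    return PhaseField(values=k_phases * image.values, k_phases=k_phases, grid=image.grid)


def run_segmentation(
    source,
    params: SolverParams | None = None,
    *,
    out_dir=None,
    to_gray: bool = False,
    **param_overrides,
) -> SegmentationResult:
    """Segment an image from a path or array; optionally write all outputs.

    ``source`` may be a file path, a raw 2-D array (any range; it will be
    normalized), or an :class:`ImageField` already in [0, 1].  Keyword
    overrides build a :class:`SolverParams` when none is given.  The pipeline
    contains no randomness: identical input and configuration give identical
    outputs.
    """
    if params is None:
        params = SolverParams(**param_overrides)
    elif param_overrides:
        raise ValueError("pass either params or keyword overrides, not both")

    if isinstance(source, ImageField):
        image = source
        if image.values.min() < 0 or image.values.max() > 1:
            raise ValueError("ImageField input must already be normalized to [0, 1]")
    elif isinstance(source, (str, Path)):
        image = normalize_intensity(load_image(source, to_gray=to_gray))
    else:
        image = normalize_intensity(np.asarray(source))

    result = evolve(image, params)
    if out_dir is not None:
        write_outputs(result, image, Path(out_dir))
    return result


def _render_contour_overlay(result: SegmentationResult, image: ImageField, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5 * image.shape[0] / image.shape[1]))
    ax.imshow(image.values, cmap="gray", vmin=0, vmax=1, interpolation="nearest")
    ax.contour(
        result.phi_final.values,
        levels=list(result.contour_levels),
        colors=["red", "lime", "cyan", "yellow", "magenta"][: len(result.contour_levels)],
        linewidths=1.0,
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight", pad_inches=0)
    plt.close(fig)


def write_outputs(result: SegmentationResult, image: ImageField, out_dir: Path) -> dict:
    """Write label map, masks, contour overlay, energy trace and config echo.

    Returns a dict of the written paths.  The label map is an 8-bit PNG whose
    pixel value is the phase index; masks are 0/255 binary PNGs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    labels_path = out_dir / "labels.png"
    iio.imwrite(labels_path, result.labels.astype(np.uint8))
    paths["labels"] = labels_path

    for k, mask in enumerate(result.masks):
        p = out_dir / f"mask_{k}.png"
        iio.imwrite(p, (mask.astype(np.uint8) * 255))
        paths[f"mask_{k}"] = p

    overlay_path = out_dir / "contours.png"
    _render_contour_overlay(result, image, overlay_path)
    paths["contours"] = overlay_path

    trace_path = out_dir / "energy_trace.tsv"
    K = result.params.k_phases
    with open(trace_path, "w") as fh:
        fh.write("step\tenergy\t" + "\t".join(f"C_{k}" for k in range(K)) + "\n")
        for step, energy in enumerate(result.energy_trace):
            means = result.means_trace[min(step, len(result.means_trace) - 1)]
            row = "\t".join(f"{c:.10g}" for c in means.values)
            fh.write(f"{step}\t{energy:.10g}\t{row}\n")
    paths["energy_trace"] = trace_path

    config_path = out_dir / "config.txt"
    p = result.params
    with open(config_path, "w") as fh:
        for key in (
            "k_phases",
            "epsilon",
            "m",
            "rho",
            "lam",
            "dt",
            "n_steps",
            "scheme",
            "subgrid_enabled",
            "update_means",
        ):
            fh.write(f"{key}={getattr(p, key)}\n")
        fh.write(f"potential_mode={p.potential.mode}\n")
        fh.write(f"deriv_mode={p.potential.deriv_mode}\n")
        fh.write(f"source_min={image.source_min}\nsource_max={image.source_max}\n")
    paths["config"] = config_path
    logger.info("wrote segmentation outputs to %s", out_dir)
    return paths
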