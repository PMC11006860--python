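"""Grid and field containers for the cell-centered finite-difference lattice.

The computational domain is a rectangle ``(a, b) x (c, d)`` discretized into
``N_x x N_y`` square cells; all fields (image intensity, phase field) live at
the cell centers ``x_i = a + (i - 1/2) h``, ``y_j = c + (j - 1/2) h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "ImageField", "PhaseField"]

_SQUARE_TOL = 1e-12


@dataclass(frozen=True)
class GridSpec:
    """Uniform cell-centered grid on the rectangle ``(a, b) x (c, d)``.

    ``h = (b - a) / N_x`` is the common mesh size; the cell aspect ratio must
    be 1 (square pixels), i.e. ``(d - c) / N_y == h`` up to round-off.
    """

    n_x: int
    n_y: int
    a: float = 0.0
    b: float = 1.0
    c: float = 0.0
    d: float | None = None

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid must have at least one cell per axis")
        if self.d is None:
            # default: unit width, height set by the aspect ratio
            object.__setattr__(self, "d", self.c + (self.b - self.a) * self.n_y / self.n_x)
        h = (self.b - self.a) / self.n_x
        if h <= 0:
            raise ValueError("domain width must be positive")
        h_y = (self.d - self.c) / self.n_y
        if abs(h_y - h) > _SQUARE_TOL * max(1.0, abs(h)):
            raise ValueError(
                f"non-square cells: h_x={h} but h_y={h_y}; "
                "resample the image or adjust the domain"
            )

    @property
    def h(self) -> float:
        return (self.b - self.a) / self.n_x

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(n_y, n_x)`` (row = y index)."""
        return (self.n_y, self.n_x)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` center coordinate arrays of shape ``(n_y, n_x)``."""
        h = self.h
        x = self.a + (np.arange(self.n_x) + 0.5) * h
        y = self.c + (np.arange(self.n_y) + 0.5) * h
        return np.meshgrid(x, y)

    @classmethod
    def from_shape(cls, shape: tuple[int, int]) -> "GridSpec":
        n_y, n_x = shape
        return cls(n_x=n_x, n_y=n_y)


@dataclass
class ImageField:
    """Normalized intensity :math:`I_0 \\in [0, 1]` on a grid.

    ``source_min``/``source_max`` record the affine normalization applied to
    the raw input so results can be reported in original units.
    """

    values: np.ndarray
    grid: GridSpec
    source_min: float = 0.0
    source_max: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"image shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PhaseField:
    """Scalar phase field φ whose near-integer plateaus encode phase labels.

    ``k_phases`` is the number of phases K; during evolution φ is expected to
    stay in roughly ``[-0.5, K + 0.5]``.  ``time_index`` is the step count n.
    """

    values: np.ndarray
    k_phases: int
    grid: GridSpec
    time_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.k_phases < 1:
            raise ValueError("number of phases K must be >= 1")
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"phase-field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.time_index < 0:
            raise ValueError("time_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, values: np.ndarray, time_index: int | None = None) -> "PhaseField":
        return PhaseField(
            values=values,
            k_phases=self.k_phases,
            grid=self.grid,
            time_index=self.time_index if time_index is None else time_index,
        )
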