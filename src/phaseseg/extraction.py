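"""Label and contour extraction from a phase field.

Phase k occupies the half-open band φ ∈ [k − 1/2, k + 1/2); the two outer
bands are clipped so label 0 takes everything below 1/2 and label K−1 takes
everything above K − 3/2.  Contours are the half-integer level sets
φ = k + 1/2, reported as the set of 4-neighbor cell edges they cross.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import PhaseField

__all__ = ["ContourSet", "extract_phases", "extract_contour", "contour_levels"]


def contour_levels(k_phases: int) -> np.ndarray:
    """Half-integer separating levels {0.5, 1.5, ..., K − 0.5}."""
    return np.arange(k_phases) + 0.5


def extract_phases(phi: PhaseField, k_phases: int | None = None):
    """Band the phase field into labels and per-phase masks.

    Ties at band edges go upward: φ exactly at k + 1/2 is assigned phase
    k + 1 (half-open bands), so the rule is total and deterministic.

    Returns
    -------
    labels : int array in {0, ..., K−1}
    masks : list of K boolean arrays forming a disjoint cover of the domain
    """
    K = phi.k_phases if k_phases is None else int(k_phases)
    if K < 1:
        raise ValueError("K must be >= 1")
    values = phi.values
    if not np.all(np.isfinite(values)):
        raise ValueError("phase field contains non-finite values")
    labels = np.clip(np.floor(values + 0.5).astype(int), 0, K - 1)
    masks = [labels == k for k in range(K)]
    return labels, masks


@dataclass(frozen=True)
class ContourSet:
    """Grid edges crossed by a level set, plus cells lying exactly on it.

    ``edges`` holds 4-neighbor cell index pairs ``((i1, j1), (i2, j2))`` with
    ``(φ1 − level)(φ2 − level) < 0``; ``on_level`` holds cells with
    φ exactly equal to the level.
    """

    level: float
    edges: frozenset
    on_level: frozenset

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def is_empty(self) -> bool:
        return not self.edges and not self.on_level


def extract_contour(phi: PhaseField, level: float) -> ContourSet:
    """All grid edges where the field crosses ``level`` (sign change)."""
    if not np.isfinite(level):
        raise ValueError("contour level must be finite")
    s = phi.values - level
    edges = set()
    # vertical neighbors (i, j)-(i+1, j)
    cross_v = s[:-1, :] * s[1:, :] < 0
    for i, j in zip(*np.nonzero(cross_v)):
        edges.add(((int(i), int(j)), (int(i) + 1, int(j))))
    # horizontal neighbors (i, j)-(i, j+1)
    cross_h = s[:, :-1] * s[:, 1:] < 0
    for i, j in zip(*np.nonzero(cross_h)):
        edges.add(((int(i), int(j)), (int(i), int(j) + 1)))
    on_level = {(int(i), int(j)) for i, j in zip(*np.nonzero(s == 0.0))}
    return ContourSet(level=float(level), edges=frozenset(edges), on_level=frozenset(on_level))
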