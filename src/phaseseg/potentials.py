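"""Scalar nonlinearities of the multiphase phase-field model.

The model penalizes phase-field values away from the integers through a
piecewise-cubic ("Bi-cubic spline") multi-well potential composed with the
fractional part ⟨φ⟩ = φ − ⌊φ⌋, and fits region intensities through sinc²
bump weights centered at the integers.  Everything here is a pure pointwise
kernel; the solver and the energy assemble them over the grid.

Three potential variants are provided:

``literal_eq2``
    The published five-branch piecewise cubic on [−1, 1], exactly as printed:
    (2+u³)/150, (4−6u²−3u³)/150, (4−6u²+3u³)/150, (2−u³)/150, 0 outside.
    As printed it has a jump at |u| = 1/2 (see ``docs/methods.md``); it is kept
    verbatim for fidelity.
``rescaled_bspline``
    A continuity-repaired compressed cubic B-spline with the same 1/150
    normalization: (4−24u²+24|u|³)/150 for |u| ≤ 1/2, (2−2|u|)³/150 for
    1/2 < |u| ≤ 1, 0 outside.  Continuous on ℝ.
``double_well``
    ¼⟨u⟩²(1−⟨u⟩)², the antiderivative-consistent companion of the cubic
    derivative u³ − (3/2)u² + u/2 that the published discretization actually
    evaluates.

The derivative used by the solver likewise has two modes:
``double_well_printed`` (default) evaluates the cubic
⟨φ⟩³ − (3/2)⟨φ⟩² + (1/2)⟨φ⟩, and ``literal_piecewise`` differentiates the
selected potential branchwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PotentialSpec",
    "frac_part",
    "bicubic_potential",
    "bicubic_deriv",
    "sinc",
    "sinc_sq",
    "sinc_sq_deriv",
    "fitting_force",
]

POTENTIAL_MODES = ("literal_eq2", "rescaled_bspline", "double_well")
DERIV_MODES = ("double_well_printed", "literal_piecewise")

#: below this |u| the removable limits of sinc (=1) and d[sinc²]/du (=0) are
#: returned directly to avoid catastrophic cancellation
SINC_SINGULARITY_TOL = 1e-8


@dataclass(frozen=True)
class PotentialSpec:
    """Selection of potential branch set, derivative rule and stiffness ε.

    ``mode`` and ``deriv_mode`` are independent: the published scheme pairs the
    literal potential with the cubic double-well derivative.
    """

    mode: str = "literal_eq2"
    deriv_mode: str = "double_well_printed"
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in POTENTIAL_MODES:
            raise ValueError(f"unknown potential mode {self.mode!r}; choose from {POTENTIAL_MODES}")
        if self.deriv_mode not in DERIV_MODES:
            raise ValueError(
                f"unknown derivative mode {self.deriv_mode!r}; choose from {DERIV_MODES}"
            )
        if not (np.isfinite(self.epsilon) and self.epsilon > 0):
            raise ValueError("epsilon must be a positive finite real")


def _validate_finite(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def frac_part(phi):
    """Fractional part ⟨φ⟩ = φ − ⌊φ⌋, in [0, 1).

    ⌊φ⌋ is the largest integer not greater than φ, so the identity
    φ = ⌊φ⌋ + ⟨φ⟩ holds exactly and negative inputs wrap (⟨−0.3⟩ = 0.7).
    """
    arr = _validate_finite(phi, "phi")
    out = arr - np.floor(arr)
    # for tiny negative phi the exact value 1 - |phi| rounds to 1.0, outside
    # [0,1); the nearest representable in-range value keeps the identity to 1 ulp
    out = np.where(out >= 1.0, np.nextafter(1.0, 0.0), out)
    return out if isinstance(phi, np.ndarray) else float(out)


def _potential_literal(u: np.ndarray) -> np.ndarray:
    u2, u3 = u * u, u * u * u
    return np.select(
        [
            (u >= -1.0) & (u <= -0.5),
            (u > -0.5) & (u <= 0.0),
            (u > 0.0) & (u <= 0.5),
            (u > 0.5) & (u <= 1.0),
        ],
        [
            (2.0 + u3) / 150.0,
            (4.0 - 6.0 * u2 - 3.0 * u3) / 150.0,
            (4.0 - 6.0 * u2 + 3.0 * u3) / 150.0,
            (2.0 - u3) / 150.0,
        ],
        default=0.0,
    )


def _potential_rescaled(u: np.ndarray) -> np.ndarray:
    a = np.abs(u)
    return np.select(
        [a <= 0.5, a <= 1.0],
        [
            (4.0 - 24.0 * a * a + 24.0 * a * a * a) / 150.0,
            (2.0 - 2.0 * a) ** 3 / 150.0,
        ],
        default=0.0,
    )


def _potential_double_well(u: np.ndarray) -> np.ndarray:
    v = u - np.floor(u)
    v = np.where(v >= 1.0, 0.0, v)
    return 0.25 * v * v * (1.0 - v) ** 2


def bicubic_potential(u, spec: PotentialSpec | None = None, *, mode: str | None = None):
    """Multi-well phase transition potential.

    ``u`` is taken as the already-reduced argument for the literal and
    rescaled modes (they are defined on their printed support [−1, 1] and are
    0 outside); the ``double_well`` mode composes with ⟨·⟩ itself.  Inside the
    solver the potential is always applied to ⟨φ⟩.
    """
    if mode is None:
        mode = (spec or PotentialSpec()).mode
    if mode not in POTENTIAL_MODES:
        raise ValueError(f"unknown potential mode {mode!r}")
    arr = _validate_finite(u, "u")
    if mode == "literal_eq2":
        out = _potential_literal(arr)
    elif mode == "rescaled_bspline":
        out = _potential_rescaled(arr)
    else:
        out = _potential_double_well(arr)
    return out if isinstance(u, np.ndarray) else float(out)


def _deriv_literal(v: np.ndarray) -> np.ndarray:
    # branchwise derivative of the printed cubic on the reachable branches
    # v in [0, 1); the jump point 1/2 takes the left branch
    return np.where(
        v <= 0.5,
        (-12.0 * v + 9.0 * v * v) / 150.0,
        -3.0 * v * v / 150.0,
    )


def _deriv_rescaled(v: np.ndarray) -> np.ndarray:
    return np.where(
        v <= 0.5,
        (-48.0 * v + 72.0 * v * v) / 150.0,
        -6.0 * (2.0 - 2.0 * v) ** 2 / 150.0,
    )


def _deriv_double_well(v: np.ndarray) -> np.ndarray:
    # d/dv [¼ v²(1−v)²] = v³ − (3/2)v² + v/2, identical to the printed cubic
    return v * v * v - 1.5 * v * v + 0.5 * v


def bicubic_deriv(phi, spec: PotentialSpec | None = None):
    """Derivative of the transition potential, evaluated at ⟨φ⟩.

    ``double_well_printed`` returns the cubic ⟨φ⟩³ − (3/2)⟨φ⟩² + (1/2)⟨φ⟩
    that the published discretization substitutes for the piecewise
    derivative; it is continuous across the integers (it vanishes at both well
    bottoms 0 and 1).  ``literal_piecewise`` differentiates the selected
    potential mode branch by branch on [0, 1).
    """
    spec = spec or PotentialSpec()
    arr = _validate_finite(phi, "phi")
    v = arr - np.floor(arr)
    v = np.where(v >= 1.0, 0.0, v)
    if spec.deriv_mode == "double_well_printed":
        out = _deriv_double_well(v)
    else:
        if spec.mode == "literal_eq2":
            out = _deriv_literal(v)
        elif spec.mode == "rescaled_bspline":
            out = _deriv_rescaled(v)
        else:
            out = _deriv_double_well(v)
    return out if isinstance(phi, np.ndarray) else float(out)


def sinc(u):
    """Normalized sinc: sin(πu)/(πu), with sinc(0) = 1."""
    arr = _validate_finite(u, "u")
    out = np.sinc(arr)  # numpy's sinc is the normalized one
    return out if isinstance(u, np.ndarray) else float(out)


def sinc_sq(u):
    """sinc²(u) = sin²(πu)/(πu)²; in [0, 1], zero at nonzero integers."""
    arr = _validate_finite(u, "u")
    s = np.sinc(arr)
    out = s * s
    return out if isinstance(u, np.ndarray) else float(out)


def sinc_sq_deriv(u):
    """d/du [sinc²(u)] = sin(2πu)/(πu²) − 2 sin²(πu)/(π²u³).

    Evaluated in the factored form 2·sinc(u)·(cos(πu) − sinc(u))/u, which is
    algebraically identical but exactly 0 at every nonzero integer (where
    sinc vanishes).  Returns 0 at |u| < tol, the removable limit at the
    critical point of sinc² at the origin.
    """
    arr = _validate_finite(u, "u")
    small = np.abs(arr) < SINC_SINGULARITY_TOL
    safe = np.where(small, 1.0, arr)
    s = np.sinc(safe)
    out = 2.0 * s * (np.cos(np.pi * safe) - s) / safe
    # exact integers are analytic zeros (sinc vanishes); snap past sin(πk) noise
    out = np.where(small | (arr == np.round(arr)), 0.0, out)
    return out if isinstance(u, np.ndarray) else float(out)


def fitting_force(phi, means, image_values, lam: float):
    """Data-fidelity force λ Σ_k (C_k − I₀)² · d/dφ[sinc²(φ − k)].

    ``means`` is the vector of region means C_k (or a RegionMeans); the force
    pushes φ away from wells whose fitted intensity disagrees with the local
    image value and vanishes wherever φ sits exactly at integer offsets from
    every well.
    """
    values = np.asarray(getattr(means, "values", means), dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("means must provide at least one region mean C_k")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    phi_arr = _validate_finite(phi, "phi")
    img = np.asarray(image_values, dtype=float)
    out = np.zeros(np.broadcast(phi_arr, img).shape)
    if lam == 0.0:
        return out if isinstance(phi, np.ndarray) else float(out)
    for k, c_k in enumerate(values):
        misfit = (c_k - img) ** 2
        out = out + misfit * sinc_sq_deriv(np.asarray(phi_arr - k))
    out = lam * out
    return out if isinstance(phi, np.ndarray) else float(out)
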