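"""Sulfur isotope notation, reference scales and conversions.

Everything downstream (forward distillation model, inversion, error
propagation) works on absolute rare/:sup:`32`S abundance ratios ``R`` and on
fractionation factors ``alpha``.  Measured data arrive in per-mil delta
notation relative to V-CDT::

    delta_x = 1000 * (R_x / R_x_ref - 1)        (x = 33, 34, 36)

Mass-dependent fractionation of the minor isotopes is described by the
exponent ``lambda = ln(a3x) / ln(a34)``; the reference mass-fractionation
line uses ``lambda = 0.515`` for 33S and ``1.90`` for 36S, and the deviation
of a sample from that line is the capital-delta value::

    Delta33 = delta33 - 1000 * ((1 + delta34/1000)**0.515 - 1)

Only ratios of ratios enter any epsilon or lambda result, so the choice of
absolute V-CDT ratios is inert for fractionation estimates; they are kept
configurable regardless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReferenceScale",
    "VCDT",
    "DeltaTriple",
    "RatioTriple",
    "FractionationTriple",
    "delta_to_ratio",
    "ratio_to_delta",
    "alpha_to_epsilon",
    "epsilon_to_alpha",
    "cap_delta",
    "lambda_from_alphas",
]


class InvalidIsotopeInput(ValueError):
    """Raised when a delta/ratio/alpha violates its physical domain."""


@dataclass(frozen=True)
class ReferenceScale:
    """Absolute isotope ratios of the reporting standard plus the
    reference mass-fractionation-line exponents.

    Defaults are the community V-CDT values; swapping them rescales
    absolute ratios only and leaves every epsilon/lambda result unchanged.
    """

    r33_ref: float = 0.0078776
    r34_ref: float = 0.0441626
    r36_ref: float = 0.0001533
    lambda33_rfl: float = 0.515
    lambda36_rfl: float = 1.90

    def __post_init__(self) -> None:
        if not (self.r33_ref > 0 and self.r34_ref > 0 and self.r36_ref > 0):
            raise InvalidIsotopeInput("reference ratios must be strictly positive")
        if not (self.r34_ref > self.r33_ref > self.r36_ref):
            raise InvalidIsotopeInput(
                "expected r34 > r33 > r36 for a V-CDT-like sulfur scale"
            )


VCDT = ReferenceScale()


def _check_delta(name: str, value: float | None) -> None:
    if value is not None and value <= -1000.0:
        raise InvalidIsotopeInput(f"{name} = {value} implies a non-positive ratio")


@dataclass(frozen=True)
class DeltaTriple:
    """delta-33/34/36 of one sulfur pool, in per mil vs V-CDT.

    ``d33``/``d36`` may be ``None`` for partial (major-isotope-only)
    measurements; missingness propagates, it is never treated as zero.
    """

    d34: float
    d33: float | None = None
    d36: float | None = None

    def __post_init__(self) -> None:
        _check_delta("d34", self.d34)
        _check_delta("d33", self.d33)
        _check_delta("d36", self.d36)


@dataclass(frozen=True)
class RatioTriple:
    """Absolute rare/32S ratios of one pool; r33/r36 optional."""

    r34: float
    r33: float | None = None
    r36: float | None = None

    def __post_init__(self) -> None:
        for name in ("r34", "r33", "r36"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidIsotopeInput(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class FractionationTriple:
    """Dimensionless fractionation factors for one branch or process."""

    a34: float
    a33: float | None = None
    a36: float | None = None

    def __post_init__(self) -> None:
        for name in ("a34", "a33", "a36"):
            v = getattr(self, name)
            if v is None:
                continue
            if v <= 0:
                raise InvalidIsotopeInput(f"{name} must be strictly positive, got {v}")
            if abs(v - 1.0) >= 0.2:
                warnings.warn(
                    f"{name} = {v} is far outside the physically sensible "
                    "range |alpha - 1| < 0.2",
                    stacklevel=3,
                )


def delta_to_ratio(d: DeltaTriple, scale: ReferenceScale = VCDT) -> RatioTriple:
    """Convert per-mil deltas to absolute ratios on ``scale``."""
    def conv(dx: float | None, ref: float) -> float | None:
        return None if dx is None else ref * (1.0 + dx / 1000.0)

    return RatioTriple(
        r34=scale.r34_ref * (1.0 + d.d34 / 1000.0),
        r33=conv(d.d33, scale.r33_ref),
        r36=conv(d.d36, scale.r36_ref),
    )


def ratio_to_delta(r: RatioTriple, scale: ReferenceScale = VCDT) -> DeltaTriple:
    """Convert absolute ratios back to per-mil deltas on ``scale``."""
    def conv(rx: float | None, ref: float) -> float | None:
        return None if rx is None else 1000.0 * (rx / ref - 1.0)

    return DeltaTriple(
        d34=1000.0 * (r.r34 / scale.r34_ref - 1.0),
        d33=conv(r.r33, scale.r33_ref),
        d36=conv(r.r36, scale.r36_ref),
    )


def alpha_to_epsilon(alpha, convention: str = "process"):
    """Express a fractionation factor in per-mil epsilon units.

    convention="process"
        ``eps = 1000 * (alpha - 1)``, the instantaneous-product/reactant
        orientation used internally.
    convention="reactant-product"
        ``eps_r-p = 1000 * (1/alpha - 1)``; a product-depleting branch
        (alpha < 1 in product/reactant orientation) reports a positive
        epsilon, which is the headline orientation for enzyme
        fractionations.

    Accepts scalars, numpy arrays, or a :class:`FractionationTriple`.
    """
    if isinstance(alpha, FractionationTriple):
        return tuple(
            None if a is None else alpha_to_epsilon(a, convention)
            for a in (alpha.a33, alpha.a34, alpha.a36)
        )
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= 0):
        raise InvalidIsotopeInput("alpha must be strictly positive")
    if convention == "process":
        out = 1000.0 * (a - 1.0)
    elif convention == "reactant-product":
        out = 1000.0 * (1.0 / a - 1.0)
    else:
        raise ValueError(f"unknown epsilon convention: {convention!r}")
    return out.item() if np.isscalar(alpha) or np.ndim(alpha) == 0 else out


def epsilon_to_alpha(eps, convention: str = "process"):
    """Inverse of :func:`alpha_to_epsilon` for scalar/array epsilon."""
    e = np.asarray(eps, dtype=float)
    if convention == "process":
        out = 1.0 + e / 1000.0
    elif convention == "reactant-product":
        out = 1.0 / (1.0 + e / 1000.0)
    else:
        raise ValueError(f"unknown epsilon convention: {convention!r}")
    return out.item() if np.isscalar(eps) or np.ndim(eps) == 0 else out


def cap_delta(d: DeltaTriple, scale: ReferenceScale = VCDT) -> tuple[float | None, float | None]:
    """Deviation from the reference mass-fractionation line, (Delta33, Delta36) in per mil.

    ``Delta3x = d3x - 1000 * ((1 + d34/1000)**lambda_rfl - 1)``.  Missing
    minor-isotope deltas yield missing capital-deltas.
    """
    u = 1.0 + d.d34 / 1000.0
    d33 = None
    d36 = None
    if d.d33 is not None:
        d33 = d.d33 - 1000.0 * (u ** scale.lambda33_rfl - 1.0)
    if d.d36 is not None:
        d36 = d.d36 - 1000.0 * (u ** scale.lambda36_rfl - 1.0)
    return d33, d36


def lambda_from_alphas(a3x: float, a34: float) -> float:
    """Mass-law exponent ``lambda = ln(a3x)/ln(a34)``.

    Undefined when a34 == 1 (no major-isotope fractionation to normalise
    against); that raises rather than returning inf.
    """
    if a3x <= 0 or a34 <= 0:
        raise InvalidIsotopeInput("alphas must be strictly positive")
    la34 = math.log(a34)
    if la34 == 0.0:
        raise InvalidIsotopeInput("lambda is undefined for a34 == 1 (ln(a34) == 0)")
    return math.log(a3x) / la34
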