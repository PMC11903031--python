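"""Monotone likelihood warping.

Normative regression assumes Gaussian residuals in a *warped* space: the
observed phenotype y is mapped through a strictly increasing function
phi(y; gamma) before the linear model is applied.  Two families are
provided:

* ``identity`` — no transformation (keeps all downstream algebra exactly
  checkable);
* ``sinh-arcsinh`` — phi(y) = sinh(b * asinh(y~) - a), with
  y~ = (y - loc) / scale and gamma = (a, b), b > 0.  ``a`` controls skew
  and ``b`` tail weight; (a, b) = (0, 1) with loc = 0, scale = 1 is the
  identity.

``warp_logderiv`` returns log phi'(y), the Jacobian term required by the
warped marginal likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WARP_FAMILIES = ("identity", "sinh-arcsinh")


@dataclass(frozen=True)
class WarpSpec:
    """Warp family plus shape parameters gamma and input standardization."""

    family: str = "identity"
    gamma: tuple[float, ...] = ()
    loc: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if self.family not in WARP_FAMILIES:
            raise ValueError(f"unknown warp family {self.family!r}")
        if self.family == "sinh-arcsinh":
            if len(self.gamma) != 2:
                raise ValueError("sinh-arcsinh warp needs gamma = (a, b)")
            if not self.gamma[1] > 0:
                raise ValueError(f"sinh-arcsinh tail parameter b must be > 0, got {self.gamma[1]}")
        if not self.scale > 0:
            raise ValueError("standardization scale must be > 0")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "gamma": [float(g) for g in self.gamma],
            "loc": float(self.loc),
            "scale": float(self.scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WarpSpec":
        return cls(
            family=d["family"], gamma=tuple(d["gamma"]),
            loc=float(d["loc"]), scale=float(d["scale"]),
        )


def _check_finite(y):
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input to warp")
    return y


def warp(y, spec: WarpSpec):
    """phi(y): observed space -> warped (Gaussian-residual) space."""
    y = _check_finite(y)
    if spec.family == "identity":
        return y
    a, b = spec.gamma
    yt = (y - spec.loc) / spec.scale
    return np.sinh(b * np.arcsinh(yt) - a)


def unwarp(z, spec: WarpSpec):
    """phi^{-1}(z): warped space back to observed units."""
    z = _check_finite(z)
    if spec.family == "identity":
        return z
    a, b = spec.gamma
    return spec.loc + spec.scale * np.sinh((np.arcsinh(z) + a) / b)


def warp_logderiv(y, spec: WarpSpec):
    """log phi'(y), the Jacobian of the warp at y."""
    y = _check_finite(y)
    if spec.family == "identity":
        return np.zeros_like(y)
    a, b = spec.gamma
    yt = (y - spec.loc) / spec.scale
    u = b * np.arcsinh(yt) - a
    # phi'(y) = b * cosh(u) / (scale * sqrt(1 + yt^2))
    return np.log(b) + np.log(np.cosh(u)) - 0.5 * np.log1p(yt**2) - np.log(spec.scale)


def check_monotone(spec: WarpSpec, lo: float = -5.0, hi: float = 5.0, n: int = 501) -> bool:
    """Numerically check strict monotonicity of the warp on a grid.

    The grid spans ``[loc + lo*scale, loc + hi*scale]``.
    """
    grid = spec.loc + spec.scale * np.linspace(lo, hi, n)
    vals = warp(grid, spec)
    return bool(np.all(np.diff(vals) > 0))
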