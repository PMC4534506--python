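"""Diffusion-model parameter container and scaling rules.

The Wiener diffusion model for binary choice is parameterised by a mean
drift rate ``v`` (evidence/s, signed; positive drifts toward the upper
boundary), a boundary separation ``a`` (the lower boundary sits at 0), a
relative start point ``zr = z / a``, a mean non-decision time ``t0``
(encoding + motor time, in seconds), and three across-trial variability
parameters: ``sv`` (normal SD of the drift), ``sz`` (uniform range of the
start point, in evidence units) and ``st`` (uniform range of ``t0``).
The within-trial noise scale ``s`` is a free scaling constant; all
parameters except the time parameters scale linearly with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum


class Boundary(str, Enum):
    """Absorbing boundary label; ``UPPER`` maps to the "old" response."""

    UPPER = "upper"
    LOWER = "lower"

    @property
    def response(self) -> str:
        return "old" if self is Boundary.UPPER else "new"

    @classmethod
    def from_response(cls, response: str) -> "Boundary":
        if response == "old":
            return cls.UPPER
        if response == "new":
            return cls.LOWER
        raise ValueError(f"unknown response label {response!r}")


@dataclass(frozen=True)
class DiffusionParams:
    """One condition's diffusion-model parameters.

    Parameters
    ----------
    v : float
        Mean drift rate (evidence units / s, signed).
    a : float
        Boundary separation (> 0); the lower boundary is fixed at 0.
    zr : float
        Relative start point z/a in (0, 1); 0.5 is unbiased.
    t0 : float
        Mean non-decision time in seconds (>= 0).
    sv, sz, st : float
        Across-trial SD of drift, uniform range of the start point
        (evidence units) and uniform range of t0 (s). All >= 0.
    s : float
        Diffusion (scaling) constant, default 0.1.
    """

    v: float
    a: float
    zr: float = 0.5
    t0: float = 0.0
    sv: float = 0.0
    sz: float = 0.0
    st: float = 0.0
    s: float = 0.1

    def __post_init__(self) -> None:
        vals = (self.v, self.a, self.zr, self.t0, self.sv, self.sz, self.st, self.s)
        if not all(math.isfinite(x) for x in vals):
            raise ValueError("diffusion parameters must be finite")
        if self.a <= 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not 0.0 < self.zr < 1.0:
            raise ValueError(f"relative start point must lie in (0, 1), got zr={self.zr}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be >= 0, got t0={self.t0}")
        if self.s <= 0:
            raise ValueError(f"scaling constant must be positive, got s={self.s}")
        if min(self.sv, self.sz, self.st) < 0:
            raise ValueError("variability parameters sv, sz, st must be >= 0")
        z = self.zr * self.a
        if self.sz > 0 and not (z - self.sz / 2 > 0 and z + self.sz / 2 < self.a):
            raise ValueError("start-point range sz extends outside the boundaries")
        if self.t0 - self.st / 2 < 0:
            raise ValueError("t0 range st allows negative non-decision times")

    @property
    def z(self) -> float:
        """Absolute start point z = zr * a."""
        return self.zr * self.a

    @property
    def has_variability(self) -> bool:
        return self.sv > 0 or self.sz > 0 or self.st > 0

    def without_variability(self) -> "DiffusionParams":
        return replace(self, sv=0.0, sz=0.0, st=0.0)

    def rescaled(self, s_new: float) -> "DiffusionParams":
        """Return the equivalent parameter set under scaling constant ``s_new``.

        Drift, boundary separation and the evidence-unit variability
        parameters scale by ``s_new / s``; the time parameters and the
        dimensionless start point are untouched.  Predicted choice
        probabilities and RT distributions are invariant.
        """
        if not (s_new > 0 and math.isfinite(s_new)):
            raise ValueError(f"scaling constant must be positive, got {s_new}")
        f = s_new / self.s
        return replace(self, v=self.v * f, a=self.a * f, sv=self.sv * f,
                       sz=self.sz * f, s=s_new)


def rescale_params(p: DiffusionParams, s_new: float) -> DiffusionParams:
    """Functional alias for :meth:`DiffusionParams.rescaled`."""
    return p.rescaled(s_new)
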