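"""Closed-form moment-based (EZ) estimation.

Accuracy, and the mean and variance of correct response times, are
inverted analytically into drift rate, boundary separation and
non-decision time.  The inversion assumes an unbiased start point
(z/a = 0.5) and no across-trial variability; it is undefined at
accuracy 0, 0.5 or 1 (an optional edge correction replaces perfect
accuracy by 1 - 1/(2n)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..params import DiffusionParams


@dataclass(frozen=True)
class SummaryStats:
    """Accuracy and correct-RT moments entering the closed-form inversion."""

    pc: float   # proportion correct
    mrt: float  # mean correct RT (s)
    vrt: float  # variance of correct RTs (s^2)
    n: int      # total trial count

    def __post_init__(self) -> None:
        if not 0.0 <= self.pc <= 1.0:
            raise ValueError(f"proportion correct must be in [0, 1], got {self.pc}")
        if self.vrt < 0:
            raise ValueError("RT variance must be >= 0")
        if self.n < 1:
            raise ValueError("need at least one trial")


def summarize_for_ez(trials: pd.DataFrame,
                     coding: str = "accuracy") -> SummaryStats:
    """Accuracy-code trials and compute the moments EZ needs.

    The default coding marks a trial correct when the response matches
    the stimulus class ("old" response to an old item, "new" to a new
    item); moments are taken over correct trials only.
    """
    if coding != "accuracy":
        raise ValueError(f"unknown coding rule {coding!r}")
    correct = (trials["response"] == trials["stimulus_class"]).to_numpy()
    rts = trials["rt"].to_numpy(dtype=float)
    rc = rts[correct]
    if rc.size < 2:
        raise ValueError("need >= 2 correct trials for an RT variance")
    return SummaryStats(pc=float(correct.mean()), mrt=float(rc.mean()),
                        vrt=float(rc.var(ddof=1)), n=int(correct.size))


def ez_fit(stats: SummaryStats, s: float = 0.1,
           edge_correction: bool = False) -> tuple[float, float, float]:
    """Invert (Pc, MRT, VRT) into (v, a, t0).

    With L = logit(Pc):

        v  = sign(Pc - 1/2) * s * [ L (L Pc^2 - L Pc + Pc - 1/2) / VRT ]^(1/4)
        a  = s^2 L / v
        t0 = MRT - (a / 2v) * (1 - e^y) / (1 + e^y),   y = -v a / s^2

    Raises on Pc in {0, 1/2, 1} unless ``edge_correction`` replaces the
    extremes by the 1/(2n) rule.
    """
    pc = stats.pc
    if edge_correction:
        if pc == 1.0:
            pc = 1.0 - 1.0 / (2 * stats.n)
        elif pc == 0.0:
            pc = 1.0 / (2 * stats.n)
        elif pc == 0.5:
            pc = 0.5 + 1.0 / (2 * stats.n)
    if pc in (0.0, 0.5, 1.0):
        raise ValueError(
            f"closed-form estimates undefined at accuracy {pc} "
            "(perfect, zero, or chance-level accuracy)")
    if stats.vrt <= 0:
        raise ValueError("closed-form estimates need a positive RT variance")
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / stats.vrt
    v = math.copysign(s * x**0.25, pc - 0.5)
    a = s**2 * L / v
    y = -v * a / s**2
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    t0 = stats.mrt - mdt
    return v, a, t0


def ez_fit_trials(trials: pd.DataFrame, s: float = 0.1,
                  edge_correction: bool = False) -> DiffusionParams:
    """Accuracy-code trials and return the EZ parameter point estimate
    (zr fixed at 0.5, variability parameters at 0)."""
    stats = summarize_for_ez(trials)
    v, a, t0 = ez_fit(stats, s=s, edge_correction=edge_correction)
    return DiffusionParams(v=v, a=a, zr=0.5, t0=max(t0, 0.0), s=s)
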