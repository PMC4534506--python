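"""Kolmogorov–Smirnov distribution fitting on the signed-RT axis.

Per stimulus class, the statistic T is the supremum distance between the
empirical CDF of signed response times (lower-boundary responses
negated) and the model-predicted signed CDF.  The p-value uses the
asymptotic Kolmogorov distribution at that class's trial count; classes
are combined by multiplying p-values, and fitting maximises that
product (equivalently minimises -sum log p).  A fit with overall
p <= 0.05 is flagged as screened (insufficient fit).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from ..params import DiffusionParams
from .. import wfpt
from .fitting import (DesignMatrix, FitResult, FitSpec, initial_vector,
                      profile_starts, run_nelder_mead, signed_rts,
                      structure_of)


def kolmogorov_logsf(x: float) -> float:
    """log of the asymptotic Kolmogorov survival function.

    For small x the survival probability is 1 minus an astronomically
    small CDF; computing log(p) as log1p(-cdf) with the small-x series
    for the CDF keeps the objective strictly monotone in T even where
    p rounds to 1 in double precision.
    """
    if x <= 0:
        return 0.0
    if x < 1.0:
        # cdf(x) = sqrt(2 pi)/x * sum_k exp(-(2k-1)^2 pi^2 / (8 x^2))
        k = np.arange(1, 6)
        cdf = math.sqrt(2.0 * math.pi) / x * float(
            np.sum(np.exp(-((2 * k - 1) ** 2) * math.pi**2 / (8.0 * x**2))))
        cdf = min(cdf, 1.0 - 1e-300)
        return math.log1p(-cdf)
    p = float(kolmogorov(x))
    return math.log(max(p, 1e-300))


def _class_T(signed_sorted: np.ndarray, params: DiffusionParams) -> float:
    """Supremum ECDF distance over the jump points of one class."""
    n = signed_sorted.size
    F = wfpt.predicted_signed_cdf(signed_sorted, params)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - F, F - (i - 1) / n)))


def ks_statistic(trials: pd.DataFrame,
                 params: dict[str, dict[str, DiffusionParams]]
                 ) -> tuple[float, float, dict]:
    """KS fit statistic of a fixed parameter set against trial data.

    Returns ``(T, p, detail)`` where T is the largest per-class supremum
    distance, p the product of per-class asymptotic p-values, and
    ``detail`` maps (condition, class) to its (T, n, p).
    """
    srt = signed_rts(trials)
    if not srt:
        raise ValueError("no trials to evaluate")
    detail = {}
    log_p = 0.0
    T_max = 0.0
    for (cond, cl), x in srt.items():
        if x.size == 0:
            raise ValueError(f"empty class {(cond, cl)}")
        p_cc = params[cond][cl]
        T = _class_T(x, p_cc)
        lp = kolmogorov_logsf(math.sqrt(x.size) * T)
        detail[(cond, cl)] = (T, x.size, math.exp(lp))
        log_p += lp
        T_max = max(T_max, T)
    return T_max, math.exp(log_p), detail


def ks_fit(trials: pd.DataFrame, design: DesignMatrix | None = None,
           s: float = 0.1, init: np.ndarray | None = None,
           restarts: int = 2, maxiter: int | None = None) -> FitResult:
    """Fit the diffusion model by maximising the product of per-class
    KS p-values (Nelder–Mead from EZ-derived starting values)."""
    design = design or DesignMatrix()
    spec = FitSpec(structure_of(trials), design, s=s)
    srt = signed_rts(trials)
    for key, x in srt.items():
        if x.size == 0:
            raise ValueError(f"empty class {key}")

    def objective(xv: np.ndarray) -> float:
        try:
            params = spec.build(xv)
            obj = 0.0
            for (cond, cl), data in srt.items():
                T = _class_T(data, params[cond][cl])
                obj -= kolmogorov_logsf(math.sqrt(data.size) * T)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e10
        return obj if math.isfinite(obj) else 1e10

    x0 = init if init is not None else initial_vector(spec, trials)
    extra, pilot_evals = ([], 0) if init is not None else \
        profile_starts(objective, spec, x0)
    xb, fb, converged, n_evals = run_nelder_mead(objective, x0,
                                                 restarts=restarts,
                                                 maxiter=maxiter,
                                                 extra_starts=extra)
    n_evals += pilot_evals
    params = spec.build(xb)
    T, p, _ = ks_statistic(trials, params)
    return FitResult(params=params, objective="KS", statistic=T, p=p,
                     converged=converged, n_evals=n_evals,
                     free_names=spec.free_names)
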