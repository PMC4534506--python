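"""Quantile-bin chi-square fitting (DMAT-style default bins).

Per stimulus class and response type, observed RTs are binned at their
0.1 / 0.3 / 0.5 / 0.7 / 0.9 quantiles (six bins per response, twelve per
class); expected counts come from the model-predicted signed CDF.
Adjacent bins are collapsed until every expected count is at least 1 so
the statistic stays defined for participants with very few errors; a
warning (not an error) is emitted when a response type has fewer than
11 trials, where the quantile edges are unstable.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ..params import DiffusionParams
from .. import wfpt
from .fitting import (DesignMatrix, FitResult, FitSpec, initial_vector,
                      profile_starts, run_nelder_mead, structure_of)

QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)
MIN_EXPECTED = 1.0
SPARSE_WARN_N = 11


def _bin_layout(trials: pd.DataFrame):
    """Observed counts and signed bin edges per (condition, class).

    Returns a dict mapping (condition, class) to a list of per-response
    ``(signed_edges, observed_counts)`` pairs; edges are increasing on
    the signed axis and cover that response's half-line.
    """
    layout = {}
    for (cond, cl), sub in trials.groupby(["condition", "stimulus_class"],
                                          observed=True):
        sides = []
        for resp, sign in (("new", -1.0), ("old", 1.0)):
            rts = np.sort(sub.loc[sub["response"] == resp, "rt"].to_numpy(float))
            if rts.size == 0:
                # one catch-all bin holding this response's total mass
                edges = np.array([0.0, np.inf]) * sign
                counts = np.array([0.0])
            else:
                if rts.size < SPARSE_WARN_N:
                    warnings.warn(
                        f"only {rts.size} '{resp}' responses in {(cond, cl)}: "
                        "quantile bin edges are unstable", stacklevel=2)
                q = np.quantile(rts, QUANTILES)
                edges = np.concatenate([[0.0], q, [np.inf]]) * sign
                counts = np.histogram(rts, np.concatenate([[0.0], q, [np.inf]]))[0].astype(float)
            if sign < 0:
                edges = edges[::-1]
                counts = counts[::-1]
            sides.append((edges, counts))
        layout[(cond, cl)] = sides
    return layout


def _side_chisq(edges: np.ndarray, counts: np.ndarray, n_class: int,
                params: DiffusionParams) -> tuple[float, int]:
    """(X^2 contribution, bin count after collapsing) for one response side."""
    finite = np.isfinite(edges)
    F = np.empty_like(edges)
    F[finite] = wfpt.predicted_signed_cdf(edges[finite], params)
    if not finite[0]:
        F[0] = 0.0
    if not finite[-1]:
        F[-1] = 1.0
    # clamp the inner edge of the negative side at P(lower response)
    expected = np.diff(F) * n_class
    obs = counts.copy()
    exp_ = expected.copy()
    # collapse adjacent bins until every expected count is >= MIN_EXPECTED
    i = 0
    while i < exp_.size:
        if exp_[i] < MIN_EXPECTED and exp_.size > 1:
            j = i + 1 if i + 1 < exp_.size else i - 1
            exp_[j] += exp_[i]
            obs[j] += obs[i]
            exp_ = np.delete(exp_, i)
            obs = np.delete(obs, i)
            i = 0
        else:
            i += 1
    exp_ = np.maximum(exp_, 1e-10)
    return float(np.sum((obs - exp_) ** 2 / exp_)), exp_.size


def chisq_statistic(trials: pd.DataFrame,
                    params: dict[str, dict[str, DiffusionParams]],
                    n_free: int = 0, _layout=None
                    ) -> tuple[float, float, float]:
    """(X^2, df, p) of a fixed parameter set against trial data.

    df = (total bins after collapsing - number of classes) - n_free,
    clamped at 1.
    """
    with warnings.catch_warnings():
        if _layout is not None:
            warnings.simplefilter("ignore")
        layout = _layout if _layout is not None else _bin_layout(trials)
    x2 = 0.0
    n_bins = 0
    n_classes = 0
    for (cond, cl), sides in layout.items():
        n_class = int(sum(c.sum() for _, c in sides))
        p_cc = params[cond][cl]
        n_classes += 1
        for edges, counts in sides:
            contrib, nb = _side_chisq(edges, counts, n_class, p_cc)
            x2 += contrib
            n_bins += nb
    df = max(n_bins - n_classes - n_free, 1)
    return x2, float(df), float(chi2.sf(x2, df))


def chisq_fit(trials: pd.DataFrame, design: DesignMatrix | None = None,
              s: float = 0.1, init: np.ndarray | None = None,
              restarts: int = 2, maxiter: int | None = None) -> FitResult:
    """Fit the diffusion model by minimising the quantile-bin X^2."""
    design = design or DesignMatrix()
    spec = FitSpec(structure_of(trials), design, s=s)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        layout = _bin_layout(trials)
        caught = [str(w.message) for w in wlist]
    for msg in caught:
        warnings.warn(msg, stacklevel=2)
    n_free = len(spec.slots)

    def objective(xv: np.ndarray) -> float:
        try:
            params = spec.build(xv)
            x2, _, _ = chisq_statistic(trials, params, n_free=n_free,
                                       _layout=layout)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e10
        return x2 if math.isfinite(x2) else 1e10

    x0 = init if init is not None else initial_vector(spec, trials)
    extra, pilot_evals = ([], 0) if init is not None else \
        profile_starts(objective, spec, x0)
    xb, fb, converged, n_evals = run_nelder_mead(objective, x0,
                                                 restarts=restarts,
                                                 maxiter=maxiter,
                                                 extra_starts=extra)
    n_evals += pilot_evals
    params = spec.build(xb)
    x2, df, p = chisq_statistic(trials, params, n_free=n_free, _layout=layout)
    return FitResult(params=params, objective="X2", statistic=x2, p=p,
                     converged=converged, n_evals=n_evals, df=df,
                     free_names=spec.free_names,
                     warnings=tuple(caught))
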