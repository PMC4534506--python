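"""Design-matrix-constrained fitting shared by the KS and chi-square back-ends.

A :class:`DesignMatrix` declares, per model parameter, whether it is
shared across conditions or free per condition; the drift rate is
additionally split by stimulus class within a condition.  The fitter
enumerates free-parameter slots from the data's (condition, class)
structure, optimises them with Nelder–Mead in a transformed
unconstrained space (log for the boundary separation, non-decision time
and the variability ranges; logit for the relative start point), and
starts from closed-form moment-based (EZ) estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from ..params import DiffusionParams

SCREEN_ALPHA = 0.05

_LOG = (lambda x: math.log(x), math.exp)
_LOGIT = (lambda x: float(logit(x)), lambda y: float(expit(y)))
_ID = (lambda x: x, lambda y: y)

_TRANSFORMS = {"v": _ID, "a": _LOG, "zr": _LOGIT, "t0": _LOG,
               "sv": _LOG, "sz": _LOG, "st": _LOG}

PARAM_NAMES = ("v", "a", "zr", "t0", "sv", "sz", "st")


@dataclass(frozen=True)
class DesignMatrix:
    """Sharing constraints for a multi-condition diffusion-model fit.

    Each field is ``"shared"`` (one value across all conditions),
    ``"free"`` (one value per condition), or — for the variability
    parameters — ``"fixed"`` (held at 0, not estimated).  The drift rate
    is always additionally separated by stimulus class.
    """

    v: str = "free"
    a: str = "shared"
    zr: str = "shared"
    t0: str = "shared"
    sv: str = "fixed"
    sz: str = "fixed"
    st: str = "fixed"

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            mode = getattr(self, name)
            allowed = {"shared", "free"} | ({"fixed"} if name in ("sv", "sz", "st") else set())
            if mode not in allowed:
                raise ValueError(f"{name}: invalid mode {mode!r}")

    @classmethod
    def no_variability(cls) -> "DesignMatrix":
        return cls()

    @classmethod
    def full(cls) -> "DesignMatrix":
        """Eight-parameter single-condition model (v per class + a, zr,
        t0 and the three variability parameters)."""
        return cls(sv="shared", sz="shared", st="shared")

    @classmethod
    def restricted(cls, free_param: str,
                   estimate_variability: bool = False) -> "DesignMatrix":
        """All parameters shared across conditions except ``free_param``."""
        if free_param not in ("v", "a", "zr", "t0"):
            raise ValueError(f"unknown parameter {free_param!r}; "
                             "expected one of v, a, zr, t0")
        modes = {n: "shared" for n in ("v", "a", "zr", "t0")}
        modes[free_param] = "free"
        var = "shared" if estimate_variability else "fixed"
        return cls(**modes, sv=var, sz=var, st=var)


@dataclass
class FitResult:
    """Estimated parameters and goodness of fit for one participant.

    ``params[condition][stimulus_class]`` holds the full parameter set
    applying to that cell.  ``screened`` is True when the fit statistic
    rejects the model at the 0.05 level, i.e. the participant should be
    excluded from group-level analyses.
    """

    params: dict[str, dict[str, DiffusionParams]]
    objective: str
    statistic: float
    p: float
    converged: bool
    n_evals: int
    df: float | None = None
    free_names: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def screened(self) -> bool:
        return bool(self.p <= SCREEN_ALPHA)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def flat_estimates(self) -> dict[str, float]:
        """One row of named estimates (condition/class-qualified)."""
        out: dict[str, float] = {}
        for cond, by_cls in self.params.items():
            first = next(iter(by_cls.values()))
            for name in ("a", "zr", "t0", "sv", "sz", "st"):
                out[f"{name}@{cond}"] = getattr(first, name)
            for cls, p in by_cls.items():
                out[f"v:{cls}@{cond}"] = p.v
        return out


class FitSpec:
    """Maps an unconstrained optimisation vector to per-cell parameters."""

    def __init__(self, structure: dict[str, list[str]], design: DesignMatrix,
                 s: float = 0.1):
        self.structure = {c: sorted(cl) for c, cl in structure.items()}
        self.design = design
        self.s = s
        self.slots: list[tuple[str, str | None, str | None]] = []
        for name in ("a", "zr", "t0", "sv", "sz", "st"):
            mode = getattr(design, name)
            if mode == "fixed":
                continue
            if mode == "shared":
                self.slots.append((name, None, None))
            else:
                for cond in self.structure:
                    self.slots.append((name, cond, None))
        all_classes = sorted({cl for cls in self.structure.values() for cl in cls})
        if design.v == "shared":
            for cl in all_classes:
                self.slots.append(("v", None, cl))
        else:
            for cond, classes in self.structure.items():
                for cl in classes:
                    self.slots.append(("v", cond, cl))

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(
            name + (f":{cl}" if cl else "") + (f"@{cond}" if cond else "")
            for name, cond, cl in self.slots
        )

    def _lookup(self, values: dict, name: str, cond: str, cl: str | None):
        mode = getattr(self.design, name)
        if mode == "fixed":
            return 0.0
        if name == "v":
            return values[("v", None if mode == "shared" else cond, cl)]
        return values[(name, None if mode == "shared" else cond, None)]

    def build(self, x: np.ndarray) -> dict[str, dict[str, DiffusionParams]]:
        values = {}
        for slot, xi in zip(self.slots, x):
            values[slot] = _TRANSFORMS[slot[0]][1](xi)
        out: dict[str, dict[str, DiffusionParams]] = {}
        for cond, classes in self.structure.items():
            a = self._lookup(values, "a", cond, None)
            zr = self._lookup(values, "zr", cond, None)
            t0 = self._lookup(values, "t0", cond, None)
            sv = self._lookup(values, "sv", cond, None)
            sz = self._lookup(values, "sz", cond, None)
            st = self._lookup(values, "st", cond, None)
            # keep the uniform supports strictly inside the feasible set
            zr = min(max(zr, 1e-4), 1 - 1e-4)
            z = zr * a
            sz = min(sz, 1.98 * min(z, a - z))
            st = min(st, 1.98 * t0)
            out[cond] = {}
            for cl in classes:
                v = self._lookup(values, "v", cond, cl)
                out[cond][cl] = DiffusionParams(v=v, a=a, zr=zr, t0=t0,
                                                sv=sv, sz=sz, st=st, s=self.s)
        return out

    def pack(self, natural: dict) -> np.ndarray:
        return np.array([_TRANSFORMS[s[0]][0](natural[s]) for s in self.slots])


def _accuracy_coded(trials: pd.DataFrame) -> pd.Series:
    return trials["response"] == trials["stimulus_class"]


def _zr_from_proportion(v: float, a: float, s: float, p_up: float) -> float:
    """Invert the absorption probability for the relative start point.

    Given a drift and boundary separation, solve
    ``P_up = (1 - exp(-2 v' a' zr)) / (1 - exp(-2 v' a'))`` for zr at the
    observed upper-response proportion; used only to seed the optimiser.
    """
    p_up = min(max(p_up, 1e-3), 1 - 1e-3)
    x = 2.0 * (v / s) * (a / s)
    if abs(x) < 1e-6:
        return p_up
    arg = 1.0 - p_up * (-math.expm1(-x))
    if arg <= 0:
        return 0.5
    return min(max(-math.log(arg) / x, 0.15), 0.85)


def initial_vector(spec: FitSpec, trials: pd.DataFrame) -> np.ndarray:
    """EZ-derived starting values; realistic defaults where EZ fails."""
    from .ez import summarize_for_ez, ez_fit

    s = spec.s
    per_cond: dict[str, tuple[float, float, float]] = {}
    zr_guesses: list[float] = []
    for cond in spec.structure:
        sub = trials[trials["condition"] == cond]
        min_rt = float(sub["rt"].min())
        try:
            stats = summarize_for_ez(sub)
            v, a, t0 = ez_fit(stats, s=s, edge_correction=True)
            v, a = abs(v), min(max(a, 0.3 * s), 5.0 * s)
            t0 = min(max(t0, 0.05), 0.95 * min_rt)
        except (ValueError, ZeroDivisionError):
            v, a, t0 = 0.05 * s, 1.2 * s, max(0.9 * min_rt, 0.1)
        per_cond[cond] = (v, a, t0)
        for cl, cl_sub in sub.groupby("stimulus_class", observed=True):
            sign = -1.0 if cl == "new" else 1.0
            p_up = float((cl_sub["response"] == "old").mean())
            zr_guesses.append(_zr_from_proportion(sign * v, a, s, p_up))

    zr0 = float(np.mean(zr_guesses)) if zr_guesses else 0.5
    natural = {}
    for name, cond, cl in spec.slots:
        conds = [cond] if cond else list(spec.structure)
        vs, as_, t0s = zip(*(per_cond[c] for c in conds))
        if name == "v":
            sign = -1.0 if cl == "new" else 1.0
            natural[(name, cond, cl)] = sign * max(float(np.mean(vs)), 1e-3)
        elif name == "a":
            natural[(name, cond, cl)] = float(np.mean(as_))
        elif name == "t0":
            natural[(name, cond, cl)] = float(np.mean(t0s))
        elif name == "zr":
            natural[(name, cond, cl)] = zr0
        elif name == "sv":
            natural[(name, cond, cl)] = 0.5 * s
        elif name == "sz":
            natural[(name, cond, cl)] = 0.1 * float(np.mean(as_))
        elif name == "st":
            natural[(name, cond, cl)] = 0.1
    return spec.pack(natural)


#: logit-scale start-point offsets explored by the pilot stage
_ZR_PROFILE_OFFSETS = (-1.2, -0.6, 0.0, 0.6, 1.2)


def profile_starts(obj, spec: FitSpec, x0: np.ndarray,
                   maxiter: int = 200) -> tuple[list[np.ndarray], int]:
    """Pilot the start-point dimension before the full search.

    Drift and start point trade off along a curved valley with
    genuinely separated local minima, and the moment-based start
    absorbs any start-point bias into the drift (it assumes zr = 0.5).
    Short simplex runs from a grid of zr offsets find the promising
    basins; the best two candidates seed the full optimisation.
    """
    zr_idx = [i for i, s in enumerate(spec.slots) if s[0] == "zr"]
    if not zr_idx:
        return [], 0
    cands = []
    n_evals = 0
    for dz in _ZR_PROFILE_OFFSETS:
        xs = x0.copy()
        xs[zr_idx] += dz
        res = minimize(obj, xs, method="Nelder-Mead",
                       options={"xatol": 5e-3, "fatol": 1e-4,
                                "maxiter": maxiter, "maxfev": maxiter})
        n_evals += res.nfev
        cands.append((res.fun, res.x))
    cands.sort(key=lambda c: c[0])
    return [x for _, x in cands[:2]], n_evals


def run_nelder_mead(obj, x0: np.ndarray, restarts: int = 2,
                    xatol: float = 1e-3, fatol: float = 1e-6,
                    maxiter: int | None = None,
                    extra_starts: list[np.ndarray] | None = None):
    """Multi-start Nelder–Mead; returns the best (x, fval, converged,
    n_evals).

    Full runs start from the seed point, any caller-provided candidates
    (typically the zr-profile winners), and ``restarts`` deterministic
    random perturbations; the incumbent is then polished at a tighter
    simplex tolerance.
    """
    if maxiter is None:
        maxiter = 400 * len(x0)
    rng = np.random.default_rng(12345)  # restart jitter only; fit is deterministic
    opts = {"xatol": xatol, "fatol": fatol, "maxiter": maxiter,
            "maxfev": maxiter}
    best = None
    n_evals = 0
    converged = False
    starts = [x0] + list(extra_starts or []) + \
        [x0 + rng.normal(0.0, 0.35, size=x0.size) for _ in range(restarts)]
    for start in starts:
        res = minimize(obj, start, method="Nelder-Mead", options=opts)
        n_evals += res.nfev
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    polish_opts = dict(opts, xatol=min(xatol, 2e-4))
    res = minimize(obj, best.x, method="Nelder-Mead", options=polish_opts)
    n_evals += res.nfev
    converged = converged or bool(res.success)
    if res.fun < best.fun:
        best = res
    return best.x, float(best.fun), converged, n_evals


def structure_of(trials: pd.DataFrame) -> dict[str, list[str]]:
    return {cond: sorted(sub["stimulus_class"].unique())
            for cond, sub in trials.groupby("condition", observed=True)}


def signed_rts(trials: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    """Sorted signed response times per (condition, stimulus class);
    lower-boundary ("new") responses carry a negative sign."""
    out = {}
    for (cond, cl), sub in trials.groupby(["condition", "stimulus_class"],
                                          observed=True):
        signed = np.where(sub["response"] == "old", sub["rt"], -sub["rt"])
        out[(cond, cl)] = np.sort(signed.astype(float))
    return out


def restricted_fit(trials: pd.DataFrame, free_param: str,
                   objective: str = "ks", s: float = 0.1, **kw) -> FitResult:
    """Fit several conditions jointly with all parameters shared except one.

    ``free_param`` is one of ``v``, ``a``, ``zr``, ``t0`` (a shared drift
    rate is still separated by stimulus class).  Used to ask which single
    parameter suffices to explain a within-subject manipulation.
    """
    from .ks import ks_fit
    from .chisq import chisq_fit

    if trials["condition"].nunique() < 2:
        raise ValueError("restricted fits need at least two conditions")
    design = DesignMatrix.restricted(free_param)
    fit = {"ks": ks_fit, "chisq": chisq_fit}[objective]
    return fit(trials, design=design, s=s, **kw)
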