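"""Seeded trial-level simulation and synthetic recognition-memory studies.

The default sampler draws signed response times by inverse-CDF sampling
on a dense grid of the model-predicted signed-RT distribution, so that
simulated data agree with :mod:`driftfit.wfpt` by construction.  An
Euler–Maruyama path simulator is also provided; it is deliberately
independent of the first-passage series and serves as a cross-check.

Three study generators emulate recognition-memory experiments:

* ``exp1`` — old:new test-ratio manipulation (140:70 vs 70:140 trials),
  two between-subject groups of 30, biasing the relative start point.
* ``exp2`` — speed vs accuracy feedback (140+140 trials), two groups of
  30, moving boundary separation and non-decision time.
* ``exp3`` — within-subject presentation frequency (not presented /
  once / twice, 90 trials each), moving the drift rate.

Group-mean parameters and between-participant SDs default to published
group-level diffusion-model estimates for these three manipulations;
participants draw their true parameters from truncated normals around
the group means.  A 4-s response deadline flags (but keeps) slow trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import Boundary, DiffusionParams
from . import wfpt

TRIAL_COLUMNS = ["participant", "group", "condition", "stimulus_class",
                 "response", "rt", "censored"]

DEADLINE_S = 4.0


# ---------------------------------------------------------------------------
# trial-level sampling

def _signed_grid(p: DiffusionParams, n_grid: int) -> tuple[np.ndarray, np.ndarray]:
    """Signed-RT grid and CDF values covering all but ~1e-9 of the mass."""
    vs = p.v / p.s
    as_ = p.a / p.s
    lam1 = (vs**2 + (math.pi / as_) ** 2) / 2.0  # slowest decay rate
    t_dec_max = 23.0 / lam1 + 0.1
    hi = p.t0 + p.st / 2.0 + t_dec_max
    lo = max(p.t0 - p.st / 2.0, 0.0)
    tg = np.linspace(lo, hi, n_grid)
    grid = np.concatenate([-tg[::-1], tg])
    cdf = wfpt.predicted_signed_cdf(grid, p)
    return grid, cdf


def sample_trials(p: DiffusionParams, n: int, rng: np.random.Generator,
                  n_grid: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (boundary, rt) pairs from the model's predicted law.

    Returns ``(upper, rt)`` where ``upper`` is a boolean array (True =
    upper-boundary / "old" response) and ``rt`` the response time in
    seconds (decision time + non-decision time).  Across-trial
    variability is included through the mixture CDF.  All randomness
    comes from ``rng``; there is no hidden global state.
    """
    if rng is None:
        raise ValueError("an explicitly seeded numpy Generator is required")
    grid, cdf = _signed_grid(p, n_grid)
    # make the CDF strictly increasing so the inverse is well defined
    cdf = np.maximum.accumulate(cdf) + np.arange(cdf.size) * 1e-15
    u = rng.uniform(cdf[0], cdf[-1], size=n)
    signed = np.interp(u, cdf, grid)
    upper = signed >= 0
    rt = np.abs(signed)
    return upper, rt


def sample_trial(p: DiffusionParams, rng: np.random.Generator) -> tuple[Boundary, float]:
    """Single-trial convenience wrapper around :func:`sample_trials`."""
    upper, rt = sample_trials(p, 1, rng)
    return (Boundary.UPPER if upper[0] else Boundary.LOWER), float(rt[0])


def sample_trials_euler(p: DiffusionParams, n: int, rng: np.random.Generator,
                        dt: float = 1e-4, t_max: float = 60.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Euler–Maruyama path simulation of the same trial law.

    Independent of the first-passage series; used as a simulation
    oracle.  Discretisation bias is O(sqrt(dt)) at the boundaries, so
    keep ``dt`` small relative to ``(a/s)**2``.
    """
    if rng is None:
        raise ValueError("an explicitly seeded numpy Generator is required")
    v = rng.normal(p.v, p.sv, size=n) if p.sv > 0 else np.full(n, p.v)
    z = p.z + (rng.uniform(-0.5, 0.5, size=n) * p.sz if p.sz > 0 else 0.0)
    t0 = p.t0 + (rng.uniform(-0.5, 0.5, size=n) * p.st if p.st > 0 else 0.0)
    x = np.array(z, dtype=float, copy=True) if np.ndim(z) else np.full(n, z)
    alive = np.arange(n)
    upper = np.zeros(n, dtype=bool)
    t_dec = np.full(n, t_max)
    sqdt = math.sqrt(dt) * p.s
    n_steps = int(t_max / dt)
    for step in range(1, n_steps + 1):
        x[alive] += v[alive] * dt + sqdt * rng.standard_normal(alive.size)
        hit_up = x[alive] >= p.a
        hit_lo = x[alive] <= 0.0
        done = hit_up | hit_lo
        if np.any(done):
            idx = alive[done]
            upper[idx] = hit_up[done]
            t_dec[idx] = step * dt
            alive = alive[~done]
            if alive.size == 0:
                break
    return upper, t_dec + t0


# ---------------------------------------------------------------------------
# study designs

@dataclass(frozen=True)
class CellDesign:
    """One (group x condition) cell: trial counts and true parameters.

    Drift rate may differ by stimulus class within the cell (old vs new
    items); all other parameters are shared.
    """

    condition: str
    class_counts: dict[str, int]
    class_drifts: dict[str, float]
    base: DiffusionParams

    def __post_init__(self) -> None:
        if set(self.class_counts) != set(self.class_drifts):
            raise ValueError("class_counts and class_drifts must share keys")
        if any(c < 1 for c in self.class_counts.values()):
            raise ValueError("trial counts must be >= 1")

    def params_for(self, stimulus_class: str) -> DiffusionParams:
        return replace(self.base, v=self.class_drifts[stimulus_class])


@dataclass(frozen=True)
class GroupDesign:
    group: str
    n_participants: int
    cells: tuple[CellDesign, ...]
    #: between-participant SDs keyed by parameter name; drift entries use
    #: "v:<stimulus_class>"; absent keys mean SD 0 (all participants equal)
    between_sd: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ExperimentDesign:
    design_id: str
    groups: tuple[GroupDesign, ...]
    deadline: float = DEADLINE_S


@dataclass
class StudyDataset:
    """Simulated (or imported) trial table plus provenance."""

    trials: pd.DataFrame
    design_id: str = "custom"
    seed: int | None = None
    deadline: float = DEADLINE_S

    def __post_init__(self) -> None:
        missing = set(TRIAL_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        if (self.trials["rt"] <= 0).any():
            raise ValueError("all response times must be positive")
        bad = self.trials["censored"] & (self.trials["rt"] < self.deadline)
        if bad.any():
            raise ValueError("censored trials must have rt >= deadline")


def simulate_condition(cell: CellDesign, deadline: float,
                       rng: np.random.Generator, participant: str,
                       group: str) -> pd.DataFrame:
    """Simulate one participant's trials in one condition cell.

    Old-class trials use the old-item drift, new-class the new-item
    drift; everything else is shared.  Trials slower than the deadline
    are flagged censored, not dropped.
    """
    frames = []
    for cls in sorted(cell.class_counts):
        p = cell.params_for(cls)
        upper, rt = sample_trials(p, cell.class_counts[cls], rng)
        frames.append(pd.DataFrame({
            "participant": participant,
            "group": group,
            "condition": cell.condition,
            "stimulus_class": cls,
            "response": np.where(upper, "old", "new"),
            "rt": rt,
            "censored": rt >= deadline,
        }))
    return pd.concat(frames, ignore_index=True)


_MAX_TRUNC_TRIES = 1000


def _draw_participant_cells(grp: GroupDesign,
                            rng: np.random.Generator) -> list[CellDesign]:
    """Draw one participant's true parameters for every cell of a group.

    Shared parameters (a, zr, t0) are drawn once per participant from a
    normal around the group mean, truncated to the valid region by
    rejection; drift rates are drawn per cell and stimulus class
    (independently — within-participant parameter correlations are not
    modelled).
    """
    sd = grp.between_sd
    if not sd:
        return list(grp.cells)
    base0 = grp.cells[0].base
    shared: dict[str, float] = {}
    for _ in range(_MAX_TRUNC_TRIES):
        cand = {}
        for name in ("a", "zr", "t0"):
            if sd.get(name):
                cand[name] = rng.normal(getattr(base0, name), sd[name])
        try:
            replace(base0, **cand)
        except ValueError:
            continue  # outside the valid region: redraw
        shared = cand
        break
    else:
        raise ValueError("truncation region appears empty for this design")
    cells = []
    for cell in grp.cells:
        drifts = {
            cls: (rng.normal(mu, sd[f"v:{cls}"]) if sd.get(f"v:{cls}") else mu)
            for cls, mu in cell.class_drifts.items()
        }
        cells.append(replace(cell, base=replace(cell.base, **shared),
                             class_drifts=drifts))
    return cells


def generate_experiment(design: ExperimentDesign, seed: int) -> StudyDataset:
    """Simulate a full synthetic study; byte-reproducible from the seed."""
    root = np.random.SeedSequence(seed)
    frames = []
    idx = 0
    for grp in design.groups:
        for i in range(grp.n_participants):
            idx += 1
            rng = np.random.default_rng(root.spawn(1)[0])
            pid = f"p{idx:03d}"
            for cell in _draw_participant_cells(grp, rng):
                frames.append(simulate_condition(cell, design.deadline, rng,
                                                 pid, grp.group))
    trials = pd.concat(frames, ignore_index=True)
    return StudyDataset(trials=trials, design_id=design.design_id, seed=seed,
                        deadline=design.deadline)


# ---------------------------------------------------------------------------
# default study designs (group-mean truths and between-participant SDs)

#: non-decision time is not reported for the ratio-manipulation study;
#: 0.6 s is a documented plausible default (config-overridable)
EXP1_T0_DEFAULT = 0.6
#: bias and threshold defaults for cells where a study did not report them
EXP3_A_DEFAULT = 0.12
EXP3_T0_DEFAULT = 0.55
EXP2_ZR_DEFAULT = 0.55
DEFAULT_UNREPORTED_SD = 0.08


def exp1_design(n_per_group: int = 30, heterogeneity: bool = True,
                s: float = 0.1) -> ExperimentDesign:
    """Old:new ratio manipulation targeting the start point (z/a)."""
    def grp(name, zr, a, v_old, v_new, counts, sds):
        base = DiffusionParams(v=0.0, a=a, zr=zr, t0=EXP1_T0_DEFAULT, s=s)
        cell = CellDesign(condition="test", class_counts=counts,
                          class_drifts={"old": v_old, "new": v_new}, base=base)
        return GroupDesign(group=name, n_participants=n_per_group,
                           cells=(cell,), between_sd=sds if heterogeneity else {})

    old_bias = grp("old-bias", 0.66, 0.14, 0.04, -0.14,
                   {"old": 140, "new": 70},
                   {"zr": 0.09, "a": 0.02, "v:old": 0.05, "v:new": 0.07,
                    "t0": DEFAULT_UNREPORTED_SD})
    new_bias = grp("new-bias", 0.49, 0.13, 0.05, -0.14,
                   {"old": 70, "new": 140},
                   {"zr": 0.10, "a": 0.02, "v:old": 0.08, "v:new": 0.06,
                    "t0": DEFAULT_UNREPORTED_SD})
    return ExperimentDesign(design_id="exp1", groups=(old_bias, new_bias))


def exp2_design(n_per_group: int = 30, heterogeneity: bool = True,
                s: float = 0.1) -> ExperimentDesign:
    """Speed vs accuracy feedback targeting boundary separation."""
    def grp(name, a, t0, v_old, v_new, sds):
        base = DiffusionParams(v=0.0, a=a, zr=EXP2_ZR_DEFAULT, t0=t0, s=s)
        cell = CellDesign(condition="test",
                          class_counts={"old": 140, "new": 140},
                          class_drifts={"old": v_old, "new": v_new}, base=base)
        return GroupDesign(group=name, n_participants=n_per_group,
                           cells=(cell,), between_sd=sds if heterogeneity else {})

    speed = grp("speed", 0.09, 0.54, 0.04, -0.17,
                {"a": 0.02, "t0": 0.08, "v:old": 0.08, "v:new": 0.11,
                 "zr": DEFAULT_UNREPORTED_SD})
    accuracy = grp("accuracy", 0.17, 0.67, 0.05, -0.09,
                   {"a": 0.06, "t0": 0.12, "v:old": 0.06, "v:new": 0.08,
                    "zr": DEFAULT_UNREPORTED_SD})
    return ExperimentDesign(design_id="exp2", groups=(speed, accuracy))


def exp3_design(n_participants: int = 26, heterogeneity: bool = True,
                s: float = 0.1, trials_per_condition: int = 90
                ) -> ExperimentDesign:
    """Presentation-frequency manipulation (within subject) targeting drift.

    Built under the simplified assumptions of closed-form moment-based
    estimation: unbiased start point, no across-trial variability; drift
    magnitudes follow group-level closed-form estimates (the
    not-presented drift points toward the correct "new" response).
    """
    base = DiffusionParams(v=0.0, a=EXP3_A_DEFAULT, zr=0.5, t0=EXP3_T0_DEFAULT, s=s)
    cells = (
        CellDesign(condition="not_presented",
                   class_counts={"new": trials_per_condition},
                   class_drifts={"new": -0.19}, base=base),
        CellDesign(condition="once",
                   class_counts={"old": trials_per_condition},
                   class_drifts={"old": 0.03}, base=base),
        CellDesign(condition="twice",
                   class_counts={"old": trials_per_condition},
                   class_drifts={"old": 0.13}, base=base),
    )
    sds = ({"v:new": 0.06, "v:old": 0.10, "a": 0.02, "t0": 0.06}
           if heterogeneity else {})
    # a within-subject study is one group; drift SDs are per class so the
    # once/twice cells share the "v:old" spread
    grp = GroupDesign(group="within", n_participants=n_participants,
                      cells=cells, between_sd=sds)
    return ExperimentDesign(design_id="exp3", groups=(grp,))


DESIGN_FACTORIES = {"exp1": exp1_design, "exp2": exp2_design, "exp3": exp3_design}


def make_design(design_id: str, **kwargs) -> ExperimentDesign:
    try:
        return DESIGN_FACTORIES[design_id](**kwargs)
    except KeyError:
        raise ValueError(f"unknown design {design_id!r}; expected one of "
                         f"{sorted(DESIGN_FACTORIES)}") from None
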