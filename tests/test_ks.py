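import math

import numpy as np
import pytest
from scipy.special import kolmogorov

from driftfit import (CellDesign, DiffusionParams, ks_fit, ks_statistic,
                      predicted_signed_cdf, sample_trials, simulate_condition)
from driftfit.estimators import DesignMatrix
from driftfit.estimators.ks import kolmogorov_logsf
from tests.conftest import make_trials


class TestKolmogorovLogSf:
    def test_matches_scipy_in_moderate_range(self):
        for x in (1.0, 1.4, 2.0, 3.0):
            assert kolmogorov_logsf(x) == pytest.approx(
                math.log(kolmogorov(x)), rel=1e-8)

    def test_strictly_decreasing_even_where_p_rounds_to_one(self):
        xs = np.linspace(0.2, 1.5, 40)
        vals = [kolmogorov_logsf(x) for x in xs]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestKsStatistic:
    P = {"test": {"old": DiffusionParams(v=0.05, a=0.14, zr=0.5, t0=0.3,
                                         s=0.1)}}

    def test_brute_force_enumeration_of_jump_points(self):
        rts = [0.45, 0.8, 1.4]
        resp = ["old", "new", "old"]
        tr = make_trials(rts, resp, ["old"] * 3)
        signed = sorted(r if p == "old" else -r for r, p in zip(rts, resp))
        # independent enumeration: check both sides of every ECDF jump
        n = 3
        T_expected = 0.0
        for i, x in enumerate(signed, start=1):
            F = predicted_signed_cdf(x, self.P["test"]["old"])
            T_expected = max(T_expected, abs(i / n - F), abs((i - 1) / n - F))
        T, p, detail = ks_statistic(tr, self.P)
        assert T == pytest.approx(T_expected, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_statistic_vanishes_on_model_generated_data(self, rng):
        truth = self.P["test"]["old"]
        upper, rt = sample_trials(truth, 40_000, rng)
        tr = make_trials(rt, np.where(upper, "old", "new"), ["old"] * rt.size)
        T, p, _ = ks_statistic(tr, self.P)
        assert T < 0.012  # ~1.36/sqrt(n) at this n
        assert p > 0.01

    def test_p_in_unit_interval_for_random_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            rts = rng.uniform(0.35, 2.0, n)
            resp = np.where(rng.random(n) < 0.5, "old", "new")
            tr = make_trials(rts, resp, ["old"] * n)
            _, p, _ = ks_statistic(tr, self.P)
            assert 0.0 <= p <= 1.0


class TestKsFit:
    def test_recovery_on_large_sample(self, rng):
        truth = DiffusionParams(v=0.08, a=0.13, zr=0.6, t0=0.45, s=0.1)
        cell = CellDesign(condition="test", class_counts={"old": 5000},
                          class_drifts={"old": truth.v},
                          base=truth)
        df = simulate_condition(cell, np.inf, rng, "p1", "g")
        res = ks_fit(df, restarts=1)
        est = res.params["test"]["old"]
        assert est.v == pytest.approx(truth.v, rel=0.05)
        assert est.a == pytest.approx(truth.a, rel=0.05)
        assert est.zr == pytest.approx(truth.zr, rel=0.05)
        assert est.t0 == pytest.approx(truth.t0, rel=0.05)

    def test_estimator_consistency_error_shrinks_with_n(self, rng):
        truth = DiffusionParams(v=0.08, a=0.13, zr=0.6, t0=0.45, s=0.1)
        errs = {}
        for n in (250, 5000):
            rel = []
            for rep in range(3):
                cell = CellDesign(condition="test", class_counts={"old": n},
                                  class_drifts={"old": truth.v}, base=truth)
                df = simulate_condition(cell, np.inf, rng, f"p{rep}", "g")
                est = ks_fit(df, restarts=1).params["test"]["old"]
                rel.append(np.median([
                    abs(est.v - truth.v) / truth.v,
                    abs(est.a - truth.a) / truth.a,
                    abs(est.zr - truth.zr) / truth.zr,
                    abs(est.t0 - truth.t0) / truth.t0]))
            errs[n] = np.median(rel)
        assert errs[5000] < errs[250]

    def test_shared_design_on_identical_conditions(self, rng):
        """Two conditions generated from one parameter set: the all-shared
        (restricted) fit must achieve an objective no better than, and
        close to, the sum of free per-condition fits."""
        truth = DiffusionParams(v=0.07, a=0.13, zr=0.55, t0=0.4, s=0.1)
        frames = []
        for cond in ("c1", "c2"):
            cell = CellDesign(condition=cond, class_counts={"old": 400},
                              class_drifts={"old": truth.v}, base=truth)
            frames.append(simulate_condition(cell, np.inf, rng, "p1", "g"))
        import pandas as pd
        both = pd.concat(frames, ignore_index=True)
        shared = ks_fit(both, design=DesignMatrix(v="shared"), restarts=1)
        free_obj = 0.0
        for f in frames:
            r = ks_fit(f, restarts=1)
            free_obj += -math.log(max(r.p, 1e-300))
        shared_obj = -math.log(max(shared.p, 1e-300))
        assert shared_obj >= free_obj - 0.2   # nested-model inequality
        assert shared.p > 0.05                # and the shared fit is adequate

    def test_degenerate_single_boundary_data_does_not_crash(self):
        tr = make_trials([0.5, 0.6, 0.7, 0.8], "old", "old")
        res = ks_fit(tr, restarts=0, maxiter=150)
        assert res.statistic >= 0

    def test_determinism(self, exp1_participant):
        r1 = ks_fit(exp1_participant, restarts=1)
        r2 = ks_fit(exp1_participant, restarts=1)
        assert r1.params == r2.params
        assert r1.statistic == r2.statistic
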