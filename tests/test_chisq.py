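import warnings

import numpy as np
import pytest

from driftfit import (CellDesign, DiffusionParams, chisq_fit,
                      chisq_statistic, predicted_signed_cdf,
                      simulate_condition)
from tests.conftest import make_trials


PARAMS = {"test": {"old": DiffusionParams(v=0.06, a=0.14, zr=0.5, t0=0.3,
                                          s=0.1)}}


def _hand_chisq(trials, params):
    """Independent re-derivation: quantile edges per response, expected
    counts from the signed CDF, straight summation (no collapsing)."""
    sub = trials
    n_class = len(sub)
    x2 = 0.0
    n_bins = 0
    for resp, sign in (("new", -1.0), ("old", 1.0)):
        rts = np.sort(sub.loc[sub["response"] == resp, "rt"].to_numpy(float))
        q = np.quantile(rts, [0.1, 0.3, 0.5, 0.7, 0.9])
        edges = np.concatenate([[0.0], q, [np.inf]])
        obs = np.histogram(rts, edges)[0]
        signed_edges = np.sort(sign * edges[np.isfinite(edges)])
        F = predicted_signed_cdf(signed_edges, params)
        if sign > 0:
            F = np.concatenate([F, [1.0]])
        else:
            F = np.concatenate([[0.0], F])
            obs = obs[::-1]
        exp = np.diff(F) * n_class
        x2 += float(np.sum((obs - exp) ** 2 / exp))
        n_bins += 6
    return x2, n_bins


class TestChisqStatistic:
    def test_matches_hand_summation(self, rng):
        # plenty of trials on both sides so no bin collapsing occurs
        p = PARAMS["test"]["old"]
        cell = CellDesign(condition="test", class_counts={"old": 400},
                          class_drifts={"old": p.v},
                          base=p)
        df = simulate_condition(cell, np.inf, rng, "p1", "g")
        x2_hand, n_bins = _hand_chisq(df, p)
        x2, df_stat, pval = chisq_statistic(df, PARAMS, n_free=5)
        assert x2 == pytest.approx(x2_hand, rel=1e-10)
        assert df_stat == n_bins - 1 - 5
        assert 0.0 <= pval <= 1.0

    def test_statistic_small_on_model_generated_data(self, rng):
        p = PARAMS["test"]["old"]
        cell = CellDesign(condition="test", class_counts={"old": 2000},
                          class_drifts={"old": p.v}, base=p)
        df = simulate_condition(cell, np.inf, rng, "p1", "g")
        x2, dof, pval = chisq_statistic(df, PARAMS)
        assert pval > 0.001  # truth should not be rejected wildly

    def test_sparse_side_collapses_instead_of_failing(self):
        # 2 errors only: their expected bins are tiny and must be merged
        rts = list(np.linspace(0.4, 1.6, 40)) + [0.5, 0.9]
        resp = ["old"] * 40 + ["new"] * 2
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            x2, dof, pval = chisq_statistic(
                make_trials(rts, resp, ["old"] * 42), PARAMS)
            assert any("unstable" in str(x.message) for x in w)
        assert np.isfinite(x2) and x2 >= 0


class TestChisqFit:
    def test_recovery_on_large_sample(self, rng):
        truth = DiffusionParams(v=0.08, a=0.13, zr=0.6, t0=0.45, s=0.1)
        cell = CellDesign(condition="test", class_counts={"old": 5000},
                          class_drifts={"old": truth.v}, base=truth)
        df = simulate_condition(cell, np.inf, rng, "p1", "g")
        res = chisq_fit(df, restarts=1)
        est = res.params["test"]["old"]
        assert est.v == pytest.approx(truth.v, rel=0.07)
        assert est.a == pytest.approx(truth.a, rel=0.07)
        assert est.zr == pytest.approx(truth.zr, rel=0.07)
        assert est.t0 == pytest.approx(truth.t0, rel=0.07)

    def test_few_errors_warns_but_returns_estimate(self, rng):
        truth = DiffusionParams(v=0.25, a=0.16, zr=0.5, t0=0.4, s=0.1)
        cell = CellDesign(condition="test", class_counts={"old": 120},
                          class_drifts={"old": truth.v}, base=truth)
        df = simulate_condition(cell, np.inf, rng, "p1", "g")
        assert (df["response"] == "new").sum() < 11  # near-perfect accuracy
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            res = chisq_fit(df, restarts=0, maxiter=300)
        assert any("unstable" in str(x.message) for x in w)
        assert res.params["test"]["old"].a > 0

    def test_determinism(self, exp1_participant):
        r1 = chisq_fit(exp1_participant, restarts=0, maxiter=400)
        r2 = chisq_fit(exp1_participant, restarts=0, maxiter=400)
        assert r1.params == r2.params
        assert r1.statistic == r2.statistic
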