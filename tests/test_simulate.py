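import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import ks_2samp

from driftfit import (Boundary, CellDesign, DiffusionParams,
                      absorption_probability, fpt_density,
                      generate_experiment, make_design, sample_trial,
                      sample_trials, simulate_condition, trim_trials)
from driftfit.simulate import StudyDataset


class TestSampleTrials:
    def test_requires_seeded_generator(self):
        with pytest.raises(ValueError):
            sample_trials(DiffusionParams(v=0.1, a=0.14), 10, None)

    def test_extreme_drift_dominates(self, rng):
        p = DiffusionParams(v=10.0, a=0.14, zr=0.5, s=0.1)
        upper, _ = sample_trials(p, 500, rng)
        assert upper.all()

    def test_rt_support_bound(self, rng):
        p = DiffusionParams(v=0.05, a=0.14, zr=0.5, t0=0.5, st=0.2, s=0.1)
        _, rt = sample_trials(p, 2000, rng)
        assert (rt >= p.t0 - p.st / 2).all()

    def test_choice_proportion_matches_closed_form(self, rng):
        p = DiffusionParams(v=0.04, a=0.14, zr=0.66, s=0.1)
        n = 100_000
        upper, _ = sample_trials(p, n, rng)
        se = np.sqrt(0.776 * (1 - 0.776) / n)
        assert abs(upper.mean() - 0.776) < 3 * se + 5e-4

    def test_choice_proportions_across_random_parameter_sets(self, rng):
        for _ in range(20):
            p = DiffusionParams(v=rng.uniform(-0.2, 0.2),
                                a=rng.uniform(0.08, 0.2),
                                zr=rng.uniform(0.25, 0.75), s=0.1)
            n = 20_000
            upper, _ = sample_trials(p, n, rng)
            pu = absorption_probability(p)
            se = np.sqrt(pu * (1 - pu) / n)
            assert abs(upper.mean() - pu) < 4 * se + 1e-3

    def test_rt_moments_match_density_quadrature(self, rng):
        # E[RT] and Var[RT] from the sampler vs numeric integration
        p = DiffusionParams(v=0.08, a=0.14, zr=0.5, t0=0.3, s=0.1)
        n = 60_000
        upper, rt = sample_trials(p, n, rng)
        m1 = sum(quad(lambda t: t * fpt_density(t, p, b), 1e-9, 30,
                      limit=200)[0] for b in Boundary)
        m2 = sum(quad(lambda t: t * t * fpt_density(t, p, b), 1e-9, 30,
                      limit=200)[0] for b in Boundary)
        mean_pred = m1 + p.t0
        var_pred = m2 - m1**2
        assert rt.mean() == pytest.approx(mean_pred, abs=4 * np.sqrt(var_pred / n))
        assert rt.var() == pytest.approx(var_pred, rel=0.05)

    def test_single_trial_wrapper(self, rng):
        b, rt = sample_trial(DiffusionParams(v=0.1, a=0.14, t0=0.3), rng)
        assert b in (Boundary.UPPER, Boundary.LOWER)
        assert rt > 0.3


class TestSimulateCondition:
    CELL = CellDesign(condition="test", class_counts={"old": 140, "new": 70},
                      class_drifts={"old": 0.04, "new": -0.14},
                      base=DiffusionParams(v=0, a=0.14, zr=0.66, t0=0.6, s=0.1))

    def test_trial_counts(self, rng):
        df = simulate_condition(self.CELL, 4.0, rng, "p1", "g")
        assert len(df) == 210
        assert (df["stimulus_class"] == "old").sum() == 140
        assert (df["stimulus_class"] == "new").sum() == 70

    def test_infinite_deadline_never_censors(self, rng):
        df = simulate_condition(self.CELL, np.inf, rng, "p1", "g")
        assert not df["censored"].any()

    def test_equal_drifts_make_classes_exchangeable(self, rng):
        cell = CellDesign(condition="test",
                          class_counts={"old": 4000, "new": 4000},
                          class_drifts={"old": 0.06, "new": 0.06},
                          base=DiffusionParams(v=0, a=0.14, zr=0.5, t0=0.4,
                                               s=0.1))
        df = simulate_condition(cell, np.inf, rng, "p1", "g")
        old = df.loc[df["stimulus_class"] == "old", "rt"]
        new = df.loc[df["stimulus_class"] == "new", "rt"]
        assert ks_2samp(old, new).pvalue > 0.01


class TestGenerateExperiment:
    def test_exp1_shape(self):
        ds = generate_experiment(make_design("exp1"), seed=3)
        counts = ds.trials.groupby("participant").size()
        assert len(counts) == 60
        assert (counts == 210).all()
        assert set(ds.trials["group"]) == {"old-bias", "new-bias"}

    def test_reproducible_from_seed(self):
        d1 = generate_experiment(make_design("exp3", n_participants=4), 11)
        d2 = generate_experiment(make_design("exp3", n_participants=4), 11)
        pd.testing.assert_frame_equal(d1.trials, d2.trials)

    def test_different_seeds_differ(self):
        d1 = generate_experiment(make_design("exp3", n_participants=2), 1)
        d2 = generate_experiment(make_design("exp3", n_participants=2), 2)
        assert not d1.trials["rt"].equals(d2.trials["rt"])

    def test_censoring_and_trimming_rare_under_default_designs(self):
        ds = generate_experiment(make_design("exp1"), seed=5)
        assert ds.trials["censored"].mean() < 0.05
        _, n_excl = trim_trials(ds.trials)
        assert n_excl / len(ds.trials) < 0.05

    def test_dataset_invariants_enforced(self):
        bad = pd.DataFrame({"participant": ["p1"], "group": ["g"],
                            "condition": ["test"], "stimulus_class": ["old"],
                            "response": ["old"], "rt": [-0.5],
                            "censored": [False]})
        with pytest.raises(ValueError):
            StudyDataset(trials=bad)
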