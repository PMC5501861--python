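"""Observation layers: scaling, detection, conversions, survey sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from apedyn import reference
from apedyn.observation import (ObservationParams, SurveyData, SurveyDesign,
                                aerial_index_to_nest_density,
                                interview_detection_prob,
                                nest_count_detection_prob,
                                nest_occurrence_detection_prob,
                                nest_scaling_factor, nest_state,
                                orangutan_density_from_nests,
                                sample_observations)


def _indicators(**flags):
    base = {"MGV": 0, "PT": 0, "LOWL": 0, "MONT": 0, "FRGM": 0}
    base.update(flags)
    return pd.DataFrame([base])


@pytest.mark.parametrize("flags,days", [
    ({}, 228), ({"MGV": 1}, 266), ({"PT": 1}, 209),
    ({"LOWL": 1}, 244), ({"MONT": 1}, 236)])
def test_decay_days_by_forest_type(flags, days):
    """The nest scaling factor at the reference coefficients reproduces the
    published decay times: 228 baseline, 266 mangrove, 209 peat, 244
    lowland, 236 montane days."""
    p = reference.borneo_observation_params()
    psi = nest_scaling_factor(p, _indicators(**flags))
    assert round(float(psi[0])) == days


def test_scaling_factor_trivial_and_invalid():
    p = ObservationParams(upsilon=[0, 0], gamma=[1, 0, 0, 0, 0, 0],
                          mu=[0, 0], zeta=0.0)
    assert float(nest_scaling_factor(p, _indicators())[0]) == 100.0
    p.gamma = np.array([-1.0, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError, match="positive"):
        nest_scaling_factor(p, _indicators())


@pytest.mark.parametrize("fn,args,pct", [
    (nest_count_detection_prob, ("aerial",), 82),
    (nest_count_detection_prob, ("ground",), 75),
    (nest_occurrence_detection_prob, (), 64),
    (interview_detection_prob, (0,), 15),
    (interview_detection_prob, (1,), 21)])
def test_detection_percentages(fn, args, pct):
    """Inverse-logit of the reference posterior means rounds to the
    published detection percentages."""
    p = reference.borneo_observation_params()
    assert round(100 * float(fn(p, *args))) == pct


def test_neutral_detection_probs():
    p = ObservationParams(upsilon=[0, 0], gamma=[1, 0, 0, 0, 0, 0],
                          mu=[0, 0], zeta=0.0)
    assert nest_count_detection_prob(p, "aerial") == 0.5
    assert nest_occurrence_detection_prob(p) == 0.5
    assert interview_detection_prob(p, 0) == interview_detection_prob(p, 1) == 0.5
    p.zeta = 4.0
    assert abs(nest_occurrence_detection_prob(p) - 0.982) < 1e-3


def test_unknown_protocol():
    p = reference.borneo_observation_params()
    with pytest.raises(ValueError, match="protocol"):
        nest_count_detection_prob(p, "drone")


def test_probabilities_bounded_under_priors():
    """Within the [-4, 4] logit prior bounds all detection probabilities
    stay inside (0.018, 0.982)."""
    rng = np.random.default_rng(4)
    for _ in range(200):
        p = ObservationParams(upsilon=rng.uniform(-4, 4, 2),
                              gamma=rng.uniform(-10, 10, 6),
                              mu=rng.uniform(-4, 4, 2),
                              zeta=float(rng.uniform(-4, 4)))
        probs = [nest_count_detection_prob(p, "aerial"),
                 nest_count_detection_prob(p, "ground"),
                 nest_occurrence_detection_prob(p)]
        fe_probs = [interview_detection_prob(p, 0)]
        if -4 <= p.upsilon.sum() <= 4:   # combined logit within bounds
            fe_probs.append(interview_detection_prob(p, 1))
        for pr in probs + fe_probs:
            assert 0.0179 < pr < 0.9821


def test_aerial_index_conversion():
    assert np.isclose(aerial_index_to_nest_density(1.0), np.exp(4.7297))
    assert abs(aerial_index_to_nest_density(1.0) - 113.3) < 0.1
    ratio = aerial_index_to_nest_density(2.0) / aerial_index_to_nest_density(1.0)
    assert np.isclose(ratio, 2 ** 0.9796)
    with pytest.warns(UserWarning):
        assert aerial_index_to_nest_density(0.0) == 0.0
    with pytest.raises(ValueError):
        aerial_index_to_nest_density(-1.0)


def test_density_from_nests():
    assert np.isclose(orangutan_density_from_nests(228.0, b=1.0, q=1.0,
                                                   d=228.0), 1.0)
    assert np.isclose(orangutan_density_from_nests(100.0, b=0.9, q=1.1,
                                                   d=200.0), 100 / 198.0)
    with pytest.raises(ValueError):
        orangutan_density_from_nests(100.0, b=0.0)


# ---------------------------------------------------------------------------
# survey sampling


def _toy_latents(C=6, T=2, seed=0):
    rng = np.random.default_rng(seed)
    O = rng.integers(0, 2, (C, T))
    Nou = rng.integers(0, 4, (C, T)) * O
    psi = np.full((C, T), 100.0)
    return O, Nou, nest_state(Nou, psi)


def _design(C, T, all_on=True):
    mask = np.full((C, T), all_on)
    return SurveyDesign(count_cells={"aerial": mask.copy(), "ground": mask.copy()},
                        occurrence_cells=mask.copy(),
                        interview_cells=np.ones(C, bool))


def test_perfect_detection_recovers_nest_counts(rng):
    O, Nou, nest = _toy_latents()
    p = ObservationParams(upsilon=[0, 0], gamma=[1, 0, 0, 0, 0, 0],
                          mu=[40.0, 40.0], zeta=0.0)   # xi ~ 1
    data = sample_observations(nest, O, p, _design(6, 2), rng)
    for j in range(2):
        assert np.array_equal(data.Y[:, j, :], nest.Nnest)


def test_unoccupied_cells_yield_no_reports(rng):
    C, T = 6, 2
    O = np.zeros((C, T), dtype=int)
    nest = nest_state(np.zeros((C, T), dtype=int), np.full((C, T), 100.0))
    p = reference.borneo_observation_params()
    data = sample_observations(nest, O, p, _design(C, T), rng)
    assert np.nansum(data.Zou) == 0
    assert np.nansum(data.Znest) == 0


def test_subcell_positive_fraction_matches_rho(rng):
    """With Onest = 1 everywhere, the positive sub-cell fraction estimates
    rho_nest = 0.64 within Monte-Carlo error."""
    C, T = 100, 1
    O = np.ones((C, T), dtype=int)
    nest = nest_state(np.ones((C, T), dtype=int), np.full((C, T), 100.0))
    p = reference.borneo_observation_params()
    total = pos = 0
    for _ in range(100):
        d = sample_observations(nest, O, p, _design(C, T), rng)
        pos += np.nansum(d.Znest == 1)
        total += np.isfinite(d.Znest).sum()
    frac = pos / total
    rho = nest_occurrence_detection_prob(p)
    se = np.sqrt(rho * (1 - rho) / total)
    assert abs(frac - rho) < 3 * se


def test_empty_design_masks_everything(rng):
    O, Nou, nest = _toy_latents()
    p = reference.borneo_observation_params()
    design = _design(6, 2, all_on=False)
    design.interview_cells = np.zeros(6, bool)
    data = sample_observations(nest, O, p, design, rng)
    assert np.all(np.isnan(data.Y))
    assert np.all(np.isnan(data.Znest))
    assert np.all(np.isnan(data.Zou))


def test_survey_data_validation():
    Y = np.full((2, 2, 1), np.nan)
    Y[0, 0, 0] = -1
    with pytest.raises(ValueError):
        SurveyData(Y=Y, Znest=np.full((2, 25, 1), np.nan),
                   Zou=np.full((2, 10, 1), np.nan), FE=np.full((2, 10), np.nan))
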