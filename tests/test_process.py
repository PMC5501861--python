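"""Level-1 link functions, neighbourhood recruitment and dynamics."""

import numpy as np
import pytest
from scipy.special import expit

from apedyn.landscape import build_neighbor_graph
from apedyn.process import (LatentTrajectory, ProcessParams, design_matrix,
                            initial_abundance_rate, neighborhood_mean,
                            occupancy_rate, recruitment_rate, simulate_dynamics,
                            survival_rate)
from apedyn import reference
from conftest import make_landscape, make_z


def _zero_z(C, T):
    z = make_z(C, T)
    for name in ("ALT", "DRY", "WET", "MS"):
        setattr(z, name, np.zeros(C))
    for name in ("DPA", "FR", "CFA"):
        setattr(z, name, np.zeros((C, T)))
    return z


def _oracle_linear_predictor(coef, z, cell, period):
    """Independent term-by-term evaluation of the covariate link."""
    return (coef[0]
            + coef[1] * z.ALT[cell] + coef[2] * z.ALT[cell] ** 2
            + coef[3] * z.DRY[cell] + coef[4] * z.DRY[cell] ** 2
            + coef[5] * z.WET[cell] + coef[6] * z.WET[cell] ** 2
            + coef[7] * z.DPA[cell, period] + coef[8] * z.MS[cell]
            + coef[9] * z.FR[cell, period]
            + coef[10] * z.FR[cell, period] * z.CFA[cell, period])


def test_reference_intercepts_give_printed_rates():
    """At mean covariates the reference coefficients give the familiar
    baseline rates: ~2.78 animals/km2, 81% occupancy, 93% survival."""
    z = _zero_z(3, 2)
    p = reference.borneo_process_params()
    assert np.isclose(initial_abundance_rate(p, z, cell=0), np.exp(1.023))
    assert abs(initial_abundance_rate(p, z, cell=0) - 2.782) < 1e-3
    assert np.isclose(occupancy_rate(p, z, 0, cell=0), expit(1.423))
    assert abs(occupancy_rate(p, z, 0, cell=0) - 0.806) < 1e-3
    assert np.isclose(survival_rate(p, z, 0, cell=0), expit(2.662))
    assert abs(survival_rate(p, z, 0, cell=0) - 0.935) < 1e-3


def test_zero_coefficients_give_neutral_rates():
    z = make_z(4, 2, seed=1)
    p = ProcessParams(alpha=np.zeros(11), beta=np.zeros(11),
                      eta=np.zeros(11), chi=0.0)
    assert np.allclose(initial_abundance_rate(p, z), 1.0)
    assert np.allclose(occupancy_rate(p, z, 1), 0.5)
    assert np.allclose(survival_rate(p, z, 1), 0.5)


def test_links_match_term_by_term_oracle():
    rng = np.random.default_rng(99)
    z = make_z(30, 3, seed=5)
    for _ in range(1000):
        coef = rng.normal(0, 2, 11)
        cell = int(rng.integers(30))
        t = int(rng.integers(3))
        lp = _oracle_linear_predictor(coef, z, cell, t)
        p = ProcessParams(alpha=coef, beta=coef, eta=coef, chi=0.0)
        assert abs(np.log(initial_abundance_rate(p, z, cell=cell))
                   - _oracle_linear_predictor(coef, z, cell, 0)) < 1e-10
        assert abs(occupancy_rate(p, z, t, cell=cell) - expit(lp)) < 1e-10
        assert abs(survival_rate(p, z, t, cell=cell) - expit(lp)) < 1e-10


def test_survival_increases_with_forest_when_eta10_positive():
    p = reference.borneo_process_params()   # eta10 = 0.133 > 0
    z = _zero_z(1, 1)
    vals = []
    for fr in (-1.0, 0.0, 1.0, 2.0):
        z.FR[0, 0] = fr
        vals.append(survival_rate(p, z, 0, cell=0))
    assert np.all(np.diff(vals) > 0)


def test_dry_response_unimodal_with_argmax():
    rng = np.random.default_rng(0)
    a4, a5 = 2.0, -1.5   # concave in DRY
    p = ProcessParams(alpha=[0.3, 0, 0, a4, a5, 0, 0, 0, 0, 0, 0],
                      beta=np.zeros(11), eta=np.zeros(11), chi=0.0)
    z = _zero_z(1, 1)
    grid = np.linspace(-3, 3, 601)
    lam = []
    for d in grid:
        z.DRY[0] = d
        lam.append(initial_abundance_rate(p, z, cell=0))
    argmax = grid[int(np.argmax(lam))]
    assert abs(argmax - (-a4 / (2 * a5))) < 0.02


def test_neighborhood_mean_cases():
    land = make_landscape(nrow=5, ncol=5)
    g = build_neighbor_graph(land, [])
    interior = 12
    N = np.ones(25)
    assert np.isclose(neighborhood_mean(N, g)[interior], 1.0)
    # all barriers: only the self term remains, divisor unchanged
    g.w[:] = 0.0
    N = np.zeros(25)
    N[interior] = 9
    assert np.isclose(neighborhood_mean(N, g)[interior], 1.0)   # 9 / (8+1)


def test_neighborhood_mean_corner_hand_value():
    land = make_landscape(nrow=3, ncol=3)
    g = build_neighbor_graph(land, [])
    N = np.zeros(9)
    N[0] = 2                     # corner, neighbours 1, 3, 4
    N[1], N[3], N[4] = 2, 0, 4
    assert np.isclose(neighborhood_mean(N, g)[0], (2 + 0 + 4 + 2) / 4.0)


def test_recruitment_rate():
    p = ProcessParams(alpha=np.zeros(11), beta=np.zeros(11),
                      eta=np.zeros(11), chi=-2.265)
    assert np.isclose(recruitment_rate(p, 1.0), np.exp(-2.265))
    assert abs(recruitment_rate(p, 1.0) - 0.1038) < 1e-4
    assert recruitment_rate(p, 0.0) == 0.0
    p.chi = 0.0
    assert np.isclose(recruitment_rate(p, 3.5), 3.5)


def _one_cell_setup(lam, phi_logit, theta_logit, chi):
    land = make_landscape(nrow=1, ncol=2)   # 2 cells so SDs exist
    g = build_neighbor_graph(land, [])
    z = _zero_z(2, 3)
    p = ProcessParams(
        alpha=[np.log(lam)] + [0.0] * 10,
        beta=[phi_logit] + [0.0] * 10,
        eta=[theta_logit] + [0.0] * 10, chi=chi)
    return p, z, g


def test_dynamics_expectation_pure_survival(rng):
    """theta -> 1, delta -> 0, phi -> 1: abundance is conserved in
    expectation (Poisson thinning keeps the mean)."""
    p, z, g = _one_cell_setup(lam=3.0, phi_logit=30.0, theta_logit=30.0,
                              chi=-60.0)
    tot = np.zeros(2)
    reps = 10_000
    for _ in range(reps):
        traj = simulate_dynamics(p, z, g, 2, rng)
        tot += traj.Nou[0]
    mean2 = tot[1] / reps
    # E[Nou2] = lam = 3; MC SE of a compound Poisson mean
    se = np.sqrt(2 * 3.0 / reps)   # Var <= Var(Pois(Pois)) ~ 2 lam
    assert abs(mean2 - 3.0) < 3 * se


def test_dynamics_expectation_half_survival(rng):
    """lambda=2, phi=1, theta=0.5, delta=0: E[Nou2] = 1."""
    p, z, g = _one_cell_setup(lam=2.0, phi_logit=30.0, theta_logit=0.0,
                              chi=-60.0)
    tot = 0.0
    reps = 10_000
    for _ in range(reps):
        tot += simulate_dynamics(p, z, g, 2, rng).Nou[0, 1]
    se = np.sqrt(2.5 / reps)
    assert abs(tot / reps - 1.0) < 3 * se


def test_unoccupied_everywhere_means_zero(rng):
    p, z, g = _one_cell_setup(lam=5.0, phi_logit=-40.0, theta_logit=0.0,
                              chi=0.0)
    traj = simulate_dynamics(p, z, g, 3, rng)
    assert np.all(traj.Nou == 0) and np.all(traj.O == 0)


def test_trajectory_invariants_on_simulations(rng):
    land = make_landscape(nrow=6, ncol=6, seed=8)
    g = build_neighbor_graph(land, [])
    z = make_z(36, 3, seed=8)
    p = ProcessParams(alpha=[0.5] + [0.1] * 10, beta=[0.5] + [0.1] * 10,
                      eta=[1.0] + [0.1] * 10, chi=-1.0)
    for _ in range(20):
        traj = simulate_dynamics(p, z, g, 3, rng)
        traj.validate()                       # raises on violation
        assert np.all(traj.Ntilde == traj.S + traj.R)


def test_reproducible_from_seed():
    land = make_landscape(nrow=4, ncol=4)
    g = build_neighbor_graph(land, [])
    z = make_z(16, 2)
    p = ProcessParams(alpha=[0.5] + [0.0] * 10, beta=[0.5] + [0.0] * 10,
                      eta=[1.0] + [0.0] * 10, chi=-1.0)
    t1 = simulate_dynamics(p, z, g, 2, np.random.default_rng(7))
    t2 = simulate_dynamics(p, z, g, 2, np.random.default_rng(7))
    assert np.array_equal(t1.Nou, t2.Nou) and np.array_equal(t1.O, t2.O)


def test_rivers_confine_recruitment(rng):
    """With every link severed, a population seeded on one side of a
    barrier never recruits across it (NEIGH decomposition)."""
    land = make_landscape(nrow=1, ncol=4)
    g = build_neighbor_graph(land, [])
    g.w[:] = 0.0                       # hard barrier everywhere
    N = np.array([5.0, 0.0, 0.0, 0.0])
    neigh = neighborhood_mean(N, g)
    assert neigh[0] > 0 and np.all(neigh[1:] == 0.0)
    p = ProcessParams(alpha=np.zeros(11), beta=np.zeros(11),
                      eta=np.zeros(11), chi=0.0)
    assert np.all(recruitment_rate(p, neigh)[1:] == 0.0)


def test_non_finite_rate_raises():
    land = make_landscape(nrow=1, ncol=2)
    g = build_neighbor_graph(land, [])
    z = _zero_z(2, 2)
    z.ALT[0] = np.nan
    p = ProcessParams(alpha=[0.5] + [0.1] * 10, beta=np.zeros(11),
                      eta=np.zeros(11), chi=0.0)
    with pytest.raises(FloatingPointError, match="cell 1"):
        simulate_dynamics(p, z, g, 2, np.random.default_rng(0))
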