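"""Joint density, sampler correctness and posterior summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from apedyn.inference import (ChainSet, MCMCConfig, Model, PriorSpec,
                              forest_indicator_array, log_posterior,
                              pack_params, rhat, run_mcmc,
                              summarize_posterior, unpack_params, PARAM_NAMES,
                              NPARAM)
from apedyn.landscape import build_neighbor_graph, StandardizedCovariates
from apedyn.observation import ObservationParams, SurveyData
from apedyn.process import LatentTrajectory, ProcessParams, design_matrix, \
    neighborhood_mean
from conftest import make_landscape, make_z


# ---------------------------------------------------------------------------
# shared toy study


def toy_study(nrow=1, ncol=2, T=2, seed=0):
    land = make_landscape(nrow=nrow, ncol=ncol, T=T, seed=seed,
                          village_all=True)
    C = land.ncell
    z = make_z(C, T, seed=seed)
    graph = build_neighbor_graph(land, [])
    ind = forest_indicator_array(land)
    rng = np.random.default_rng(seed)
    Y = np.full((C, 2, T), np.nan)
    Y[0, 1, 0] = 150
    Znest = np.full((C, 25, T), np.nan)
    Znest[0, :5, 0] = [1, 0, 1, 0, 0]
    Znest[C - 1, :5, T - 1] = [1, 0, 0, 1, 0]
    Zou = np.full((C, 10, T), np.nan)
    Zou[0, :4, 0] = [1, 0, 0, 0]
    Zou[C - 1, :4, T - 1] = [0, 0, 0, 0]
    FE = np.full((C, 10), np.nan)
    FE[0, :4] = [1, 0, 1, 0]
    FE[C - 1, :4] = [0, 1, 1, 0]
    data = SurveyData(Y=Y, Znest=Znest, Zou=Zou, FE=FE)
    vec = pack_params(
        ProcessParams(alpha=[0.5] + [0.1] * 10, beta=[0.8] + [0.1] * 10,
                      eta=[1.0] + [0.1] * 10, chi=-0.7),
        ObservationParams(upsilon=[-1.0, 0.5], gamma=[2.2, 0, 0, 0.1, 0, 0],
                          mu=[1.5, 1.1], zeta=0.6))
    return land, z, graph, ind, data, vec


def scipy_joint_density(vec, traj, data, z, graph, ind, priors):
    """Independent term-by-term evaluation of the full joint log density
    using scipy.stats pmfs (the exhaustive-factor oracle)."""
    C, T = traj.ncell, traj.nperiod
    O, Nou, S, R = traj.O, traj.Nou, traj.S, traj.R
    if np.any(vec < priors.lower) or np.any(vec > priors.upper):
        return -np.inf
    lp = -np.sum(np.log(priors.upper - priors.lower))
    al, be, et = vec[:11], vec[11:22], vec[22:33]
    chi, up, ga = vec[33], vec[34:36], vec[36:42]
    mu, ze = vec[42:44], vec[44]
    X = [design_matrix(z, t) for t in range(T)]
    lam = np.exp(X[0] @ al)
    for t in range(T):
        phi = expit(X[t] @ be)
        for i in range(C):
            lp += stats.bernoulli.logpmf(O[i, t], phi[i])
    for i in range(C):
        lp += stats.poisson.logpmf(Nou[i, 0], lam[i] * O[i, 0])
    for t in range(T - 1):
        th = expit(X[t + 1] @ et)
        for i in range(C):
            lp += stats.binom.logpmf(S[i, t], Nou[i, t], th[i])
            neigh = neighborhood_mean(Nou[:, t].astype(float), graph)[i]
            delta = np.exp(chi) * neigh
            lp += (stats.poisson.logpmf(R[i, t], delta) if delta > 0
                   else (0.0 if R[i, t] == 0 else -np.inf))
            lp += stats.poisson.logpmf(Nou[i, t + 1],
                                       (S[i, t] + R[i, t]) * O[i, t + 1])
    psi = 100 * (ga[0] + ind @ ga[1:])
    for i in range(C):
        for t in range(T):
            nn = round(psi[i, t] * Nou[i, t])
            for j in range(2):
                if not np.isnan(data.Y[i, j, t]):
                    lp += stats.binom.logpmf(data.Y[i, j, t], nn, expit(mu[j]))
            onest = 1 if nn > 0 else 0
            for k in range(data.Znest.shape[1]):
                if not np.isnan(data.Znest[i, k, t]):
                    lp += stats.bernoulli.logpmf(data.Znest[i, k, t],
                                                 expit(ze) * onest)
            for m in range(data.Zou.shape[1]):
                if not (np.isnan(data.Zou[i, m, t]) or np.isnan(data.FE[i, m])):
                    rho = expit(up[0] + up[1] * data.FE[i, m])
                    lp += stats.bernoulli.logpmf(data.Zou[i, m, t],
                                                 rho * O[i, t])
    return lp


def random_latents(C, T, rng, bound=3):
    O = rng.integers(0, 2, (C, T))
    Nou = rng.integers(0, bound + 1, (C, T)) * O
    S = np.minimum(rng.integers(0, bound + 1, (C, T - 1)), Nou[:, :-1])
    R = rng.integers(0, bound + 1, (C, T - 1))
    return LatentTrajectory(O=O, Nou=Nou, S=S, R=R)


# ---------------------------------------------------------------------------
# log-posterior


def test_log_posterior_matches_factor_oracle():
    priors = PriorSpec()
    rng = np.random.default_rng(5)
    for nrow, ncol in ((1, 2), (1, 3)):
        land, z, graph, ind, data, vec = toy_study(nrow, ncol)
        for _ in range(40):
            traj = random_latents(land.ncell, 2, rng)
            got = log_posterior(vec, traj, data, z, graph, priors, ind)
            want = scipy_joint_density(vec, traj, data, z, graph, ind, priors)
            if np.isinf(want):
                assert np.isinf(got)
            else:
                assert abs(got - want) < 1e-8


def test_log_posterior_outside_prior_support():
    land, z, graph, ind, data, vec = toy_study()
    priors = PriorSpec()
    traj = random_latents(2, 2, np.random.default_rng(0))
    bad = vec.copy()
    bad[0] = 9.0   # alpha1 outside U[-8, 8]
    assert log_posterior(bad, traj, data, z, graph, priors, ind) == -np.inf


def test_log_posterior_rejects_nan():
    land, z, graph, ind, data, vec = toy_study()
    traj = random_latents(2, 2, np.random.default_rng(0))
    bad = vec.copy()
    bad[3] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        log_posterior(bad, traj, data, z, graph, PriorSpec(), ind)


def test_masked_observations_do_not_affect_density():
    land, z, graph, ind, data, vec = toy_study()
    priors = PriorSpec()
    traj = random_latents(2, 2, np.random.default_rng(1))
    base = log_posterior(vec, traj, data, z, graph, priors, ind)
    # perturb entries behind the mask: the density must not move
    data.Y[1, 0, 0] = np.nan
    data.Znest[1, 20, 0] = np.nan
    pert = SurveyData(Y=data.Y.copy(), Znest=data.Znest.copy(),
                      Zou=data.Zou.copy(), FE=data.FE.copy())
    assert log_posterior(vec, traj, pert, z, graph, priors, ind) == base


def test_impossible_latents_are_zero_probability():
    land, z, graph, ind, data, vec = toy_study()
    priors = PriorSpec()
    traj = random_latents(2, 2, np.random.default_rng(2))
    traj.S[0, 0] = traj.Nou[0, 0] + 1   # survivors exceed abundance
    assert log_posterior(vec, traj, data, z, graph, priors, ind) == -np.inf


# ---------------------------------------------------------------------------
# rhat


def test_rhat_identical_chains():
    x = np.arange(20.0)
    assert rhat(np.stack([x, x, x])) <= 1.0 + 1e-6


def test_rhat_separated_chains():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 1000)
    b = rng.normal(10, 1, 1000)
    assert rhat(np.stack([a, b])) > 1.1


def test_rhat_hand_computation():
    chains = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 7.0]])
    n = 4
    W = (chains[0].var(ddof=1) + chains[1].var(ddof=1)) / 2
    B_over_n = np.var([chains[0].mean(), chains[1].mean()], ddof=1)
    want = np.sqrt(((n - 1) / n * W + B_over_n) / W)
    assert np.isclose(rhat(chains), want)


def test_rhat_single_chain_errors():
    with pytest.raises(ValueError):
        rhat(np.arange(10.0)[None, :])


# ---------------------------------------------------------------------------
# summaries


def _chainset_from_draws(draws):
    return ChainSet(draws=draws, param_names=PARAM_NAMES,
                    Nou_draws=np.zeros((draws.shape[0], 1, 1, 1), dtype=int),
                    latent_rows=np.array([0]), O_mean=np.zeros((1, 1)),
                    accept_rates={}, config=MCMCConfig(n_iter=10, n_burn=1),
                    priors=PriorSpec(), seeds=(0,))


def test_summary_constant_draws():
    draws = np.full((2, 50, NPARAM), 1.7)
    s = summarize_posterior(_chainset_from_draws(draws))
    row = s.table.loc["alpha1"]
    assert np.isclose(row["mean"], 1.7)
    assert np.isclose(row["q2.5"], 1.7) and np.isclose(row["q97.5"], 1.7)


def test_summary_quantile_rule():
    draws = np.zeros((1, 100, NPARAM))
    draws[0, :, 0] = np.arange(1.0, 101.0)
    s = summarize_posterior(_chainset_from_draws(draws))
    row = s.table.loc["alpha1"]
    assert np.isclose(row["mean"], 50.5)
    assert np.isclose(row["q2.5"], 3.475)     # type-7 interpolation
    assert np.isclose(row["q97.5"], 97.525)


def test_summary_self_correlation():
    rng = np.random.default_rng(0)
    draws = np.zeros((1, 200, NPARAM))
    col = rng.normal(size=200)
    names = list(PARAM_NAMES)
    draws[0, :, names.index("alpha2")] = col
    draws[0, :, names.index("alpha3")] = col   # identical -> r = 1
    s = summarize_posterior(_chainset_from_draws(draws))
    assert np.isclose(s.linquad_correlations[("alpha2", "alpha3")], 1.0)


def test_pack_unpack_roundtrip():
    land, z, graph, ind, data, vec = toy_study()
    proc, obs = unpack_params(vec)
    assert np.allclose(pack_params(proc, obs), vec)


# ---------------------------------------------------------------------------
# sampler behaviour (short runs)


ENGINES = ("numba", "python")


@pytest.mark.parametrize("engine", ENGINES)
def test_mcmc_deterministic_per_seed(engine):
    land, z, graph, ind, data, vec = toy_study()
    cfg = MCMCConfig(n_chains=2, n_iter=200, n_burn=100, seed=9,
                     latent_thin=10, engine=engine)
    a = run_mcmc(data, z, graph, PriorSpec(), cfg, ind)
    b = run_mcmc(data, z, graph, PriorSpec(), cfg, ind)
    assert np.array_equal(a.draws, b.draws)
    assert np.array_equal(a.Nou_draws, b.Nou_draws)


@pytest.mark.parametrize("engine", ENGINES)
def test_mcmc_respects_prior_bounds(engine):
    land, z, graph, ind, data, vec = toy_study()
    priors = PriorSpec()
    cfg = MCMCConfig(n_chains=1, n_iter=300, n_burn=100, seed=3,
                     latent_thin=20, engine=engine)
    ch = run_mcmc(data, z, graph, priors, cfg, ind)
    assert np.all(ch.pooled() >= priors.lower)
    assert np.all(ch.pooled() <= priors.upper)
    assert ch.config.n_chains == 1
    assert MCMCConfig().n_chains == 3   # reference protocol default


def test_conjugate_recruitment_posterior():
    """With latents fixed and only chi free, exp(chi) has a closed-form
    Gamma posterior; the sampler mean must match within MC error."""
    from apedyn.synthetic import SyntheticScenario, generate_dataset
    ds = generate_dataset(SyntheticScenario(nrow=8, ncol=8, enforce_correlation_screen=False), 2)
    ind = forest_indicator_array(ds.landscape)
    vec = pack_params(ds.true_process, ds.true_observation)
    traj = ds.trajectory
    cfg = MCMCConfig(n_chains=2, n_iter=8000, n_burn=1000, seed=3,
                     latent_thin=50, sample_params=("chi",), init_params=vec,
                     init_latents=traj, update_latents=False)
    ch = run_mcmc(ds.survey, ds.z, ds.graph, PriorSpec(), cfg, ind)
    lam = np.exp(ch.pooled()[:, list(PARAM_NAMES).index("chi")])
    sumR = traj.R.sum()
    sumN = sum(neighborhood_mean(traj.Nou[:, t].astype(float), ds.graph).sum()
               for t in range(traj.nperiod - 1))
    want = sumR / sumN                     # Gamma(sum R, sum NEIGH) mean
    se = lam.std() / np.sqrt(len(lam) / 20.0)   # conservative ESS
    assert abs(lam.mean() - want) < 3 * se


def test_zero_likelihood_start_errors():
    land, z, graph, ind, data, vec = toy_study()
    impossible = LatentTrajectory(O=np.zeros((2, 2), dtype=int),
                                  Nou=np.zeros((2, 2), dtype=int),
                                  S=np.zeros((2, 1), dtype=int),
                                  R=np.zeros((2, 1), dtype=int))
    # data contain positive observations, so all-zero latents are impossible
    cfg = MCMCConfig(n_chains=1, n_iter=50, n_burn=10, seed=0,
                     init_params=vec, init_latents=impossible)
    with pytest.raises(RuntimeError, match="finite posterior"):
        run_mcmc(data, z, graph, PriorSpec(), cfg, ind)


@pytest.mark.parametrize("engine", ENGINES)
def test_latent_marginal_matches_enumeration(engine):
    """Long-run latent marginal on a single-cell toy equals the exhaustively
    enumerated conditional (detailed-balance smoke test)."""
    land, z, graph, ind, data, vec = toy_study(nrow=1, ncol=1)
    priors = PriorSpec()
    model = Model(data, z, graph, ind)
    B = 8
    weights = {}
    logs, keys = [], []
    for O0, O1 in itertools.product([0, 1], repeat=2):
        for N0 in range(B + 1):
            if O0 == 0 and N0 > 0:
                continue
            for N1 in range(B + 1):
                if O1 == 0 and N1 > 0:
                    continue
                for S0 in range(N0 + 1):
                    for R0 in range(B + 1):
                        traj = LatentTrajectory(
                            O=np.array([[O0, O1]]), Nou=np.array([[N0, N1]]),
                            S=np.array([[S0]]), R=np.array([[R0]]))
                        lp = model.log_likelihood(vec, traj)
                        if np.isfinite(lp):
                            logs.append(lp)
                            keys.append(N1)
    logs = np.array(logs)
    w = np.exp(logs - logs.max())
    w /= w.sum()
    for k, wt in zip(keys, w):
        weights[k] = weights.get(k, 0.0) + wt

    n_iter = 40000 if engine == "numba" else 25000
    cfg = MCMCConfig(n_chains=1, n_iter=n_iter, n_burn=2000, seed=11,
                     latent_thin=1, sample_params=(), init_params=vec,
                     engine=engine)
    ch = run_mcmc(data, z, graph, priors, cfg, ind)
    vals, counts = np.unique(ch.Nou_draws[0][:, 0, 1], return_counts=True)
    freq = {int(v): c / counts.sum() for v, c in zip(vals, counts)}
    tv = 0.5 * sum(abs(weights.get(k, 0) - freq.get(k, 0))
                   for k in set(weights) | set(freq))
    assert tv < 0.06
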