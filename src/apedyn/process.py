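"""Latent population dynamics (level 1 of the dynamic abundance model).

Abundance in each 1-km cell follows an open N-mixture process gated by
occupancy:

* ``O[i,t] ~ Bernoulli(phi[i,t])`` — latent occupancy per period,
* ``Nou[i,1] ~ Poisson(lambda_i * O[i,1])`` — initial abundance,
* ``S[i,t] ~ Binomial(Nou[i,t], theta[i,t+1])`` — survivors that do not
  emigrate over a transition,
* ``R[i,t] ~ Poisson(delta[i,t+1])`` — recruits (births + immigrants), with
  ``delta = exp(chi) * NEIGH`` driven by the barrier-weighted neighbourhood
  mean abundance of the previous period,
* ``Ntilde[i,t+1] = S[i,t] + R[i,t]`` and
  ``Nou[i,t+1] ~ Poisson(Ntilde[i,t+1] * O[i,t+1])``.

The vital rates are log/logit-linear in standardized covariates with
quadratic altitude and seasonal-rainfall terms and a forest x conversion
interaction; quadratics are squares of the z-scored covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .landscape import NeighborGraph, StandardizedCovariates

#: design-matrix column order shared by the three covariate link models
DESIGN_TERMS = ("intercept", "ALT", "ALT2", "DRY", "DRY2", "WET", "WET2",
                "DPA", "MS", "FR", "FRxCFA")
NCOEF = len(DESIGN_TERMS)


@dataclass
class ProcessParams:
    """Coefficients of the level-1 link models.

    ``alpha`` (log link, initial abundance), ``beta`` (logit link,
    occupancy) and ``eta`` (logit link, survival) each have 11 entries in
    :data:`DESIGN_TERMS` order; ``chi`` is the log-scale recruitment
    intercept.
    """

    alpha: np.ndarray
    beta: np.ndarray
    eta: np.ndarray
    chi: float

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        for name in ("alpha", "beta", "eta"):
            v = getattr(self, name)
            if v.shape != (NCOEF,):
                raise ValueError(f"{name} must have {NCOEF} coefficients")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
        if not np.isfinite(self.chi):
            raise ValueError("chi must be finite")


def design_matrix(z: StandardizedCovariates, period: int) -> np.ndarray:
    """(C, 11) design matrix for one period in :data:`DESIGN_TERMS` order."""
    C = z.ncell
    X = np.empty((C, NCOEF))
    X[:, 0] = 1.0
    X[:, 1] = z.ALT
    X[:, 2] = z.ALT ** 2
    X[:, 3] = z.DRY
    X[:, 4] = z.DRY ** 2
    X[:, 5] = z.WET
    X[:, 6] = z.WET ** 2
    X[:, 7] = z.DPA[:, period]
    X[:, 8] = z.MS
    X[:, 9] = z.FR[:, period]
    X[:, 10] = z.FR[:, period] * z.CFA[:, period]
    return X


def initial_abundance_rate(params: ProcessParams, z: StandardizedCovariates,
                           cell=None) -> np.ndarray | float:
    """lambda_i = exp(alpha . x_i) using period-1 covariates (individuals/km2)."""
    lam = np.exp(design_matrix(z, 0) @ params.alpha)
    return lam if cell is None else float(lam[cell])


def occupancy_rate(params: ProcessParams, z: StandardizedCovariates,
                   period: int, cell=None) -> np.ndarray | float:
    """phi_{i,t} = invlogit(beta . x_{i,t})."""
    phi = expit(design_matrix(z, period) @ params.beta)
    return phi if cell is None else float(phi[cell])


def survival_rate(params: ProcessParams, z: StandardizedCovariates,
                  period: int, cell=None) -> np.ndarray | float:
    """theta_{i,t} = invlogit(eta . x_{i,t})."""
    th = expit(design_matrix(z, period) @ params.eta)
    return th if cell is None else float(th[cell])


def neighborhood_mean(N: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """Barrier-weighted neighbourhood mean abundance.

    ``NEIGH_i = (sum_{k in n_i} w_k N_k + N_i) / (|n_i| + 1)`` where the sum
    runs over the Moore neighbours and ``w_k`` zeroes links severed by
    rivers. The divisor uses the geometric neighbour count regardless of
    barriers, so fully isolated cells still average over their would-be
    neighbourhood.
    """
    N = np.asarray(N, dtype=float)
    padded = np.concatenate([N, [0.0]])  # -1 padding gathers a zero
    gathered = padded[graph.nbr] * graph.w
    return (gathered.sum(axis=1) + N) / (graph.deg + 1.0)


def recruitment_rate(params: ProcessParams, neigh: np.ndarray) -> np.ndarray:
    """delta = exp(chi) * NEIGH.

    Algebraically identical to ``log(delta) = chi + log(NEIGH)`` for
    NEIGH > 0 and extends continuously to delta = 0 at NEIGH = 0 (an empty
    neighbourhood recruits nothing).
    """
    return np.exp(params.chi) * np.asarray(neigh, dtype=float)


@dataclass
class LatentTrajectory:
    """Latent states per cell x period.

    ``O`` occupancy (C, T); ``Nou`` individuals (C, T); ``S`` survivors and
    ``R`` recruits over each transition (C, T-1); ``Ntilde`` the pre-thinning
    expectation S + R (C, T-1), applying to periods 2..T.
    """

    O: np.ndarray
    Nou: np.ndarray
    S: np.ndarray
    R: np.ndarray

    @property
    def Ntilde(self) -> np.ndarray:
        return self.S + self.R

    @property
    def ncell(self) -> int:
        return self.O.shape[0]

    @property
    def nperiod(self) -> int:
        return self.O.shape[1]

    def validate(self) -> None:
        if np.any(self.Nou < 0) or np.any(self.S < 0) or np.any(self.R < 0):
            raise ValueError("latent counts must be non-negative")
        if np.any((self.O != 0) & (self.O != 1)):
            raise ValueError("O must be binary")
        if np.any(self.Nou[self.O == 0] != 0):
            raise ValueError("Nou must be 0 in unoccupied cell-periods")
        if np.any(self.S > self.Nou[:, :-1]):
            raise ValueError("survivors cannot exceed previous abundance")


def simulate_dynamics(params: ProcessParams, z: StandardizedCovariates,
                      graph: NeighborGraph, periods: int,
                      rng: np.random.Generator) -> LatentTrajectory:
    """Draw a full latent trajectory from the level-1 model.

    Occupancy is drawn independently per period (no persistence term), so a
    cell can in principle be re-occupied after local extinction; recruitment
    from the neighbourhood then restarts the population.
    """
    if periods < 1:
        raise ValueError("periods must be >= 1")
    C = z.ncell
    O = np.empty((C, periods), dtype=np.int64)
    Nou = np.zeros((C, periods), dtype=np.int64)
    S = np.zeros((C, max(periods - 1, 0)), dtype=np.int64)
    R = np.zeros_like(S)

    lam = initial_abundance_rate(params, z)
    _check_rates(lam, "lambda", 0)
    for t in range(periods):
        phi = occupancy_rate(params, z, t)
        _check_rates(phi, "phi", t)
        O[:, t] = rng.random(C) < phi
    Nou[:, 0] = rng.poisson(lam * O[:, 0])

    for t in range(periods - 1):
        theta = survival_rate(params, z, t + 1)
        _check_rates(theta, "theta", t + 1)
        neigh = neighborhood_mean(Nou[:, t], graph)
        delta = recruitment_rate(params, neigh)
        _check_rates(delta, "delta", t + 1)
        S[:, t] = rng.binomial(Nou[:, t], theta)
        R[:, t] = rng.poisson(delta)
        Nou[:, t + 1] = rng.poisson((S[:, t] + R[:, t]) * O[:, t + 1])

    traj = LatentTrajectory(O=O, Nou=Nou, S=S, R=R)
    traj.validate()
    return traj


def _check_rates(x, name: str, period: int) -> None:
    x = np.atleast_1d(x)
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise FloatingPointError(
            f"non-finite {name} at cell {bad + 1}, period {period + 1}")


def trajectory_to_frame(traj: LatentTrajectory):
    """Long-format export (cell_id, period, O, Nou, S, R)."""
    import pandas as pd
    C, T = traj.ncell, traj.nperiod
    frames = []
    for t in range(T):
        frames.append(pd.DataFrame({
            "cell_id": np.arange(1, C + 1),
            "period": t + 1,
            "O": traj.O[:, t],
            "Nou": traj.Nou[:, t],
            "S": traj.S[:, t - 1] if t > 0 else np.full(C, -1),
            "R": traj.R[:, t - 1] if t > 0 else np.full(C, -1),
        }))
    return pd.concat(frames, ignore_index=True)
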