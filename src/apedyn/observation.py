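"""Observation layers (levels 2-4): interviews, nest scaling and detection.

Standing nests are the observable footprint of the animals: the latent nest
count is ``Nnest = psi * Nou`` where the scaling factor
``psi = 100 * (gamma0 + gamma.indicators)`` plays the role of
``b * q * d`` — proportion of nest builders x daily nest production x nest
decay days — and varies with forest type. Nest counts are thinned
binomially with protocol-specific detection (aerial vs ground transects),
nest occurrence in 200-m sub-cells is a Bernoulli detection of nest
occupancy, and interview reports are Bernoulli detections of animal
occupancy whose rate depends on how often the respondent enters the forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

PROTOCOLS = ("aerial", "ground")

#: coefficients of the log-linear aerial-index regression (natural logs),
#: converting nests seen per km of helicopter flight to nests per km2
AERIAL_INDEX_INTERCEPT = 4.7297
AERIAL_INDEX_SLOPE = 0.9796

#: default proportion of nest builders and daily nest production rate
DEFAULT_NEST_BUILDER_PROP = 0.9
DEFAULT_NEST_PRODUCTION = 1.1


@dataclass
class ObservationParams:
    """Parameters of the observation layers.

    ``upsilon = (u1, u2)`` — interview detection logit intercept and
    forest-entry effect; ``gamma`` — 6 nest-scaling coefficients
    (intercept, MGV, PT, LOWL, MONT, FRGM); ``mu = (mu_aerial, mu_ground)``
    — nest-count detection logits; ``zeta`` — sub-cell nest-occurrence
    detection logit.
    """

    upsilon: np.ndarray
    gamma: np.ndarray
    mu: np.ndarray
    zeta: float

    def __post_init__(self) -> None:
        self.upsilon = np.asarray(self.upsilon, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.upsilon.shape != (2,):
            raise ValueError("upsilon must have 2 entries")
        if self.gamma.shape != (6,):
            raise ValueError("gamma must have 6 entries")
        if self.mu.shape != (2,):
            raise ValueError("mu must have 2 entries (aerial, ground)")
        if not (np.all(np.isfinite(self.upsilon)) and np.all(np.isfinite(self.gamma))
                and np.all(np.isfinite(self.mu)) and np.isfinite(self.zeta)):
            raise ValueError("observation parameters must be finite")


def nest_scaling_factor(params: ObservationParams,
                        indicators: pd.DataFrame) -> np.ndarray:
    """psi = 100 * (gamma0 + gamma1 MGV + gamma2 PT + gamma3 LOWL + gamma4 MONT + gamma5 FRGM).

    Interpreted in days-equivalents (b*q is around 1, so psi is dominated by
    the nest decay time). Raises if any cell gets psi <= 0, which is outside
    the meaningful parameter region.
    """
    ind = indicators[["MGV", "PT", "LOWL", "MONT", "FRGM"]].to_numpy(dtype=float)
    psi = 100.0 * (params.gamma[0] + ind @ params.gamma[1:])
    if np.any(psi <= 0):
        raise ValueError("nest scaling factor psi must be positive for all cells")
    return psi


def interview_detection_prob(params: ObservationParams, FE) -> np.ndarray | float:
    """invlogit(u1 + u2 * FE); FE = 1 for respondents entering the forest
    more than once a month, 0 otherwise."""
    FE = np.asarray(FE, dtype=float)
    out = expit(params.upsilon[0] + params.upsilon[1] * FE)
    return float(out) if out.ndim == 0 else out


def nest_count_detection_prob(params: ObservationParams, protocol: str) -> float:
    """Protocol-constant nest detection probability invlogit(mu_j)."""
    try:
        j = PROTOCOLS.index(protocol)
    except ValueError:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    return float(expit(params.mu[j]))


def nest_occurrence_detection_prob(params: ObservationParams) -> float:
    """Sub-cell nest-occurrence detection probability invlogit(zeta)."""
    return float(expit(params.zeta))


def aerial_index_to_nest_density(AI) -> np.ndarray | float:
    """Convert an aerial index (nests/km flight) to nests/km2.

    ``gnest = exp(4.7297 + 0.9796 * ln(AI))`` with natural logarithms.
    AI = 0 means no nests were seen and maps to 0 with a warning; negative
    AI is an error.
    """
    AI = np.asarray(AI, dtype=float)
    scalar = AI.ndim == 0
    AI = np.atleast_1d(AI)
    if np.any(AI < 0):
        raise ValueError("aerial index must be non-negative")
    out = np.zeros_like(AI)
    pos = AI > 0
    out[pos] = np.exp(AERIAL_INDEX_INTERCEPT + AERIAL_INDEX_SLOPE * np.log(AI[pos]))
    if np.any(~pos):
        warnings.warn("AI = 0: no nests seen; nest density set to 0")
    return float(out[0]) if scalar else out


def orangutan_density_from_nests(gnest, b: float = DEFAULT_NEST_BUILDER_PROP,
                                 q: float = DEFAULT_NEST_PRODUCTION,
                                 d: float = 228.0) -> np.ndarray | float:
    """gou = gnest / (b * q * d): individuals/km2 from standing nests/km2."""
    if b <= 0 or q <= 0 or d <= 0:
        raise ValueError("b, q and d must all be positive")
    out = np.asarray(gnest, dtype=float) / (b * q * d)
    return float(out) if out.ndim == 0 else out


@dataclass
class NestState:
    """Latent nest layer derived deterministically from the animal layer.

    ``Nnest = round(psi * Nou)`` (rounded so the level-4 binomial is
    well-defined) and ``Onest = 1{Nnest > 0}``.
    """

    Nnest: np.ndarray   # (C, T) int
    Onest: np.ndarray   # (C, T) int
    psi: np.ndarray     # (C, T)


def nest_state(traj_Nou: np.ndarray, psi: np.ndarray) -> NestState:
    """Build the nest layer from abundance and the scaling factor."""
    Nnest = np.rint(psi * traj_Nou).astype(np.int64)
    return NestState(Nnest=Nnest, Onest=(Nnest > 0).astype(np.int64), psi=psi)


# ---------------------------------------------------------------------------
# Survey design and data containers


@dataclass
class SurveyDesign:
    """Which cells/protocols/respondents are sampled per period.

    ``count_cells[j]`` maps protocol -> boolean (C, T) mask of surveyed
    cell-periods; ``occurrence_cells`` is a (C, T) mask of cells whose 25
    sub-cells are checked for nest occurrence; interviews cover every
    village cell for all periods, with ``n_respondents`` per village.
    """

    count_cells: dict
    occurrence_cells: np.ndarray
    interview_cells: np.ndarray   # (C,) bool
    n_respondents: int = 10
    n_subcells: int = 25


@dataclass
class SurveyData:
    """The four observation streams with explicit NaN masks.

    ``Y`` (C, 2, T) float — nest counts per cell x protocol x period;
    ``Znest`` (C, K, T) float — binary nest occurrence per sub-cell;
    ``Zou`` (C, M, T) float — binary interview reports per respondent;
    ``FE`` (C, M) float — respondent forest-entry frequency (1 = more than
    once a month). Unsampled entries are NaN and are never imputed.
    """

    Y: np.ndarray
    Znest: np.ndarray
    Zou: np.ndarray
    FE: np.ndarray
    AI: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("Y", "Znest", "Zou"):
            arr = getattr(self, name)
            obs = arr[~np.isnan(arr)]
            if name == "Y":
                if np.any(obs < 0) or np.any(obs != np.rint(obs)):
                    raise ValueError("Y must contain non-negative integers")
            elif np.any(~np.isin(obs, (0.0, 1.0))):
                raise ValueError(f"{name} must be binary where observed")

    @property
    def ncell(self) -> int:
        return self.Y.shape[0]

    @property
    def nperiod(self) -> int:
        return self.Y.shape[2]


def sample_observations(nest: NestState, O: np.ndarray,
                        params: ObservationParams, design: SurveyDesign,
                        rng: np.random.Generator,
                        FE: np.ndarray | None = None) -> SurveyData:
    """Draw all four survey streams given the latent states.

    Each respondent's detection rate uses that respondent's own
    forest-entry value; FE is drawn Bernoulli(0.5) when not supplied.
    Entries outside the design are masked with NaN.
    """
    C, T = nest.Nnest.shape
    M, K = design.n_respondents, design.n_subcells
    for name, mask in design.count_cells.items():
        if name not in PROTOCOLS:
            raise ValueError(f"unknown protocol {name!r} in survey design")
        if mask.shape != (C, T):
            raise ValueError("count_cells masks must have shape (C, T)")
    if design.occurrence_cells.shape != (C, T):
        raise ValueError("occurrence_cells mask must have shape (C, T)")
    if design.interview_cells.shape != (C,):
        raise ValueError("interview_cells mask must have shape (C,)")

    Y = np.full((C, 2, T), np.nan)
    for j, name in enumerate(PROTOCOLS):
        mask = design.count_cells.get(name)
        if mask is None or not mask.any():
            continue
        xi = nest_count_detection_prob(params, name)
        draws = rng.binomial(nest.Nnest, xi)
        Y[:, j, :][mask] = draws[mask]

    Znest = np.full((C, K, T), np.nan)
    rho_nest = nest_occurrence_detection_prob(params)
    p_sub = rho_nest * nest.Onest  # (C, T)
    sub = rng.random((C, K, T)) < p_sub[:, None, :]
    occ3 = np.broadcast_to(design.occurrence_cells[:, None, :], (C, K, T))
    Znest[occ3] = sub[occ3].astype(float)

    if FE is None:
        FE_full = np.full((C, M), np.nan)
        nvil = int(design.interview_cells.sum())
        FE_full[design.interview_cells] = (rng.random((nvil, M)) < 0.5)
    else:
        FE_full = np.asarray(FE, dtype=float)
        if FE_full.shape != (C, M):
            raise ValueError("FE must have shape (C, n_respondents)")
    Zou = np.full((C, M, T), np.nan)
    vil = design.interview_cells
    if vil.any():
        rho_ou = interview_detection_prob(params, np.nan_to_num(FE_full[vil]))
        p_ou = rho_ou[:, :, None] * O[vil][:, None, :]  # (V, M, T)
        Zou[vil] = (rng.random(p_ou.shape) < p_ou).astype(float)

    return SurveyData(Y=Y, Znest=Znest, Zou=Zou, FE=FE_full)


def survey_to_frames(data: SurveyData) -> dict[str, pd.DataFrame]:
    """Tidy CSV-ready tables (counts, sub-cell occurrence, interviews) with
    an explicit ``observed`` mask column."""
    C, _, T = data.Y.shape
    K, M = data.Znest.shape[1], data.Zou.shape[1]
    cells = np.arange(1, C + 1)

    rec = []
    for j, name in enumerate(PROTOCOLS):
        for t in range(T):
            col = data.Y[:, j, t]
            rec.append(pd.DataFrame({
                "cell_id": cells, "protocol": name, "period": t + 1,
                "Y": col, "observed": (~np.isnan(col)).astype(int)}))
    counts = pd.concat(rec, ignore_index=True)

    rec = []
    for k in range(K):
        for t in range(T):
            col = data.Znest[:, k, t]
            rec.append(pd.DataFrame({
                "cell_id": cells, "subcell": k + 1, "period": t + 1,
                "Znest": col, "observed": (~np.isnan(col)).astype(int)}))
    occurrence = pd.concat(rec, ignore_index=True)

    rec = []
    for m in range(M):
        for t in range(T):
            col = data.Zou[:, m, t]
            rec.append(pd.DataFrame({
                "cell_id": cells, "respondent": m + 1, "period": t + 1,
                "Zou": col, "FE": data.FE[:, m],
                "observed": (~np.isnan(col)).astype(int)}))
    interviews = pd.concat(rec, ignore_index=True)
    return {"counts": counts, "occurrence": occurrence, "interviews": interviews}


def survey_from_frames(frames: dict[str, pd.DataFrame]) -> SurveyData:
    """Inverse of :func:`survey_to_frames`."""
    counts, occurrence, interviews = (
        frames["counts"], frames["occurrence"], frames["interviews"])
    for name, df, cols in (
            ("counts", counts, {"cell_id", "protocol", "period", "Y", "observed"}),
            ("occurrence", occurrence, {"cell_id", "subcell", "period", "Znest", "observed"}),
            ("interviews", interviews, {"cell_id", "respondent", "period", "Zou", "FE", "observed"})):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} table is missing columns: {sorted(missing)}")
    C = int(counts["cell_id"].max())
    T = int(counts["period"].max())
    K = int(occurrence["subcell"].max())
    M = int(interviews["respondent"].max())
    Y = np.full((C, 2, T), np.nan)
    for j, name in enumerate(PROTOCOLS):
        sub = counts[counts["protocol"] == name]
        Y[sub["cell_id"] - 1, j, sub["period"] - 1] = np.where(
            sub["observed"] == 1, sub["Y"], np.nan)
    Znest = np.full((C, K, T), np.nan)
    Znest[occurrence["cell_id"] - 1, occurrence["subcell"] - 1,
          occurrence["period"] - 1] = np.where(
        occurrence["observed"] == 1, occurrence["Znest"], np.nan)
    Zou = np.full((C, M, T), np.nan)
    Zou[interviews["cell_id"] - 1, interviews["respondent"] - 1,
        interviews["period"] - 1] = np.where(
        interviews["observed"] == 1, interviews["Zou"], np.nan)
    FE = np.full((C, M), np.nan)
    FE[interviews["cell_id"] - 1, interviews["respondent"] - 1] = interviews["FE"]
    return SurveyData(Y=Y, Znest=Znest, Zou=Zou, FE=FE)
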