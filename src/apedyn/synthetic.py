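"""Synthetic study generator.

Emulates the structure of the island-wide orangutan survey: a rectangular
1-km grid with smooth environmental fields (altitude, dry/wet-season
rainfall), block-level district composition, protected-area blobs, a
conversion front of industrial agriculture advancing over three 6-year
periods (driving forest loss and the CFA covariate), meandering river
barriers, interview villages with ten respondents each, and partial
ground/aerial transect coverage with 25 nest-occurrence sub-cells per cell.

Only the statistical structure matters for testing the pipeline: fields are
smoothed noise rather than real topography, and covariates are re-drawn
until all pairwise Pearson correlations are below 0.45 in magnitude, the
pre-fit screen applied to the real data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage
from shapely.geometry import LineString

from .landscape import (GridLandscape, NeighborGraph, build_neighbor_graph,
                        standardize_covariates, StandardizedCovariates)
from .observation import (ObservationParams, SurveyData, SurveyDesign,
                          nest_state, NestState, sample_observations)
from .process import LatentTrajectory, ProcessParams, simulate_dynamics
from . import reference

#: pre-fit covariate correlation screen threshold
CORRELATION_LIMIT = 0.45


def default_true_process() -> ProcessParams:
    """Borneo-like level-1 truth for the default scenario.

    Signs follow the reference estimates (unimodal abundance and occupancy
    in seasonal rainfall, U-shaped survival, positive forest and
    forest x conversion-distance effects); rainfall curvature is moderated
    relative to the island-wide fit because a small synthetic landscape
    spans a narrower covariate range, and the survival intercept is set so
    that survival plus neighbourhood recruitment, thinned by the
    independent per-period occupancy draw, yields a decline of roughly a
    third per decade.
    """
    return ProcessParams(
        alpha=np.array([1.0, 0.02, -0.03, 0.9, -0.9, 0.9, -1.0,
                        -0.07, 0.001, 0.88, 0.07]),
        beta=np.array([1.4, 0.18, -0.12, 0.9, -0.85, 0.76, -0.9,
                       -0.04, 0.005, 0.87, 0.05]),
        eta=np.array([2.0, -0.02, 0.03, -0.4, 0.36, -0.26, 0.27,
                      -0.14, 0.01, 0.13, 0.21]),
        chi=-2.265,
    )


def default_true_observation() -> ObservationParams:
    """Observation-layer truth: the reference posterior means."""
    return reference.borneo_observation_params()


@dataclass
class SyntheticScenario:
    """Configuration of a synthetic study (defaults mirror the reference
    design: three 6-year periods, 25 sub-cells, 10 respondents/village)."""

    nrow: int = 40
    ncol: int = 40
    n_periods: int = 3
    length_scale: float = 4.0          # smoothing of environmental fields (cells)
    alt_range: tuple = (0.0, 1300.0)   # m
    dry_range: tuple = (80.0, 320.0)   # mm/month
    wet_range: tuple = (150.0, 450.0)  # mm/month
    district_size: int = 5             # cells per district block side (for MS)
    n_protected: int = 3
    protected_radius: int = 3          # cells
    front_fraction: tuple = (0.05, 0.15, 0.30)  # converted share of columns per period
    forest_base: tuple = (0.2, 0.97)   # range of the smooth baseline forest field
    n_rivers: int = 1
    village_fraction: float = 0.08
    n_respondents: int = 10
    n_subcells: int = 25
    ground_fraction: float = 0.15
    aerial_fraction: float = 0.10
    targeted_fraction: float = 0.05
    max_correlation_retries: int = 20
    enforce_correlation_screen: bool = True
    true_process: ProcessParams = field(default_factory=default_true_process)
    true_observation: ObservationParams = field(default_factory=default_true_observation)

    def config_dict(self) -> dict:
        d = asdict(self)
        d["true_process"] = {k: np.asarray(v).tolist()
                             for k, v in asdict(self.true_process).items()}
        d["true_observation"] = {k: np.asarray(v).tolist()
                                 for k, v in asdict(self.true_observation).items()}
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.config_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _smooth_field(rng: np.random.Generator, nrow: int, ncol: int,
                  sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=(nrow, ncol)), sigma,
                                mode="reflect")
    f = (f - f.mean()) / (f.std() + 1e-12)
    return f.ravel()


def _orthogonalize(f: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
    """Remove the sample projection of ``f`` onto earlier (centered) fields,
    keeping the field smooth while zeroing its correlation with them."""
    f = f - f.mean()
    for g in others:
        g = g - g.mean()
        denom = g @ g
        if denom > 0:
            f = f - (f @ g) / denom * g
    return f / (f.std() + 1e-12)


def _orthonormal_basis(fields: list[np.ndarray]) -> list[np.ndarray]:
    """Centered Gram-Schmidt basis spanning the given covariate columns."""
    basis: list[np.ndarray] = []
    for f in fields:
        f = np.asarray(f, dtype=float)
        g = _orthogonalize(f, basis)
        if g.std() > 1e-8:
            basis.append(g)
    return basis


def _to_range(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    g = (f - f.min()) / (f.max() - f.min() + 1e-12)
    return lo + g * (hi - lo)


def generate_landscape(scenario: SyntheticScenario,
                       seed: int) -> tuple[GridLandscape, list[LineString]]:
    """Draw one landscape; re-drawn until the covariate correlation screen
    (all pairwise |Pearson r| < 0.45 among period-1 covariates) passes."""
    root = np.random.SeedSequence(seed)
    last_corr = None
    for attempt, ss in enumerate(root.spawn(scenario.max_correlation_retries)):
        rng = np.random.default_rng(ss)
        land, rivers = _draw_landscape(scenario, rng)
        if not scenario.enforce_correlation_screen:
            return land, rivers
        corr = _covariate_corr(land)
        if np.all(np.abs(corr[np.triu_indices_from(corr, 1)]) < CORRELATION_LIMIT):
            return land, rivers
        last_corr = corr
    raise RuntimeError(
        "could not satisfy the covariate correlation screen "
        f"(|r| < {CORRELATION_LIMIT}) in {scenario.max_correlation_retries} "
        f"attempts; last correlation matrix:\n{np.round(last_corr, 3)}")


def _covariate_corr(land: GridLandscape) -> np.ndarray:
    cols = np.column_stack([land.ALT, land.DRY, land.WET, land.DPA[:, 0],
                            land.MS, land.FR[:, 0], land.CFA[:, 0]])
    return np.corrcoef(cols, rowvar=False)


def _draw_landscape(scenario: SyntheticScenario,
                    rng: np.random.Generator) -> tuple[GridLandscape, list[LineString]]:
    nrow, ncol, T = scenario.nrow, scenario.ncol, scenario.n_periods
    C = nrow * ncol
    # cap the correlation length relative to the grid so small landscapes
    # keep enough effective spatial degrees of freedom for the screen
    ls = min(scenario.length_scale, nrow / 5.0, ncol / 5.0)
    rows = np.arange(C) // ncol
    cols = np.arange(C) % ncol

    # proportion Muslim: constant within square district blocks
    ds = scenario.district_size
    ndr, ndc = -(-nrow // ds), -(-ncol // ds)
    district_vals = rng.beta(2.0, 2.0, size=(ndr, ndc))
    MS = district_vals[rows // ds, cols // ds]

    # protected areas: square blobs; DPA = distance (km) to nearest PA cell
    pa_mask = np.zeros((nrow, ncol), dtype=bool)
    for _ in range(scenario.n_protected):
        r0 = rng.integers(0, nrow)
        c0 = rng.integers(0, ncol)
        rad = max(1, min(scenario.protected_radius, nrow // 8, ncol // 8))
        pa_mask[max(0, r0 - rad):r0 + rad + 1, max(0, c0 - rad):c0 + rad + 1] = True
    DPA1 = ndimage.distance_transform_edt(~pa_mask).ravel().astype(float)
    DPA = np.tile(DPA1[:, None], (1, T))

    # industrial-agriculture conversion: scattered estates whose cumulative
    # footprint grows each period (an advancing front in aggregate without
    # imposing a grid-wide gradient on CFA)
    CFA = np.empty((C, T))
    conv_masks = []
    converted = np.zeros((nrow, ncol), dtype=bool)
    for t in range(T):
        target = scenario.front_fraction[t] * C
        for _ in range(400):
            if converted.sum() >= target:
                break
            r0 = rng.integers(0, nrow)
            c0 = rng.integers(0, ncol)
            rad = int(rng.integers(1, 3))
            converted[max(0, r0 - rad):r0 + rad + 1,
                      max(0, c0 - rad):c0 + rad + 1] = True
            converted &= ~pa_mask
        conv_masks.append(converted.ravel().copy())
        CFA[:, t] = ndimage.distance_transform_edt(~converted).ravel()

    # baseline forest: smoothed field decorrelated from the structural
    # covariates, eroded gently near (and removed inside) the conversion
    base_forest = _to_range(
        _orthogonalize(_smooth_field(rng, nrow, ncol, ls / 2),
                       [DPA1, MS, CFA[:, 0]]),
        *scenario.forest_base)
    FR = np.empty((C, T))
    for t in range(T):
        erosion = np.exp(-CFA[:, t] / 1.0)
        FR[:, t] = np.clip(base_forest * (1.0 - 0.15 * erosion), 0.0, 1.0)
        conv = conv_masks[t]
        FR[conv, t] = rng.uniform(0.0, 0.05, conv.sum())

    # climate/terrain fields: smoothed noise, decorrelated by Gram-Schmidt
    # against each other and against the structural period-1 covariates
    basis = _orthonormal_basis([DPA1, MS, FR[:, 0], CFA[:, 0]])
    f_alt = _orthogonalize(_smooth_field(rng, nrow, ncol, ls), basis)
    basis.append(f_alt)
    f_dry = _orthogonalize(_smooth_field(rng, nrow, ncol, ls), basis)
    basis.append(f_dry)
    f_wet = _orthogonalize(_smooth_field(rng, nrow, ncol, ls), basis)
    ALT = _to_range(f_alt, *scenario.alt_range)
    DRY = _to_range(f_dry, *scenario.dry_range)
    WET = _to_range(f_wet, *scenario.wet_range)

    # majority forest class: coastal mangrove strip, low-altitude peat blobs,
    # generic forest elsewhere (split lowland/montane by altitude at use time)
    peat_field = _smooth_field(rng, nrow, ncol, ls / 2)
    fclass1 = np.full(C, "other", dtype=object)
    fclass1[(cols <= 1) & (ALT < 200)] = "mangrove"
    fclass1[(peat_field > 1.0) & (ALT < 300) & (fclass1 == "other")] = "peat"
    forest_class = np.empty((C, T), dtype=object)
    for t in range(T):
        forest_class[:, t] = fclass1
        forest_class[FR[:, t] < 0.05, t] = "none"

    # land use per period
    landuse = np.full((C, T), "OTHER", dtype=object)
    logg = np.zeros(C, dtype=bool)
    for _ in range(2):
        r0, c0 = rng.integers(0, nrow), rng.integers(0, ncol)
        sel = (np.abs(rows - r0) <= 5) & (np.abs(cols - c0) <= 5)
        logg |= sel
    itp = np.zeros(C, dtype=bool)
    r0, c0 = rng.integers(0, nrow), rng.integers(0, ncol)
    itp[(np.abs(rows - r0) <= 3) & (np.abs(cols - c0) <= 3)] = True
    for t in range(T):
        landuse[logg, t] = "LOGG"
        landuse[itp, t] = "ITP"
        landuse[CFA[:, t] == 0, t] = "OPP"   # inside converted estates
        landuse[pa_mask.ravel(), t] = "PA"

    # regions: vertical thirds
    region = np.where(cols < ncol / 3, "west",
                      np.where(cols < 2 * ncol / 3, "central", "east")).astype(object)

    village_flag = rng.random(C) < scenario.village_fraction

    rivers = []
    for k in range(scenario.n_rivers):
        x0 = (k + 1) * ncol / (scenario.n_rivers + 1)
        ys = np.linspace(0.0, nrow, 4 * nrow + 1)
        amp = rng.uniform(1.0, 3.0)
        freq = rng.uniform(0.15, 0.35)
        phase = rng.uniform(0, 2 * np.pi)
        xs = x0 + amp * np.sin(freq * ys + phase)
        rivers.append(LineString(np.column_stack([xs, ys])))

    land = GridLandscape(
        nrow=nrow, ncol=ncol, region=region, landuse=landuse,
        ALT=ALT, DRY=DRY, WET=WET, MS=MS, DPA=DPA, FR=FR, CFA=CFA,
        forest_class=forest_class, village_flag=village_flag)
    return land, rivers


def default_survey_design(scenario: SyntheticScenario, land: GridLandscape,
                          rng: np.random.Generator) -> SurveyDesign:
    """Random partial transect coverage plus targeted occurrence cells;
    interviews at every village cell in all periods."""
    C, T = land.ncell, scenario.n_periods
    ground = rng.random((C, T)) < scenario.ground_fraction
    aerial = rng.random((C, T)) < scenario.aerial_fraction
    occurrence = ground | aerial | (rng.random((C, T)) < scenario.targeted_fraction)
    return SurveyDesign(
        count_cells={"aerial": aerial, "ground": ground},
        occurrence_cells=occurrence,
        interview_cells=land.village_flag.copy(),
        n_respondents=scenario.n_respondents,
        n_subcells=scenario.n_subcells)


@dataclass
class SyntheticDataset:
    """A complete synthetic study with the generating truth retained."""

    landscape: GridLandscape
    rivers: list
    z: StandardizedCovariates
    graph: NeighborGraph
    trajectory: LatentTrajectory
    nests: NestState
    design: SurveyDesign
    survey: SurveyData
    true_process: ProcessParams
    true_observation: ObservationParams
    manifest: dict


def generate_dataset(scenario: SyntheticScenario, seed: int) -> SyntheticDataset:
    """Landscape -> latent dynamics -> nests -> all four survey streams."""
    from .inference import forest_indicator_array  # local to avoid cycle

    land, rivers = generate_landscape(scenario, seed)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    rng = np.random.default_rng(ss)
    z = standardize_covariates(land)
    graph = build_neighbor_graph(land, rivers)
    traj = simulate_dynamics(scenario.true_process, z, graph,
                             scenario.n_periods, rng)
    ind = forest_indicator_array(land)
    psi = 100.0 * (scenario.true_observation.gamma[0]
                   + ind @ scenario.true_observation.gamma[1:])
    nests = nest_state(traj.Nou, psi)
    design = default_survey_design(scenario, land, rng)
    survey = sample_observations(nests, traj.O, scenario.true_observation,
                                 design, rng)
    manifest = {
        "seed": int(seed),
        "scenario_hash": scenario.hash(),
        "grid": [scenario.nrow, scenario.ncol],
        "n_periods": scenario.n_periods,
        "generator": "apedyn.synthetic.generate_dataset",
    }
    return SyntheticDataset(
        landscape=land, rivers=rivers, z=z, graph=graph, trajectory=traj,
        nests=nests, design=design, survey=survey,
        true_process=scenario.true_process,
        true_observation=scenario.true_observation, manifest=manifest)


def truths_json(ds: SyntheticDataset) -> str:
    """Generating parameter values as a JSON document."""
    d = {
        "process": {k: np.asarray(v).tolist()
                    for k, v in asdict(ds.true_process).items()},
        "observation": {k: np.asarray(v).tolist()
                        for k, v in asdict(ds.true_observation).items()},
        "manifest": ds.manifest,
    }
    return json.dumps(d, indent=2)
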