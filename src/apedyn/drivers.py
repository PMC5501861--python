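"""Trend aggregation and threat-driver attribution.

Abundance is aggregated by region and land use, the decadal decline rate is
derived by geometric interpolation between the first and last survey-period
midpoints, and four driver scores summarise the threats acting on the
population: HLOSS (forest-extent loss, high = high threat), CONFL
(forest x distance-to-conversion product, low = high threat), ANTH (the
survival submodel's rainfall/protected-area component evaluated at the
fitted coefficients, low = high threat) and FRAG (mean occupied-patch size
x mean reciprocal patch isolation, low = high threat). Scores are binned
into Strong / Moderate / Mild / Minimal importance classes by percentile
across the units being compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import GridLandscape, PatchSet, LANDUSE_CLASSES

IMPORTANCE_CLASSES = ("Strong", "Moderate", "Mild", "Minimal")

#: whether a high score means a high threat, per driver
HIGH_IS_THREAT = {"HLOSS": True, "CONFL": False, "ANTH": False, "FRAG": False}


def abundance_by_stratum(abundance: np.ndarray, landscape: GridLandscape,
                         period: int) -> pd.DataFrame:
    """Total abundance and within-region proportions by region x land use.

    ``abundance`` is a per-cell vector (a simulated or posterior-mean Nou
    for one period). Cells with an unrecognised land-use label are counted
    under OTHER with a warning.
    """
    ab = np.asarray(abundance, dtype=float)
    if ab.shape != (landscape.ncell,):
        raise ValueError("abundance must be a per-cell vector")
    lu = landscape.landuse[:, period].copy()
    bad = ~np.isin(lu, LANDUSE_CLASSES)
    if bad.any():
        warnings.warn(f"{bad.sum()} cells with unknown land use counted as OTHER")
        lu[bad] = "OTHER"
    df = pd.DataFrame({"region": landscape.region, "landuse": lu, "N": ab})
    out = df.groupby(["region", "landuse"], as_index=False)["N"].sum()
    totals = out.groupby("region")["N"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["proportion"] = np.where(totals > 0, out["N"] / totals, np.nan)
    out["period"] = period + 1
    return out


def decline_rate(totals, mid_years, horizon: float = 10.0) -> float:
    """Percent decline over ``horizon`` years, by geometric interpolation.

    The annualised factor g = (N_last / N_first)^(1 / (y_last - y_first)) is
    compounded over the horizon; the result 100 * (1 - g^horizon) is
    positive for decline and negative for growth. NaN when the initial
    total is zero.
    """
    totals = np.asarray(totals, dtype=float)
    mid_years = np.asarray(mid_years, dtype=float)
    if len(totals) < 2 or len(totals) != len(mid_years):
        raise ValueError("need >= 2 period totals with matching mid-years")
    n0, n1 = totals[0], totals[-1]
    span = mid_years[-1] - mid_years[0]
    if span <= 0:
        raise ValueError("mid-years must increase")
    if n0 <= 0:
        return np.nan
    g = (n1 / n0) ** (1.0 / span)
    return 100.0 * (1.0 - g ** horizon)


def habitat_loss_score(FR_prev, FR_curr) -> np.ndarray | float:
    """HLOSS = FR_{t-1} - FR_t; positive = forest lost (high threat)."""
    FR_prev = np.asarray(FR_prev, dtype=float)
    FR_curr = np.asarray(FR_curr, dtype=float)
    if np.any((FR_prev < 0) | (FR_prev > 1) | (FR_curr < 0) | (FR_curr > 1)):
        raise ValueError("forest fractions must lie in [0, 1]")
    out = FR_prev - FR_curr
    return float(out) if out.ndim == 0 else out


def conflict_score(FR_curr, CFA_curr) -> np.ndarray | float:
    """CONFL = FR_t * CFA_t; low values = high conflict threat.

    Accepts raw or standardized covariates; :func:`driver_table` passes the
    raw values, because the low-score = high-threat orientation only holds
    on the raw scale (inside converted estates both z-scores are negative
    and their product turns large-positive)."""
    out = np.asarray(FR_curr, dtype=float) * np.asarray(CFA_curr, dtype=float)
    return float(out) if out.ndim == 0 else out


def anthropogenic_score(eta_hat, z_DRY, z_WET, z_DPA) -> np.ndarray | float:
    """ANTH = eta4*DRY + eta5*DRY^2 + eta6*WET + eta7*WET^2 + eta8*DPA on
    standardized covariates, using the fitted survival coefficients
    (eta_hat must supply indices 4..8 in a mapping or the full 11-vector);
    low values = high anthropogenic threat."""
    if isinstance(eta_hat, dict):
        try:
            e4, e5, e6, e7, e8 = (eta_hat[k] for k in
                                  ("eta4", "eta5", "eta6", "eta7", "eta8"))
        except KeyError as err:
            raise ValueError(f"missing fitted coefficient {err}") from None
    else:
        eta_hat = np.asarray(eta_hat, dtype=float)
        if eta_hat.shape != (11,):
            raise ValueError("eta_hat must be the 11-vector of survival coefficients")
        e4, e5, e6, e7, e8 = eta_hat[3:8]
    z_DRY = np.asarray(z_DRY, dtype=float)
    z_WET = np.asarray(z_WET, dtype=float)
    z_DPA = np.asarray(z_DPA, dtype=float)
    out = e4 * z_DRY + e5 * z_DRY ** 2 + e6 * z_WET + e7 * z_WET ** 2 + e8 * z_DPA
    return float(out) if out.ndim == 0 else out


@dataclass
class FragScore:
    """Fragmentation score with a flag for the single-patch degenerate case."""

    value: float
    isolation_omitted: bool


def fragmentation_score(patches: PatchSet, occupied: np.ndarray) -> FragScore:
    """FRAG = mean occupied-patch size x mean reciprocal nearest-patch
    distance; low values = high fragmentation threat.

    ``occupied`` is a per-cell boolean of predicted occurrence; a patch
    counts when it contains at least one occupied cell. With a single
    occupied patch the isolation factor is undefined and omitted
    (flagged). NaN when no patch is occupied.
    """
    occupied = np.asarray(occupied, dtype=bool)
    occ_patches = np.unique(patches.labels[(patches.labels > 0) & occupied])
    if len(occ_patches) == 0:
        return FragScore(value=np.nan, isolation_omitted=False)
    sizes = patches.sizes_km2[occ_patches - 1]
    dists = patches.nearest_km[occ_patches - 1]
    mean_size = float(sizes.mean())
    finite = np.isfinite(dists) & (dists > 0)
    if not finite.any():
        return FragScore(value=mean_size, isolation_omitted=True)
    return FragScore(value=mean_size * float((1.0 / dists[finite]).mean()),
                     isolation_omitted=False)


def classify_importance(scores: pd.Series | dict, driver: str) -> pd.Series:
    """Percentile-based importance classes across comparison units.

    Scores are first converted to threat orientation (negated for drivers
    where low means high threat), then ranked with midrank ties; the
    percentile (rank - 0.5)/n falls into left-closed bins:
    Strong >= 75, Moderate [50, 75), Mild [25, 50), Minimal < 25.
    Classes are invariant to positive affine rescaling of the scores.
    """
    if driver not in HIGH_IS_THREAT:
        raise ValueError(f"unknown driver {driver!r}; expected one of "
                         f"{sorted(HIGH_IS_THREAT)}")
    scores = pd.Series(scores, dtype=float)
    n = scores.notna().sum()
    if n < 4:
        raise ValueError("need at least 4 units to rank; pool strata first")
    threat = scores if HIGH_IS_THREAT[driver] else -scores
    pct = 100.0 * (threat.rank(method="average") - 0.5) / n
    out = pd.Series(index=scores.index, dtype=object)
    out[pct >= 75] = "Strong"
    out[(pct >= 50) & (pct < 75)] = "Moderate"
    out[(pct >= 25) & (pct < 50)] = "Mild"
    out[pct < 25] = "Minimal"
    return out


def driver_table(landscape: GridLandscape, eta_hat, z, occupied_by_period,
                 patches_by_period, by_landuse: bool = False) -> pd.DataFrame:
    """Per-region (or region x land use) mean driver scores over occupied
    cells, pooled over transitions, with importance classes per driver.

    HLOSS/CONFL/ANTH are averaged over cells where the species is predicted
    to occur; FRAG is computed per region from the occupied forest-patch
    structure of the final period. Two ranking variants exist (regions
    only, or region x land use jointly); both are exposed via
    ``by_landuse``.
    """
    C, T = landscape.ncell, landscape.nperiod
    frames = []
    for t in range(1, T):
        occ = np.asarray(occupied_by_period[:, t], dtype=bool)
        hl = habitat_loss_score(landscape.FR[:, t - 1], landscape.FR[:, t])
        # raw covariates: the low-score = high-threat orientation of the
        # forest x conversion-distance product only holds on the raw scale
        cf = conflict_score(landscape.FR[:, t], landscape.CFA[:, t])
        an = anthropogenic_score(eta_hat, z.DRY, z.WET, z.DPA[:, t])
        frames.append(pd.DataFrame({
            "region": landscape.region, "landuse": landscape.landuse[:, t],
            "occupied": occ, "HLOSS": hl, "CONFL": cf, "ANTH": an}))
    cells = pd.concat(frames, ignore_index=True)
    cells = cells[cells["occupied"]]
    keys = ["region", "landuse"] if by_landuse else ["region"]
    agg = cells.groupby(keys, as_index=False)[["HLOSS", "CONFL", "ANTH"]].mean()

    frag_rows = []
    for reg in np.unique(landscape.region):
        sel = landscape.region == reg
        occ = np.asarray(occupied_by_period[:, T - 1], dtype=bool) & sel
        fs = fragmentation_score(patches_by_period[T - 1], occ)
        frag_rows.append({"region": reg, "FRAG": fs.value,
                          "FRAG_isolation_omitted": fs.isolation_omitted})
    frag = pd.DataFrame(frag_rows)
    agg = agg.merge(frag, on="region", how="left")

    for drv in ("HLOSS", "CONFL", "ANTH", "FRAG"):
        try:
            agg[f"{drv}_class"] = classify_importance(
                agg[drv], drv).to_numpy()
        except ValueError:
            agg[f"{drv}_class"] = None
    return agg
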