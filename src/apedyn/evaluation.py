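"""Goodness-of-fit and validation.

Fit is assessed by comparing posterior-predictive nest counts with the
observed counts (Pearson r per period, averaged r, and the R-squared of a
pooled linear regression of predicted on observed), and by validating
predicted occupancy against interview-derived village presence/absence
labels via sensitivity (SN) and specificity (SP). A pre-fit screen flags
covariate pairs with |Pearson r| >= 0.45.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .inference import ChainSet, Model, _SL_GAMMA, _SL_MU
from .landscape import GridLandscape, standardize_covariates
from .observation import SurveyData
from scipy.special import expit

PRESENCE, ABSENCE, UNCLASSIFIED = "presence", "absence", "unclassified"

CORRELATION_FLAG = 0.45


@dataclass
class FitReport:
    """Goodness-of-fit summary."""

    r_per_period: list
    r_mean: float
    r2_pooled: float
    r2_per_period: list
    sn: float = np.nan
    sp: float = np.nan
    correlation_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "r_per_period": [None if np.isnan(v) else float(v)
                             for v in self.r_per_period],
            "r_mean": float(self.r_mean),
            "r2_pooled": float(self.r2_pooled),
            "r2_per_period": [None if np.isnan(v) else float(v)
                              for v in self.r2_per_period],
            "SN": None if np.isnan(self.sn) else float(self.sn),
            "SP": None if np.isnan(self.sp) else float(self.sp),
            "correlation_flags": self.correlation_flags,
        }


def predicted_nest_counts(chains: ChainSet, indicators: np.ndarray) -> np.ndarray:
    """(C, T) posterior-predictive mean nest count E[psi*Nou*xi_by-protocol?].

    Returns the posterior mean of the latent nest count Nnest; detection is
    applied per protocol in :func:`posterior_predictive_fit`.
    """
    acc = None
    n = 0
    for c in range(chains.n_chains):
        for s, row in enumerate(chains.latent_rows):
            vec = chains.draws[c, row]
            psi = 100.0 * (vec[_SL_GAMMA][0] + indicators @ vec[_SL_GAMMA][1:])
            nn = np.rint(psi * chains.Nou_draws[c, s])
            acc = nn if acc is None else acc + nn
            n += 1
    return acc / n


def posterior_predictive_fit(chains: ChainSet, data: SurveyData,
                             indicators: np.ndarray) -> FitReport:
    """Pearson r per period (and average) and pooled R2 between
    posterior-predictive expected counts and the observed nest counts.

    The expected count at a surveyed cell/protocol is the posterior mean of
    ``Nnest * xi_protocol`` over the stored draws. Constant predictions or
    observations make r undefined for that period (NA with a warning).
    """
    C, _, T = data.Y.shape
    pred = np.zeros((C, 2, T))
    n = 0
    for c in range(chains.n_chains):
        for s, row in enumerate(chains.latent_rows):
            vec = chains.draws[c, row]
            psi = 100.0 * (vec[_SL_GAMMA][0] + indicators @ vec[_SL_GAMMA][1:])
            nn = np.rint(psi * chains.Nou_draws[c, s])
            xi = expit(vec[_SL_MU])
            pred += nn[:, None, :] * xi[None, :, None]
            n += 1
    pred /= n

    obs_mask = ~np.isnan(data.Y)
    rs, r2s = [], []
    all_obs, all_pred = [], []
    for t in range(T):
        m = obs_mask[:, :, t]
        o = data.Y[:, :, t][m]
        p = pred[:, :, t][m]
        all_obs.append(o)
        all_pred.append(p)
        if len(o) < 2 or np.std(o) == 0 or np.std(p) == 0:
            warnings.warn(f"period {t + 1}: constant predictions or "
                          "observations; r undefined")
            rs.append(np.nan)
            r2s.append(np.nan)
            continue
        rs.append(float(np.corrcoef(o, p)[0, 1]))
        r2s.append(float(stats.linregress(o, p).rvalue ** 2))
    o = np.concatenate(all_obs)
    p = np.concatenate(all_pred)
    if len(o) >= 2 and np.std(o) > 0 and np.std(p) > 0:
        r2_pooled = float(stats.linregress(o, p).rvalue ** 2)
    else:
        r2_pooled = np.nan
    return FitReport(r_per_period=rs, r_mean=float(np.nanmean(rs)),
                     r2_pooled=r2_pooled, r2_per_period=r2s)


def village_presence_absence(data: SurveyData, period: int,
                             never_seen: np.ndarray | None = None) -> pd.Series:
    """Interview-derived village labels for one period.

    A village is labelled *presence* if at least one respondent reported
    the species in that period, *absence* if more than 50% (strictly) of
    the respondents who enter the forest more than once a month had never
    seen it, and *unclassified* otherwise (excluded from SN/SP).

    ``never_seen`` is an optional (C, M) binary override; by default a
    respondent is taken to have never seen the species if they reported it
    in no period.
    """
    Zou, FE = data.Zou, data.FE
    surveyed = ~np.isnan(Zou[:, :, period])
    villages = np.flatnonzero(surveyed.any(axis=1))
    if never_seen is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ever = np.nansum(Zou == 1.0, axis=(2,)) > 0   # (C, M)
        never_seen = ~ever
    labels = {}
    for i in villages:
        resp = surveyed[i]
        if resp.sum() == 0:
            warnings.warn(f"village cell {i + 1}: no respondents; unclassified")
            labels[i + 1] = UNCLASSIFIED
            continue
        if np.any(Zou[i, resp, period] == 1.0):
            labels[i + 1] = PRESENCE
            continue
        frequent = resp & (FE[i] == 1.0)
        nf = frequent.sum()
        if nf > 0 and never_seen[i, frequent].sum() / nf > 0.5:
            labels[i + 1] = ABSENCE
        else:
            labels[i + 1] = UNCLASSIFIED
    return pd.Series(labels, name="label", dtype=object)


def sensitivity_specificity(predicted: pd.Series | dict,
                            labels: pd.Series) -> tuple[float, float]:
    """SN = TP/(TP+FN) against presence labels, SP = TN/(TN+FP) against
    absence labels; unclassified villages are ignored. Returns NaN for a
    class with no labelled villages."""
    predicted = pd.Series(predicted)
    tp = fn = tn = fp = 0
    for vid, lab in labels.items():
        if lab == UNCLASSIFIED or vid not in predicted.index:
            continue
        p = bool(predicted[vid])
        if lab == PRESENCE:
            tp += p
            fn += not p
        elif lab == ABSENCE:
            tn += not p
            fp += p
    sn = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    sp = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    return sn, sp


def predicted_village_occupancy(chains: ChainSet, data: SurveyData,
                                period: int, threshold: float = 0.5) -> pd.Series:
    """Binary predicted presence per village: posterior mean occupancy
    above ``threshold`` (the default rule; configurable)."""
    surveyed = ~np.isnan(data.Zou[:, :, period])
    villages = np.flatnonzero(surveyed.any(axis=1))
    return pd.Series({int(i + 1): bool(chains.O_mean[i, period] > threshold)
                      for i in villages})


def covariate_correlation_screen(landscape: GridLandscape,
                                 period: int = 0) -> tuple[pd.DataFrame, list]:
    """Pairwise Pearson correlations among the raw covariates of one period
    (and the same pairs after standardisation, which leaves r unchanged);
    returns the matrix and the list of pairs flagged at |r| >= 0.45."""
    cols = {
        "ALT": landscape.ALT, "DRY": landscape.DRY, "WET": landscape.WET,
        "DPA": landscape.DPA[:, period], "MS": landscape.MS,
        "FR": landscape.FR[:, period], "CFA": landscape.CFA[:, period],
    }
    df = pd.DataFrame(cols)
    zero_var = [k for k, v in cols.items() if np.std(v) == 0]
    for k in zero_var:
        warnings.warn(f"covariate {k} has zero variance; correlations NA")
    corr = df.corr()
    flags = []
    names = list(cols)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            r = corr.iloc[a, b]
            if np.isfinite(r) and abs(r) >= CORRELATION_FLAG:
                flags.append((names[a], names[b], float(r)))
    return corr, flags


def evaluate_fit(chains: ChainSet, data: SurveyData, landscape: GridLandscape,
                 indicators: np.ndarray, period_for_villages: int | None = None
                 ) -> FitReport:
    """Full fit report: posterior-predictive r/R2, SN/SP against interview
    labels (pooled over periods unless one is given), and covariate flags."""
    report = posterior_predictive_fit(chains, data, indicators)
    periods = ([period_for_villages] if period_for_villages is not None
               else range(data.nperiod))
    sns, sps = [], []
    for t in periods:
        labels = village_presence_absence(data, t)
        if len(labels) == 0:
            continue
        pred = predicted_village_occupancy(chains, data, t)
        sn, sp = sensitivity_specificity(pred, labels)
        sns.append(sn)
        sps.append(sp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        report.sn = float(np.nanmean(sns)) if sns else np.nan
        report.sp = float(np.nanmean(sps)) if sps else np.nan
    _, flags = covariate_correlation_screen(landscape)
    report.correlation_flags = flags
    return report
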