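"""Reference parameter values for the Bornean orangutan system.

Posterior-mean coefficient estimates from the island-wide Bornean orangutan
dynamic abundance analysis (1997-2015, three 6-year periods). They serve as
a documented operating point: plugging them into the link functions yields
the familiar summary quantities — protocol detection probabilities of 82%
(aerial) and 75% (ground), 64% sub-cell nest-occurrence detection, 15%/21%
interview detection by forest-entry frequency, and forest-type nest decay
times of 228 (baseline), 266 (mangrove), 209 (peat), 244 (lowland) and 236
(montane) days — and they anchor the default synthetic scenarios.
"""

from __future__ import annotations

import numpy as np

from .observation import ObservationParams
from .process import ProcessParams

#: initial-abundance coefficients alpha_1..alpha_11 (log link)
ALPHA = np.array([1.023, 0.021, -0.025, 3.781, -3.892, 3.951, -4.162,
                  -0.072, 0.001, 0.881, 0.071])
#: occupancy coefficients beta_1..beta_11 (logit link)
BETA = np.array([1.423, 0.181, -0.123, 3.621, -3.422, 3.049, -3.664,
                 -0.036, 0.005, 0.872, 0.049])
#: survival coefficients eta_1..eta_11 (logit link)
ETA = np.array([2.662, -0.017, 0.025, -0.788, 0.721, -0.514, 0.537,
                -0.136, 0.012, 0.133, 0.215])
#: recruitment log-intercept chi
CHI = -2.265

#: interview detection (upsilon_1, upsilon_2)
UPSILON = np.array([-1.726, 0.417])
#: nest scaling gamma_0..gamma_5 (intercept, MGV, PT, LOWL, MONT, FRGM)
GAMMA = np.array([2.279, 0.385, -0.193, 0.165, 0.079, -0.153])
#: nest-count detection logits (mu_aerial, mu_ground)
MU = np.array([1.516, 1.097])
#: sub-cell nest-occurrence detection logit zeta
ZETA = 0.574


def borneo_process_params() -> ProcessParams:
    """Level-1 coefficients at the Borneo posterior means."""
    return ProcessParams(alpha=ALPHA.copy(), beta=BETA.copy(),
                         eta=ETA.copy(), chi=CHI)


def borneo_observation_params() -> ObservationParams:
    """Observation-layer coefficients at the Borneo posterior means."""
    return ObservationParams(upsilon=UPSILON.copy(), gamma=GAMMA.copy(),
                             mu=MU.copy(), zeta=ZETA)
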