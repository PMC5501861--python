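import numpy as np
import pytest

from apedyn.landscape import GridLandscape, StandardizedCovariates


def make_landscape(nrow=4, ncol=5, T=3, seed=0, village_all=False):
    """Small random-but-valid landscape for structural tests."""
    rng = np.random.default_rng(seed)
    C = nrow * ncol
    return GridLandscape(
        nrow=nrow, ncol=ncol,
        region=np.array(["west"] * (C // 2) + ["east"] * (C - C // 2),
                        dtype=object),
        landuse=np.full((C, T), "OTHER", dtype=object),
        ALT=rng.uniform(0, 900, C),
        DRY=rng.uniform(100, 300, C),
        WET=rng.uniform(200, 400, C),
        MS=rng.uniform(0, 1, C),
        DPA=rng.uniform(0, 10, (C, T)),
        FR=rng.uniform(0.05, 0.95, (C, T)),
        CFA=rng.uniform(0, 10, (C, T)),
        forest_class=np.full((C, T), "other", dtype=object),
        village_flag=(np.ones(C, bool) if village_all
                      else rng.random(C) < 0.3),
    )


def make_z(C, T, seed=0):
    """Standardized-covariate container with arbitrary finite z-scores."""
    rng = np.random.default_rng(seed)
    return StandardizedCovariates(
        ALT=rng.normal(size=C), DRY=rng.normal(size=C), WET=rng.normal(size=C),
        MS=rng.normal(size=C), DPA=rng.normal(size=(C, T)),
        FR=rng.normal(size=(C, T)), CFA=rng.normal(size=(C, T)),
        means={}, sds={})


@pytest.fixture
def landscape():
    return make_landscape()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
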