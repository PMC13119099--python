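import numpy as np
import pytest

from devkinetics import build_truth, generate_experiment
from devkinetics.data_io import NormalizedCurve
from devkinetics.pipeline import load_fixture_table

CONC_GRID = np.round(np.arange(11) * 0.15, 4)


@pytest.fixture(scope="session")
def sdvp_table():
    """Packaged per-concentration synchrony estimates (3 models x 11 concentrations)."""
    return load_fixture_table("s_dvp")


@pytest.fixture(scope="session")
def tmid_table():
    """Packaged per-concentration timing estimates (3 models x 11 concentrations)."""
    return load_fixture_table("t_mid")


def fixture_row(table, model, column):
    sub = table[table.model == model].sort_values("concentration_M")
    return (
        sub["concentration_M"].to_numpy(dtype=float),
        sub[column].to_numpy(dtype=float),
    )


@pytest.fixture(scope="session")
def default_truth():
    return build_truth({"seed": 1})


@pytest.fixture(scope="session")
def default_experiment(default_truth):
    vials, _ = generate_experiment(default_truth)
    return vials


def gompertz_curve(s_dvp, lam, t0=0.0, t1=None, step=8.0, concentration=0.0):
    """Noiseless normalized curve sampled from the Gompertz model on a grid."""
    from devkinetics.primary import gompertz_predict

    if t1 is None:
        # far enough into the plateau that y = 1.0 at machine precision,
        # so the curve is exact model output (no renormalization applied)
        t1 = lam + 45.0 / (np.e * s_dvp)
    t = np.arange(t0, t1 + step, step)
    y = gompertz_predict(t, s_dvp, lam)
    y = y / y[-1]
    y[-1] = 1.0
    return NormalizedCurve(concentration=concentration, times=t, y=y)
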