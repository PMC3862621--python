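import numpy as np
import pytest
from hypothesis import settings as hsettings

hsettings.register_profile("repro", derandomize=True, deadline=None)
hsettings.load_profile("repro")

from thermogerm import datasets
from thermogerm.germdata import GerminationMatrix, TemperatureRegime, design_regimes


@pytest.fixture(scope="session")
def matrices():
    """The three packaged transcribed germination matrices, keyed by label."""
    return datasets.load_all_matrices()


@pytest.fixture(scope="session")
def c_dactylon(matrices):
    return matrices["C. dactylon"]


@pytest.fixture(scope="session")
def savannah(matrices):
    return matrices["Savannah"]


@pytest.fixture(scope="session")
def princess(matrices):
    return matrices["Princess VII"]


@pytest.fixture(scope="session")
def printed_equations():
    return datasets.load_printed_equations()


def matrix_from_surface(fn, noise_sd=0.0, seed=0, cultivar="synthetic"):
    """Build a GerminationMatrix whose means follow fn(cool, warm) -> fraction."""
    rng = np.random.default_rng(seed)
    cells = {}
    for r in design_regimes():
        frac = float(np.clip(fn(r.cool_temp, r.warm_temp)
                             + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                             0.0, 1.0))
        cells[r] = GerminationMatrix.Cell(100.0 * frac, 0.0)
    return GerminationMatrix(cultivar=cultivar, cells=cells)


@pytest.fixture
def quadratic_truth():
    """A smooth bell-shaped quadratic germination surface (fraction scale);
    negative predictions in the cold corner are clipped to 0 by the
    generator, mimicking real data."""
    coef = np.array([-0.60, 0.070, -0.006, -0.00086, 0.00066, -0.00078])

    def fn(cool, warm):
        t1, t2 = warm, cool
        return (coef[0] + coef[1] * t1 + coef[2] * t2 + coef[3] * t1 ** 2
                + coef[4] * t1 * t2 + coef[5] * t2 ** 2)

    return coef, fn


@pytest.fixture
def bounded_quadratic_truth():
    """A quadratic surface whose values stay inside [0, 1] over the design
    triangle, so generated matrices are exactly polynomial (no clipping)."""
    coef = np.array([0.5, 0.1, -0.05, -0.1, 0.1, -0.05])

    def fn(cool, warm):
        t1, t2 = cool / 40.0, warm / 40.0
        return (coef[0] + coef[1] * t1 + coef[2] * t2 + coef[3] * t1 ** 2
                + coef[4] * t1 * t2 + coef[5] * t2 ** 2)

    return coef, fn
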