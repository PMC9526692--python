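import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from osteomics import simulate
from osteomics.proteomics import IntensityMatrix

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def irregular_polygon() -> np.ndarray:
    """A simple, non-convex-ish 7-gon fitting a 64x64 frame."""
    return np.array(
        [
            [8.3, 20.1],
            [12.7, 45.2],
            [30.5, 58.6],
            [50.2, 48.9],
            [55.8, 25.3],
            [40.1, 8.7],
            [20.4, 6.2],
        ]
    )


@pytest.fixture
def decaying_cell(irregular_polygon):
    """Noiseless synthetic cell with exponential radial decay."""
    spec = simulate.ImageSimSpec(
        image_size=(64, 64),
        polygon=irregular_polygon,
        centrosome=(30, 28),
        decay_rate=2.0,
        peak_intensity=1000.0,
        noise_sd=0.0,
        seed=0,
    )
    return simulate.gen_cell_image(spec)


def make_matrix(values: dict[str, list[float]], genes=None, log2=False) -> IntensityMatrix:
    """Small IntensityMatrix from a column -> values mapping."""
    df = pd.DataFrame(values, dtype=float)
    df.index = genes if genes is not None else [f"G{i}" for i in range(len(df))]
    return IntensityMatrix(df, log2=log2)


@pytest.fixture
def toy_matrix() -> IntensityMatrix:
    """2 genes x 14 samples in the study design, no missing values."""
    rng = np.random.default_rng(7)
    cols = (
        [f"T0_{r}" for r in (1, 2, 3)]
        + [f"T8_GC_{r}" for r in (1, 2)]
        + [f"T8_RPM_{r}" for r in (1, 2, 3)]
        + [f"T28_GC_{r}" for r in (1, 2, 3)]
        + [f"T28_RPM_{r}" for r in (1, 2, 3)]
    )
    df = pd.DataFrame(
        2.0 ** rng.normal(20, 2, (2, len(cols))), columns=cols, index=["ALPL", "COL1A1"]
    )
    return IntensityMatrix(df)
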