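import numpy as np
import pytest

from ramansip.spectra_io import BandReference, load_band_reference
from ramansip.synthetic import SimBand, SimulationConfig
import pandas as pd


@pytest.fixture(scope="session")
def ruegeria_ref():
    return load_band_reference("ruegeria")


@pytest.fixture(scope="session")
def durusdinium_ref():
    return load_band_reference("durusdinium")


@pytest.fixture(scope="session")
def durusdinium_ref_ext():
    return load_band_reference("durusdinium", extended=True)


def make_single_band_config(
    center=1000.0,
    n15_center=None,
    grid=(900.0, 1100.0, 1.0),
    noise_sd=0.0,
    jitter_sd=0.0,
    label_fraction=0.0,
    seed=0,
    baseline=False,
    **band_kwargs,
):
    """One isolated band on a compact grid; flat zero baseline unless asked."""
    band = SimBand(
        center_cm1=center,
        nitrogen_associated=n15_center is not None,
        n15_center_cm1=n15_center,
        **band_kwargs,
    )
    return SimulationConfig(
        bands=(band,),
        grid_lo_cm1=grid[0],
        grid_hi_cm1=grid[1],
        grid_step_cm1=grid[2],
        baseline_coeffs=(0.3, 0.2, -0.1) if baseline else (0.0,),
        fluorescence_weight=0.5 if baseline else 0.0,
        noise_sd=noise_sd,
        center_jitter_sd=jitter_sd,
        label_fraction=label_fraction,
        seed=seed,
    )


def single_band_reference(center, n15_center=None, assignment="test band"):
    return BandReference(
        pd.DataFrame(
            {
                "center_cm1": [center],
                "component": ["test"],
                "assignment": [assignment],
                "nitrogen_associated": [n15_center is not None],
                "n15_center_cm1": [np.nan if n15_center is None else n15_center],
            }
        )
    )
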