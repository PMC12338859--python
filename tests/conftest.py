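import numpy as np
import pandas as pd
import pytest

from phquant import io as pio
from phquant.calibrate import fit_calibration
from phquant.quantify import measurements_frame, quantify_field
from phquant.simulate import SensorModel, SimConfig, generate_calibration_series


@pytest.fixture(scope="session")
def sensor():
    return SensorModel()


@pytest.fixture(scope="session")
def calib_dataset(tmp_path_factory, sensor):
    """One rendered 8-level calibration series + its quantified measurements."""
    outdir = tmp_path_factory.mktemp("calib")
    config = SimConfig(seed=11)
    manifest, truth = generate_calibration_series(config, sensor, outdir, n_fields_per_pH=1)
    measurements = []
    for _, row in manifest.iterrows():
        pair = pio.load_field(row, root=outdir)
        measurements.extend(quantify_field(pair))
    df = measurements_frame(measurements).merge(
        manifest[["field_id", "pH_E"]], on="field_id", how="left"
    )
    return {"dir": outdir, "manifest": manifest, "truth": truth, "measurements": df}


@pytest.fixture(scope="session")
def fitted_curve(calib_dataset):
    return fit_calibration(calib_dataset["measurements"])
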