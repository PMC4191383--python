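import pytest

import silis
from silis.calibrate import calibrate_table
from silis.chem import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def default_calibration():
    """One default single-nucleoside calibration simulation plus its fits."""
    model = silis.default_model(("Am",), seed=1)
    df = silis.simulate_calibration(model, seed=1)
    rf, models = calibrate_table(df)
    return model, df, rf, models


@pytest.fixture(scope="session")
def trub_assay(registry):
    """Calibrated instrument + simulated tRNA-Phe/TruB digest (full turnover).

    Scenario constants: 13.2 pmol of a 76-mer with 23 G, one pseudouridine
    site at full occupancy, 0.1 pmol internal-standard spike per modified
    nucleoside.
    """
    counts = {"G": 23, "A": 18, "C": 18, "U": 17}
    model = silis.default_model(("Y", "C", "U", "G", "A"), seed=3)
    cal = silis.simulate_calibration(model, seed=3)
    rf, _ = calibrate_table(cal)
    truth = silis.SampleTruth.from_occupancy(
        rna_pmol=13.2,
        sequence_counts=counts,
        occupancy={"Y": (1, 1.0)},
        silis_amounts={"Y": 0.1, "C": 20.0, "U": 20.0, "G": 20.0, "A": 20.0},
    )
    digest = silis.simulate_digest(model, truth, seed=4)
    return model, rf, truth, digest, counts
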