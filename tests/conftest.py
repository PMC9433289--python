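import numpy as np
import pytest

from qnmrquant import AcquisitionParams, AnalyteSpec, SignalSpec
from qnmrquant.fixtures import load_fixtures


@pytest.fixture(scope="session")
def fx():
    """The checked-in worked-example fixtures (analytes, tables)."""
    return load_fixtures()


@pytest.fixture(scope="session")
def fine_params():
    """Acquisition grid fine enough for sub-percent trapezoidal areas
    (~10 points per linewidth at 1 Hz / 400 MHz)."""
    return AcquisitionParams(n_points=65536)


@pytest.fixture
def singlet_analyte():
    """A one-proton singlet test compound; 114.10 mg of it is one mmol,
    giving unit signal area."""
    return AnalyteSpec(
        name="probe",
        molecular_weight=114.10,
        purity=1.0,
        signals=(SignalSpec("s", 6.16, (), 1, 1.0, 0.5),),
    )


@pytest.fixture(scope="session")
def ir_tau_grid():
    """16 inversion delays log-spaced over [0.05, 4] s."""
    return np.logspace(np.log10(0.05), np.log10(4.0), 16)
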