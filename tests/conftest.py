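import numpy as np
import pandas as pd
import pytest

from pomcal import ap_model, density, synthetic


@pytest.fixture(scope="session")
def sr_table() -> pd.DataFrame:
    """SR-like synthetic biomarker table at the study's sample size."""
    return synthetic.generate("sr", 469, seed=11)


@pytest.fixture(scope="session")
def caf_table() -> pd.DataFrame:
    return synthetic.generate("caf", 469, seed=12)


@pytest.fixture(scope="session")
def toys():
    return synthetic.toy_models()


@pytest.fixture(scope="session")
def baseline_trace():
    """Baseline model paced to steady state + 90 beats (full protocol)."""
    return ap_model.pace_to_steady_state(ap_model.ParameterVector())


@pytest.fixture(scope="session")
def baseline_biomarkers(baseline_trace):
    out = ap_model.extract_biomarkers(baseline_trace)
    assert isinstance(out, ap_model.BiomarkerVector)
    return out


@pytest.fixture(scope="session")
def caf_biomarkers():
    """Biomarkers of the cAF-remodeled baseline under the full protocol."""
    trace = ap_model.pace_to_steady_state(ap_model.caf_adjusted_baseline())
    out = ap_model.extract_biomarkers(trace)
    assert isinstance(out, ap_model.BiomarkerVector)
    return out


@pytest.fixture(scope="session")
def baseline_threshold():
    return ap_model.diastolic_threshold(ap_model.ParameterVector())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
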