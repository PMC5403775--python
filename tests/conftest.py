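import hypothesis
import pytest

import ritdose as rd

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def nuclide() -> rd.Radionuclide:
    return rd.bi213()


@pytest.fixture(scope="session")
def product() -> rd.AntibodyProduct:
    """The 3 MBq/mL scenario antibody preparation."""
    return rd.AntibodyProduct(
        specific_activity_gbq_per_umol=45.6,
        injected_mass_ug=10.0,
        injected_volume_ml=1.0,
        immunoreactive_fraction=0.91,
    )
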