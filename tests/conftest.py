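import warnings

import pytest
from hypothesis import settings

import spinemech as sm

settings.register_profile("suite", max_examples=25, deadline=None,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def female_cd_truth():
    """Specimen truth at the published female Control/control-diet means."""
    return sm.SpecimenTruth.from_cell_means("female", "Control", "CD")


@pytest.fixture(scope="session")
def clean_axial_loop(female_cd_truth):
    rec = sm.generate_recording(
        sm.RecordingProtocol.axial_cyclic(), female_cd_truth, noise_sd=0.0
    )
    return sm.extract_cycle(rec, cycle_index=20)


@pytest.fixture(scope="session")
def clean_torsional_loop(female_cd_truth):
    rec = sm.generate_recording(
        sm.RecordingProtocol.torsional_cyclic(), female_cd_truth, noise_sd=0.0
    )
    return sm.extract_cycle(rec, cycle_index=20)


@pytest.fixture(scope="session")
def clean_creep_recording(female_cd_truth):
    return sm.generate_recording(
        sm.RecordingProtocol.creep(), female_cd_truth, noise_sd=0.0
    )


@pytest.fixture(autouse=True)
def _quiet_spinemech_warnings():
    """Loop-closure/design warnings are expected on noisy fixtures."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sm.errors.SpineMechWarning)
        yield
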