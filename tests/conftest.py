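import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# Published validation table: spiked-recovery amounts (μmol) and the printed
# integer recoveries (%), four samples per analyte.
RECOVERY_DATA = {
    "LA": [(34, 32, 94), (50, 49, 98), (78, 84, 108), (97, 102, 105)],
    "HMF": [(148, 130, 88), (123, 144, 116), (165, 173, 104), (200, 188, 94)],
}


@pytest.fixture
def recovery_data():
    return RECOVERY_DATA
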