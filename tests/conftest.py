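import dataclasses

import pytest

from lysoquant.presets import IMAGING_PRESETS
from lysoquant.synthdata import make_image_field

N_FIELDS = 20


@pytest.fixture(scope="session")
def control_fields():
    """20 control-condition fields (seeds 1..20) with ground truth."""
    preset = IMAGING_PRESETS["control"]
    return [make_image_field(preset, seed) for seed in range(1, N_FIELDS + 1)]


@pytest.fixture(scope="session")
def torin1_fields():
    """20 torin1-condition fields (seeds 1..20) with ground truth."""
    preset = IMAGING_PRESETS["torin1"]
    return [make_image_field(preset, seed) for seed in range(1, N_FIELDS + 1)]


@pytest.fixture()
def quiet_preset():
    """Control preset without nuclei or read noise, for constructed fixtures."""
    return dataclasses.replace(
        IMAGING_PRESETS["control"], nuclei_per_field=0, noise_sd=0.0
    )
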