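import numpy as np
import pytest

from celluscore import (
    make_flat_field,
    make_undulation_field,
    render_image,
)
from celluscore.trial_sim import OutcomeModel, TrialConfig


@pytest.fixture(scope="session")
def flat_image():
    """Noise-free render of perfectly smooth skin (60 x 70 mm, 10 px/mm)."""
    return render_image(make_flat_field((60.0, 70.0)), noise_sd=0.0)


@pytest.fixture(scope="session")
def ridge_image():
    """Noise-free horizontal-ridge render, 10 mm wavelength, in-band."""
    fld = make_undulation_field(0.12, 10.0, 0.0, extent_mm=(60.0, 70.0))
    return render_image(fld, noise_sd=0.0)


def css_only_config(
    herbal=None, placebo=None, weeks=(0, 2, 4, 8, 12, 14), seed=0, **kwargs
) -> TrialConfig:
    """Reduced trial config carrying only the severity-scale outcome."""
    if herbal is None:
        herbal = {w: v for w, v in zip(weeks, np.linspace(13.4, 9.9, len(weeks)))}
    if placebo is None:
        placebo = {w: 12.9 for w in weeks}
    model = OutcomeModel(
        trajectory={"herbal": dict(herbal), "placebo": dict(placebo)},
        participant_sd=kwargs.pop("participant_sd", 1.0),
        residual_sd=kwargs.pop("residual_sd", 0.78),
    )
    return TrialConfig(
        weeks=tuple(weeks), outcome_models={"css": model}, seed=seed, **kwargs
    )
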