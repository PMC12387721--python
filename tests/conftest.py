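"""Shared fixtures: rendered synthetic phantoms and their measurements.

Rendering at the default 512-pixel grid takes a couple of seconds, so the
standard phantoms are rendered once per session and shared.
"""

import warnings

import pytest

import cttf

# the default presets render the body filling the whole field of view,
# which legitimately trips the cropped-FOV warning
warnings.filterwarnings("ignore", message="phantom body touches all four image borders")


@pytest.fixture(scope="session")
def acr_rendered():
    """ACR-style phantom, Gaussian blur sigma=0.5 mm, noise 5 HU, seed 11."""
    spec = cttf.preset("acr_like", seed=11)
    return cttf.render(spec)


@pytest.fixture(scope="session")
def acr_measurement(acr_rendered):
    img, _ = acr_rendered
    return cttf.measure_slice(img, "computational_acr")


@pytest.fixture(scope="session")
def catphan_rendered():
    spec = cttf.preset("catphan_like", seed=12)
    return cttf.render(spec)


@pytest.fixture(scope="session")
def catphan_measurement(catphan_rendered):
    img, _ = catphan_rendered
    return cttf.measure_slice(img, "catphan604")


@pytest.fixture(scope="session")
def aapm_rendered():
    spec = cttf.preset("aapm_like", seed=13)
    return cttf.render(spec)


@pytest.fixture(scope="session")
def sharp_noiseless_acr():
    """No blur, no noise: ideal step edges and exact HU plateaus."""
    spec = cttf.preset("acr_like", seed=0, blur=cttf.NoBlur(), noise_sd_hu=0.0)
    return cttf.render(spec)
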