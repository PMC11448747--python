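import warnings

import pytest

from rtmalign import (
    ChannelSpec,
    MicroscopeConfig,
    NoSolutionWarning,
    ObjectiveSpec,
    compute_normalized_curves,
)

# Three-channel brightfield design used throughout: common 4.5 mm / NA 0.65
# objective and 45 mm tube lenses, path lengths 300/350/400 mm, 1.12 um
# camera pixels, 532 nm illumination.
F_O = 4.5
F_T = 45.0
D_TOTALS = (300.0, 350.0, 400.0)
PIXEL_PITCH = 1.12
WAVELENGTH_NM = 532.0
NA = 0.65


@pytest.fixture(scope="session")
def objective() -> ObjectiveSpec:
    return ObjectiveSpec(f_o=F_O, na=NA)


@pytest.fixture(scope="session")
def channels() -> tuple[ChannelSpec, ...]:
    return tuple(
        ChannelSpec(label=f"bf{int(d)}", d_total=d, f_t=F_T, pixel_pitch=PIXEL_PITCH)
        for d in D_TOTALS
    )


@pytest.fixture(scope="session")
def config(objective, channels) -> MicroscopeConfig:
    return MicroscopeConfig(
        objective=objective,
        wavelength_nm=WAVELENGTH_NM,
        channels=channels,
        reference_channel="bf300",
        estimation_channel="bf400",
    )


@pytest.fixture(scope="session")
def curves(config):
    """Normalized curves over the default scan (f_o +/- 0.25 mm, 1 um step).

    Computed once per session; the scan legitimately crosses each channel's
    no-imaging band, so the expected gap warnings are silenced here.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NoSolutionWarning)
        return compute_normalized_curves(config)
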