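import numpy as np
import pytest

from ctnoise import AcquisitionConfig, ImageStack, NoiseModel, \
    synthesize_noise_volume


def make_noise_stack(n_repeats=10, n_slices=1, matrix=64, sigma=10.0,
                     seed=0, fov=220.0, thickness=0.4, model=None,
                     dtype=np.float64) -> ImageStack:
    """Pure-noise stack (no phantom) for estimator tests."""
    config = AcquisitionConfig(matrix_size=matrix, fov_mm=fov,
                               slice_thickness_mm=thickness,
                               n_slices=n_slices, n_repeats=n_repeats,
                               seed=seed)
    if model is None:
        model = NoiseModel(sigma_hu=sigma)
    values = np.stack([synthesize_noise_volume(config, model, r)
                       for r in range(n_repeats)]).astype(dtype)
    return ImageStack(values=values, pixel_spacing_mm=config.pixel_spacing_mm,
                      slice_thickness_mm=thickness, label="noise")


@pytest.fixture(scope="session")
def white_stack_40():
    """40 repeats of white sigma=10 noise on a 128^2 slice."""
    return make_noise_stack(n_repeats=40, matrix=128, sigma=10.0, seed=3)
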