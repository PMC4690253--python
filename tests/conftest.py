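import numpy as np
import pytest

from cardiomad.phantom import PhantomSpec, contours_from_spec, generate_phantom_subject
from cardiomad.segmentation import ImageGrid, build_segment_masks
from cardiomad.t2fit import fit_map


@pytest.fixture(scope="session")
def noiseless_subject():
    """Deterministic lesion-free phantom with uniform tissue and no noise."""
    spec = PhantomSpec(seed=7, segment_sd_ms=0.0, pixel_jitter_sd_ms=0.0,
                       snr=np.inf)
    series, truth = generate_phantom_subject(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def highsnr_fit():
    """Lesion-free phantom at high SNR with a fitted map and polygon labels."""
    spec = PhantomSpec(seed=1, segment_sd_ms=0.0, pixel_jitter_sd_ms=0.0,
                       snr=200.0)
    series, truth = generate_phantom_subject(spec)
    t2map = fit_map(series, method="rician_mle")
    grid = ImageGrid(shape=series.grid_shape, pixel_spacing_mm=spec.pixel_spacing_mm)
    labels = build_segment_masks(contours_from_spec(spec), grid)
    return spec, series, truth, t2map, labels
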