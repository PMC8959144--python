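import numpy as np
import pytest

from ponsquant import synthetic


@pytest.fixture(scope="session")
def small_section_set():
    """Noise-free two-region section set with planted counts {A:50, B:20}."""
    shape = (200, 200)
    left = np.zeros(shape, dtype=bool)
    left[:, :100] = True
    right = ~left
    spec = synthetic.SectionSpec(
        image_shape=shape,
        n_sections=1,
        regions=[(1, (255, 0, 0), left), (2, (0, 255, 0), right)],
        planted_counts={1: 50, 2: 20},
        noise_sd=0.0,
        seed=11,
    )
    return spec, synthetic.make_section_set(spec)


@pytest.fixture(scope="session")
def tract_fixture():
    """Two-band tract: fascicles rows 100–119 and 130–149 over 300 columns."""
    spec = synthetic.TractSpec(
        fascicles=synthetic.band_fascicles(range(30, 330), [(100, 119), (130, 149)]),
        measurement_columns={"rostral": 40, "caudal": 200, "c250": 250, "c500": 320},
        image_shape=(300, 360),
        n_sections=4,
        pixel_size=2.0,
    )
    return spec, synthetic.make_tract_image(spec)


@pytest.fixture(scope="session")
def cloud_pair():
    """Control + 200 µm rostrally shifted clouds, n=10⁴ each."""
    volume = synthetic.make_pontine_volume()
    centre = np.array(volume.mask.shape) * volume.voxel_size / 2
    spec = synthetic.CloudSpec(
        volume=volume,
        clusters=[
            synthetic.ClusterSpec(centre=tuple(centre), cov=120.0**2, n_points=10000)
        ],
        group_shift=(200.0, 0.0, 0.0),
        seed=5,
    )
    control, shifted, true_shift = synthetic.make_pointclouds(spec)
    return volume, control, shifted, true_shift
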