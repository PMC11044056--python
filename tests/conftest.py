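import numpy as np
import pytest

from adhesio import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """Three well-separated FAs in a small circular cell."""
    return syn.SceneSpec(
        image_size_px=(128, 128),
        pixel_size_um=0.16,
        cell_radius_um=9.0,
        fa_specs=(
            syn.FaSpec(0.6, 0.3, 2.0, 1.0, 0.3, 100.0),
            syn.FaSpec(0.7, 2.4, 2.5, 0.8, 2.4, 100.0),
            syn.FaSpec(0.5, 4.5, 1.8, 0.9, -1.0, 100.0),
        ),
        background_level=10.0,
        noise_sigma=2.0,
        psf_sigma_px=1.0,
        seed=11,
    )


@pytest.fixture
def clean_scene(small_scene):
    """Same arrangement, noise- and blur-free."""
    import dataclasses

    return dataclasses.replace(small_scene, noise_sigma=0.0, psf_sigma_px=0.0)


@pytest.fixture
def single_fa_movie_spec():
    scene = syn.SceneSpec(
        image_size_px=(96, 96),
        pixel_size_um=0.16,
        cell_radius_um=6.5,
        fa_specs=(syn.FaSpec(0.6, 0.7, 2.5, 0.9, 0.7, 100.0),),
        background_level=10.0,
        noise_sigma=2.0,
        psf_sigma_px=1.0,
        seed=5,
    )
    return syn.MovieSpec(scene=scene, n_frames=12, frame_interval_s=20.0)
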