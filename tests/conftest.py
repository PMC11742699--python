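import numpy as np
import pytest

from plaquelipid import synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """Default calibrated cohort at the fixed session seed."""
    return synthetic.generate_lipidome_cohort(synthetic.default_cohort_config(seed=0))


@pytest.fixture(scope="session")
def zero_noise_cohort():
    cfg = synthetic.default_cohort_config(seed=0, noise_sd_scale=0.0)
    return synthetic.generate_lipidome_cohort(cfg)


@pytest.fixture(scope="session")
def calibration():
    return synthetic.calibrate_cohort(synthetic.default_cohort_config(seed=0))


@pytest.fixture(scope="session")
def ftir_lesion_scene():
    """Small FTIR scene with one lesion (alkene depressed to 0.6), no noise."""
    cfg = synthetic.IRSceneConfig(
        grid="FTIR", image_shape=(48, 48), pixel_size=1.1,
        plaque_lesions=(synthetic.Lesion(center=(24, 24), radius_um=12,
                                         alkene_scale=0.6),),
        noise_sd=0.0, seed=3)
    return synthetic.generate_ir_scene(cfg)


@pytest.fixture(scope="session")
def qcl_lesion_scene():
    """QCL whole-slide-like scene with two plaque lesions and mild noise."""
    cfg = synthetic.IRSceneConfig(
        grid="QCL", image_shape=(160, 160),
        plaque_lesions=(synthetic.Lesion(center=(60, 60), radius_um=40,
                                         amide1630_scale=1.5),
                        synthetic.Lesion(center=(115, 110), radius_um=30,
                                         amide1630_scale=1.5)),
        noise_sd=0.003, seed=5)
    return synthetic.generate_ir_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
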