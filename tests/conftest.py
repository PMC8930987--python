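import numpy as np
import pytest

from fiberimg import encoder as enc
from fiberimg import experiments as exp
from fiberimg.config import RunConfig
from fiberimg.fiber import FiberSpec, find_lp_modes


@pytest.fixture(scope="session")
def reference_fiber():
    """The reference hardware fiber: 50 um core, NA 0.22, 1 km at 1064 nm."""
    return FiberSpec()


@pytest.fixture(scope="session")
def reference_basis(reference_fiber):
    return find_lp_modes(reference_fiber, grid_size=128)


@pytest.fixture(scope="session")
def small_fiber():
    """A few-dozen-mode fiber (V ~ 11.8) for cheap coupling tests."""
    return FiberSpec(core_radius_um=10.0, na=0.2, length_m=1000.0)


@pytest.fixture(scope="session")
def small_basis(small_fiber):
    return find_lp_modes(small_fiber, grid_size=64)


@pytest.fixture(scope="session")
def oracle_basis():
    """~50-mode fiber used for the linear pseudoinverse recovery checks."""
    return find_lp_modes(FiberSpec(core_radius_um=11.0, na=0.22, length_m=1000.0), grid_size=64)


@pytest.fixture()
def pulse():
    return enc.OpticalPulse()


@pytest.fixture()
def detector():
    return enc.DetectorSpec()


@pytest.fixture()
def small_geometry(small_basis):
    """16x16 object plane mapped onto the small fiber's core, slightly off-axis."""
    a = small_basis.fiber.core_radius_um
    pitch = 2 * a / 16  # footprint = core diameter at magnification 1
    return enc.SceneGeometry(
        pixel_pitch_um=pitch, image_shape=(16, 16), magnification=1.0, offset_um=(0.7, 1.1)
    )


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_system(small_basis):
    a = small_basis.fiber.core_radius_um
    geometry = enc.SceneGeometry(
        pixel_pitch_um=2 * a / 16, image_shape=(16, 16), magnification=1.0,
        offset_um=(0.7, 1.1),
    )
    return exp.SimulatedSystem(
        basis=small_basis,
        geometry=geometry,
        pulse=enc.OpticalPulse(),
        detector=enc.DetectorSpec(),
        coupling_model="coherent",
    )


def random_image(rng, shape=(16, 16)):
    return rng.uniform(0.0, 1.0, size=shape)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale configuration bound to the small test fiber."""
    return RunConfig.model_validate(
        {
            "fiber": {"core_radius_um": 10.0, "na": 0.2},
            "geometry": {
                "pixel_pitch_um": 1.25,
                "image_shape": (16, 16),
                "magnification": 1.0,
                "offset_um": (0.7, 1.1),
            },
            "decoder": {"arch": "linear"},
        }
    )


@pytest.fixture(scope="session")
def small_cfg_system(small_cfg):
    return exp.build_system(small_cfg, grid_size=64)


@pytest.fixture(scope="session")
def robustness_study(small_cfg, small_cfg_system):
    """Perturbation study shared by the module tests and acceptance suite."""
    return exp.run_robustness(
        strengths=(0.0, 0.15, 0.3, 0.6), delay_jitter_ps=40.0,
        joint_training=True, n_train=600, n_test=120, seed=1,
        cfg=small_cfg, system=small_cfg_system, arch="linear",
    )


@pytest.fixture(scope="session")
def ablation_probe(reference_basis):
    """Length ablation on the reference fiber with a rank-probing stimulus.

    Full-rank random images and the intensity-linear coupling make the
    recovered fidelity track the number of temporally resolved modes, which
    is what fiber length controls.
    """
    a = reference_basis.fiber.core_radius_um
    cfg = RunConfig.model_validate(
        {
            "geometry": {
                "pixel_pitch_um": 2 * a / 16,
                "image_shape": (16, 16),
                "magnification": 1.0,
                "offset_um": (0.9, 1.3),
            },
            "study": {"coupling_model": "incoherent"},
            "decoder": {"arch": "linear"},
        }
    )
    system = exp.SimulatedSystem(
        basis=reference_basis,
        geometry=cfg.geometry.to_spec(),
        pulse=cfg.pulse.to_spec(),
        detector=cfg.detector.to_spec(),
        coupling_model="incoherent",
    )
    return exp.run_length_ablation(
        lengths_m=(100, 400, 1000), n_train=600, n_test=100, seed=5,
        cfg=cfg, system=system, arch="linear", stimulus="random",
    )
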