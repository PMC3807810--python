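import numpy as np
import pytest

from fetalreg.imagecore import AffineTransform, ScalarVolume, VolumeGrid
from fetalreg.pseudous import assign_pseudo_intensities
from fetalreg.synthetic import (
    PhantomSpec,
    UsArtifactSpec,
    make_label_phantom,
    make_tissue_phantom,
    shadow_half_angle_for_fraction,
    simulate_us,
)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def structure_map(phantom_spec):
    return make_label_phantom(phantom_spec)


@pytest.fixture(scope="session")
def tissue_phantom(phantom_spec):
    return make_tissue_phantom(phantom_spec)


@pytest.fixture(scope="session")
def pseudo(structure_map):
    return assign_pseudo_intensities(structure_map)


@pytest.fixture(scope="session")
def brain_mask(structure_map):
    return structure_map.labels > 0


@pytest.fixture(scope="session")
def shadow_half_angle(structure_map, brain_mask):
    """Cone half-angle occluding 20% of the brain from the default probe."""
    return shadow_half_angle_for_fraction(
        brain_mask, structure_map.grid, (0.0, 0.0, 55.0), (0.0, 0.0, -1.0), 0.2
    )


@pytest.fixture(scope="session")
def padded_us_grid(structure_map):
    """US grid with a 9 mm margin so rotated heads are not clipped."""
    g = structure_map.grid
    pad = 12
    return VolumeGrid(
        tuple(s + 2 * pad for s in g.shape),
        g.spacing,
        tuple(o - pad * sp for o, sp in zip(g.origin, g.spacing)),
    )


def random_rigid(rng, max_rot_deg=30.0, max_shift_mm=4.0):
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_rot_deg)
    m = np.eye(4)
    m[:3, :3] = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
    m[:3, 3] = rng.uniform(-max_shift_mm, max_shift_mm, 3)
    return AffineTransform(m), angle


def mean_displacement_error(t_est, t_true, mask, grid, stride=7):
    pts = grid.index_to_world(np.argwhere(mask)[::stride])
    return float(np.linalg.norm(t_est.apply(pts) - t_true.apply(pts), axis=1).mean())


@pytest.fixture(scope="session")
def standard_us(pseudo, structure_map, shadow_half_angle, padded_us_grid):
    """One simulated US volume of the phantom under a known rigid transform."""
    truth = AffineTransform.from_rigid((2.0, -3.0, 1.0), (12.0, 5.0, -8.0))
    art = UsArtifactSpec(transform=truth, shadow_half_angle_deg=shadow_half_angle, seed=3)
    us, _ = simulate_us(pseudo, art, out_grid=padded_us_grid)
    return us, truth


def textured_volume(shape=(40, 40, 40), spacing=1.0, seed=0, smooth=1.0):
    """Feature-rich random texture for block-matching tests."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    vals = gaussian_filter(rng.normal(size=shape), smooth) * 40.0 + 100.0
    grid = VolumeGrid(shape, (spacing,) * 3, (0.0, 0.0, 0.0))
    return ScalarVolume(grid, vals)
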