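"""Shared fixtures: small phantoms and templates, generated at test time."""

import numpy as np
import pytest

import rfaseg as rs


def centered_phantom_spec(shape=(97, 97, 41), spacing=(0.7, 0.7, 2.0), **kwargs):
    """Phantom spec whose lesion center falls exactly on a voxel center."""
    center = tuple(((n - 1) // 2) * s for n, s in zip(shape, spacing))
    return rs.PhantomSpec(
        shape=shape, spacing=spacing, lesion_center=center, **kwargs
    )


@pytest.fixture(scope="session")
def icosa_template():
    return rs.build_ray_template(0)


@pytest.fixture(scope="session")
def template_l2():
    return rs.build_ray_template(2)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noise-free spherical lesion, radius 15 mm, CT-like spacing."""
    spec = centered_phantom_spec(lesion_radii=(15.0, 15.0, 15.0))
    volume, truth = rs.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def needle_phantom():
    """Noisy phantom with bright rim and umbrella needle (σ = 10)."""
    spec0 = centered_phantom_spec(lesion_radii=(15.0, 15.0, 15.0))
    c = spec0.lesion_center
    needle = rs.NeedleSpec(entry_point=(c[0], 0.0, c[2]), hub=c)
    spec = centered_phantom_spec(
        lesion_radii=(15.0, 15.0, 15.0),
        rim_thickness_mm=2.0,
        needle=needle,
        noise_sigma=10.0,
        rng_seed=7,
    )
    volume, truth = rs.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture()
def uniform_volume():
    return rs.ImageVolume(np.full((20, 20, 20), 40.0), spacing=(1.0, 1.0, 1.0))


def random_node_grid(rng, template, n_nodes, cost_low=0, cost_high=100):
    """A NodeGrid with random integer costs on trivial geometry (oracle tests)."""
    rays = template.n_rays
    costs = rng.integers(cost_low, cost_high, size=(rays, n_nodes)).astype(float)
    radii = np.arange(1, n_nodes + 1, dtype=float)
    positions = (
        template.directions[:, None, :] * radii[None, :, None]
    )
    return rs.NodeGrid(
        positions=positions,
        radii=radii,
        gray=costs.copy(),
        cost=costs,
        in_bounds=np.ones((rays, n_nodes), dtype=bool),
        seed_world=np.zeros(3),
        reference_value=0.0,
    )
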