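import numpy as np
import pytest

from cardioshape.synthetic_anatomy import build_template, CohortSpec, sample_cohort


@pytest.fixture(scope="session")
def template():
    return build_template(8.0)


@pytest.fixture(scope="session")
def small_cohort(template):
    """A 10-case noisy cohort with the default five latent factors."""
    spec = CohortSpec(n_cases=10, seed=7)
    meshes, factors = sample_cohort(spec, template=template)
    return meshes, factors


@pytest.fixture(scope="session")
def noiseless_two_factor_cohort(template):
    spec = CohortSpec(
        n_cases=10, latent_sds=(0.10, 0.05), node_noise_sd=0.0, seed=3
    )
    return sample_cohort(spec, template=template)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_tet_mesh(rng, n_tets=50):
    """Well-separated random tetrahedra (disconnected, valid indices)."""
    from cardioshape.mesh import TetMesh

    points, tets = [], []
    for i in range(n_tets):
        base = rng.uniform(-100, 100, 3)
        p = base + rng.uniform(-1, 1, (4, 3))
        while abs(np.linalg.det(p[1:] - p[0])) < 1e-3:
            p = base + rng.uniform(-1, 1, (4, 3))
        tets.append([4 * i, 4 * i + 1, 4 * i + 2, 4 * i + 3])
        points.extend(p)
    return TetMesh(points=np.array(points), tets=np.array(tets), name="random")
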