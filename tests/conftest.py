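import numpy as np
import pytest

from seegqa.geometry3d import TriMesh


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_rigid(rng: np.random.Generator):
    """A random rigid transform (R, t) with |t| up to 50 mm."""
    return random_rotation(rng), rng.uniform(-50, 50, size=3)


@pytest.fixture(scope="session")
def icosphere80() -> TriMesh:
    """Icosphere of radius 80 mm, subdivision 4 (chord error ~0.05 mm)."""
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=4, radius=80.0)
    return TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def identity_cohort():
    """Zero-perturbation phantom cohort, 2 cases x 5 electrodes."""
    from seegqa.phantom import PhantomSpec, generate_cohort

    return generate_cohort(PhantomSpec(seed=11, n_cases=2, electrodes_per_case=5))
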