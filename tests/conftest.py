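import numpy as np
import pytest

from femur3d.angles import measure_femur
from femur3d.synthetic import SyntheticFemurSpec, generate_femur


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigidly_transformed(bone, R, t):
    """Apply x -> R x + t to meshes and landmarks of a BoneModel."""
    from femur3d.axes import BoneModel
    import trimesh

    def tf(mesh):
        return trimesh.Trimesh(vertices=mesh.vertices @ R.T + t, faces=mesh.faces, process=False)

    return BoneModel(
        outer=tf(bone.outer),
        inner=None if bone.inner is None else tf(bone.inner),
        landmarks={k: R @ v + t for k, v in bone.landmarks.items()},
        side=bone.side,
    )


@pytest.fixture(scope="session")
def default_femur():
    """One default synthetic femur (CCD 122.2, AV 14.2) with its truth."""
    return generate_femur(SyntheticFemurSpec(seed=1))


@pytest.fixture(scope="session")
def default_measurement(default_femur):
    bone, _ = default_femur
    return measure_femur(bone)
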