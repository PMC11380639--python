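import numpy as np
import pytest
import trimesh

from maxillomorph.phantom import REGIONS, PhantomSpec, make_reference_phantom


def zero_offsets():
    return {s: {r: 0.0 for r in REGIONS} for s in ("male", "female")}


@pytest.fixture(scope="session")
def reference_coarse():
    return make_reference_phantom("coarse")


@pytest.fixture(scope="session")
def sphere_pair():
    """Concentric spheres: reference r=30 mm, subject r=32 mm."""
    ref = trimesh.creation.icosphere(subdivisions=4, radius=30.0)
    subj = trimesh.creation.icosphere(subdivisions=4, radius=32.0)
    return ref, subj


def rigid_spec(seed, n_subjects=1, mm=3.0, deg=3.0):
    """Phantom spec with only rigid misalignment (no offsets/noise/dropout)."""
    return PhantomSpec(
        seed=seed,
        n_subjects=n_subjects,
        region_offset_mean=zero_offsets(),
        region_offset_sd=0.0,
        noise_sd=0.0,
        dropout_fraction=0.0,
        misalignment_mm=mm,
        misalignment_deg=deg,
    )


def random_rigid(rng):
    from scipy.spatial.transform import Rotation

    from maxillomorph.geometry import RigidTransform

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-np.pi, np.pi)
    return RigidTransform(
        Rotation.from_rotvec(axis * angle).as_matrix(), rng.uniform(-50, 50, 3)
    )
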