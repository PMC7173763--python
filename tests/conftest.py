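import numpy as np
import pytest

import kvpore as kp


@pytest.fixture
def config():
    return kp.AnalysisConfig()


@pytest.fixture(scope="session")
def toy_run():
    """A short deterministic toy trajectory with its ground truth."""
    spec = kp.ToyChannelSpec(n_frames=40, seed=11)
    frames, truth = kp.generate_toy_trajectory(spec)
    return spec, frames, truth


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix plus a translation vector."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return q, t


def transform_frame(frame: kp.StructureFrame, rot, trans) -> kp.StructureFrame:
    return kp.StructureFrame(
        chain_ids=frame.chain_ids,
        residue_numbers=frame.residue_numbers,
        residue_names=frame.residue_names,
        atom_names=frame.atom_names,
        elements=frame.elements,
        coords=frame.coords @ rot.T + trans,
        frame_index=frame.frame_index,
        time_ns=frame.time_ns,
    )
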