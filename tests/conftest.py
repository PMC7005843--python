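import numpy as np
import pytest

from ferroscan.family_db import default_database
from ferroscan.profile_hmm import ProfileHMM


@pytest.fixture(scope="session")
def db():
    return default_database()


def random_hmm(M: int, seed: int) -> ProfileHMM:
    """A random but valid profile HMM (Dirichlet emissions/transitions)."""
    rng = np.random.default_rng(seed)
    match = rng.dirichlet(np.full(20, 0.5), size=M)
    insert = rng.dirichlet(np.full(20, 2.0), size=M)
    trans = np.empty((M, 7))
    trans[:, :3] = rng.dirichlet(np.array([8.0, 1.0, 1.0]), size=M)
    trans[:, 3:5] = rng.dirichlet(np.array([8.0, 2.0]), size=M)
    trans[:, 5:7] = rng.dirichlet(np.array([8.0, 2.0]), size=M)
    hmm = ProfileHMM(
        name=f"rand_M{M}_s{seed}",
        match_emit=match,
        insert_emit=insert,
        trans=trans,
        background=rng.dirichlet(np.full(20, 5.0)),
    )
    hmm.validate()
    return hmm
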