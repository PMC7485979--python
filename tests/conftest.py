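import numpy as np
import pytest

from epimode import (ChainPartition, ToySpec, make_homodimer_complex,
                     make_toy_complex, toy_partition)

# TOY-A: planted contacts (binder 2..4) x (target 5..7), one-to-one.
TOY_CONTACTS = ((2, 5), (3, 6), (4, 7))


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec(binder_length=6, target_length=12, contacts=TOY_CONTACTS, seed=0)


@pytest.fixture(scope="session")
def toy(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_part(toy_spec):
    return toy_partition(toy_spec)


@pytest.fixture(scope="session")
def homodimer():
    return make_homodimer_complex(protomer_length=10, epitope_numbers=(4, 5, 6), seed=0)


def brute_force_contacts(structure, part, cutoff=5.0):
    """Exhaustive pairwise-distance oracle for residue contacts."""
    pairs = set()
    binder = [r for r in structure.residues(sorted(part.binder_chains))]
    target = [r for r in structure.residues(sorted(part.target_chains))]
    for rb in binder:
        for rt in target:
            d = np.linalg.norm(rb.coords()[:, None, :] - rt.coords()[None, :, :], axis=-1)
            if d.min() < cutoff:
                pairs.add((rb.key, rt.key))
    return pairs


def random_rigid_transform(rng):
    """Uniform random proper rotation + bounded translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(0, 2**31 - 1)))
    return rot.as_matrix(), rng.uniform(-20, 20, size=3)
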