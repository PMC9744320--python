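import numpy as np
import pytest

import dtiglyph as dg


@pytest.fixture(scope="session")
def healthy_phantom():
    """Noiseless healthy-fiber phantom: (EigenField, fiber mask, background mask)."""
    return dg.make_eigenfield_phantom(dg.healthy_spec())


@pytest.fixture(scope="session")
def healthy_scalars(healthy_phantom):
    ef, _, _ = healthy_phantom
    return dg.compute_scalars(ef)


@pytest.fixture(scope="session")
def healthy_normalized(healthy_phantom, healthy_scalars):
    ef, _, _ = healthy_phantom
    return dg.normalize_maps(ef, healthy_scalars)


def eigenfield_from_triples(triples, clamped=True):
    """Wrap an (n, 3) array of eigenvalue triples as an n x 1 x 1 EigenField."""
    L = np.asarray(triples, dtype=float).reshape(-1, 1, 1, 3)
    n = L.shape[0]
    V = np.zeros((n, 1, 1, 3, 3))
    V[..., 0, 0] = V[..., 1, 1] = V[..., 2, 2] = 1.0
    return dg.EigenField(
        L1=L[..., 0], L2=L[..., 1], L3=L[..., 2],
        V1=V[..., 0, :], V2=V[..., 1, :], V3=V[..., 2, :],
        affine=np.eye(4), clamped=clamped,
    )
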