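import numpy as np
import pytest

from endstate.io import ToySystem
from endstate.synth import ComplexSpec, ContactSpec, gen_toy_complex


def make_system(
    coords,
    charges=None,
    rmin_half=None,
    epsilon=None,
    born=None,
    groups=None,
    chains=None,
    resids=None,
    elements=None,
    names=None,
):
    """Hand-built n-atom system (single frame unless coords is 3-D)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    n = coords.shape[1]
    return ToySystem(
        names=np.asarray(names if names is not None else [f"X{i}" for i in range(n)], object),
        elements=np.asarray(elements if elements is not None else ["C"] * n, object),
        chain_ids=np.asarray(chains if chains is not None else ["A"] * n, object),
        residue_ids=np.asarray(resids if resids is not None else np.arange(1, n + 1)),
        residue_names=np.asarray(["RES"] * n, object),
        charges=np.asarray(charges if charges is not None else np.zeros(n), float),
        rmin_half=np.asarray(rmin_half if rmin_half is not None else np.full(n, 1.7), float),
        epsilon=np.asarray(epsilon if epsilon is not None else np.full(n, 0.1), float),
        born_radius=np.asarray(born if born is not None else np.full(n, 1.7), float),
        group=np.asarray(groups if groups is not None else ["receptor"] * n, object),
        coords=coords,
    )


@pytest.fixture(scope="session")
def toy_complex():
    """Small bound complex with one designed hydrogen bond (90% of frames)."""
    spec = ComplexSpec(
        n_protein_chains=3,
        residues_per_chain=2,
        n_rna_nucleotides=2,
        contact_pairs=(
            ContactSpec("hbond", "A:1:OH", "R:1:OP2", 2.7, on_fraction=0.9),
        ),
        n_frames=10,
        jitter_sigma=0.03,
        seed=11,
    )
    return gen_toy_complex(spec)


@pytest.fixture(scope="session")
def salt_bridge_complex():
    """Complex whose only strong contact is a designed salt bridge on B:1."""
    spec = ComplexSpec(
        n_protein_chains=3,
        residues_per_chain=1,
        n_rna_nucleotides=2,
        contact_pairs=(
            ContactSpec(
                "salt_bridge", "B:1:charged_group", "R:1:phosphate", 3.7, on_fraction=1.0
            ),
        ),
        n_frames=4,
        jitter_sigma=0.0,
        seed=7,
    )
    return gen_toy_complex(spec)
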