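"""Shared fixtures: small random structures and light descriptor settings.

Descriptor tests use a reduced basis (n_max=4, l_max=3) — the invariances
under test hold for any basis size, and the reduced basis keeps the suite
fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from confnav.descriptors import SoapParams
from confnav.structures import Dataset, Structure


LIGHT = dict(cutoff=4.0, atom_sigma=0.3, n_max=4, l_max=3, zeta=2.0)


@pytest.fixture
def light_params() -> SoapParams:
    return SoapParams(**LIGHT)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_structure(
    rng: np.random.Generator,
    n_atoms: int = 5,
    species_pool: tuple[str, ...] = ("C", "N", "O", "H"),
    sid: str = "s",
    scale: float = 1.2,
) -> Structure:
    """Random small molecule with atoms kept at least 0.7 Å apart."""
    while True:
        coords = rng.normal(scale=scale, size=(n_atoms, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        if n_atoms == 1 or d[np.triu_indices(n_atoms, 1)].min() > 0.7:
            break
    species = [str(s) for s in rng.choice(species_pool, size=n_atoms)]
    return Structure(sid, species, coords)


@pytest.fixture
def toy_dataset(rng) -> Dataset:
    """Five random small structures of varied size and composition."""
    return Dataset(
        [random_structure(rng, n_atoms=3 + i % 3, sid=f"t{i}") for i in range(5)],
        name="toy",
    )
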