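import numpy as np
import pytest

from ciukit.structures import Atom, IonizableSite, SiteKind, Structure


@pytest.fixture
def single_atom():
    return Structure([Atom("N", "N", 0.0, 0.0, 0.0, "UNK", 1)])


@pytest.fixture
def three_atom_chain():
    return Structure(
        [Atom("C", "C", i * 2.0, 0.0, 0.0, "UNK", 1) for i in range(3)]
    )


def random_site_system(seed: int, n_sites: int = 12, box: float = 30.0):
    """A random mixed basic/acidic site inventory with uniform coordinates."""
    basic = [SiteKind.LYS, SiteKind.ARG, SiteKind.HIS, SiteKind.NTERM]
    acidic = [SiteKind.ASP, SiteKind.GLU, SiteKind.CTERM]
    rng = np.random.default_rng(seed)
    n_basic = int(rng.integers(4, n_sites - 2))
    kinds = [basic[rng.integers(len(basic))] for _ in range(n_basic)] + [
        acidic[rng.integers(len(acidic))] for _ in range(n_sites - n_basic)
    ]
    sites = [
        IonizableSite(i, k, i + 1, "A", i) for i, k in enumerate(kinds)
    ]
    coords = rng.uniform(0.0, box, (n_sites, 3))
    z = int(rng.integers(1, n_basic + 1))
    return sites, coords, z
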