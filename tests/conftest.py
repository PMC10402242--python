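import numpy as np
import pytest

from ntdp.proteoform import Proteoform, SiteMod
from ntdp.chem import mod_delta


# residues with a side-chain mod vocabulary we can sample from
_MODDABLE = {"K": ["acetyl", "methyl"], "S": ["phospho"], "T": ["phospho"],
             "N": ["deamidation"], "C": ["nitrosyl"], "M": ["ox"]}
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def random_proteoform(rng: np.random.Generator, min_len: int = 8,
                      max_len: int = 40, p_mod: float = 0.15,
                      with_terminal: bool = True) -> Proteoform:
    """A random valid proteoform with target-compatible site modifications."""
    n = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list(_ALPHABET), size=n))
    mods = []
    for pos, aa in enumerate(seq, start=1):
        if aa in _MODDABLE and rng.random() < p_mod:
            name = str(rng.choice(_MODDABLE[aa]))
            mods.append(SiteMod(pos, mod_delta(name), True))
    nterm = mod_delta("acetyl") if (with_terminal and rng.random() < 0.3) else None
    return Proteoform("RND", seq, nterm_mod=nterm, site_mods=tuple(mods))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260201)


@pytest.fixture(scope="session")
def fixture_suite():
    """The four standard simulated datasets at default noise, fixed seed."""
    from ntdp.search import expand_search_space
    from ntdp.simulate import FIXTURES, simulate_run

    out = {}
    for i, (name, factory) in enumerate(sorted(FIXTURES.items())):
        spec, space_cfg = factory(seed=11 + i)
        spectra, truth = simulate_run(spec)
        out[name] = {
            "spec": spec,
            "spectra": spectra,
            "truth": truth,
            "space": expand_search_space(space_cfg),
            "space_cfg": space_cfg,
        }
    return out
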