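"""Complexoform search: search-space expansion and intact-mass candidate
enumeration, checked against a brute-force oracle."""

import itertools
from collections import Counter

import numpy as np
import pytest

from ntdp.chem import metal_adduct_delta
from ntdp.proteoform import Complexoform, Proteoform, proteoform_mass
from ntdp.search import (
    SearchSpace,
    SearchSpaceError,
    ambiguity_sets,
    classify_tier,
    enumerate_candidates,
    expand_search_space,
)


def _poly(n: int, aa: str = "G") -> str:
    return aa * n


def test_expand_mass_level_counting():
    # one optional acetyl (0 or 1 copies, unlocalized) gives 2 proteoforms
    space = expand_search_space({
        "proteins": [{"id": "A", "sequence": _poly(10),
                      "mods": [{"name": "acetyl", "max": 1}]}],
    })
    assert space.size == 2
    # acetyl <= 2 and methyl <= 1 give 3 x 2 = 6 mass-distinct proteoforms
    space = expand_search_space({
        "proteins": [{"id": "A", "sequence": _poly(10),
                      "mods": [{"name": "acetyl", "max": 2},
                               {"name": "methyl", "max": 1}]}],
    })
    assert space.size == 6


def test_expand_cap_overflow_names_protein():
    with pytest.raises(SearchSpaceError, match="BIGPROT"):
        expand_search_space({
            "proteins": [{"id": "BIGPROT", "sequence": _poly(10),
                          "mods": [{"name": "acetyl", "max": 9}]}],
        }, cap=3)


def test_expand_reads_fasta(tmp_path):
    fasta = tmp_path / "seqs.fasta"
    fasta.write_text(">P1 test protein\nGGGGG\nAAAAA\n")
    space = expand_search_space({
        "proteins": [{"id": "P1", "fasta": str(fasta), "fasta_id": "P1"}],
    })
    assert space.proteoforms[0].base_sequence == "GGGGGAAAAA"


def test_unique_trimer_match():
    # subunits A (homopolymer) and B (A + one extra residue): observed mass
    # 2 m_A + m_B has the unique multiset solution A+A+B
    space = expand_search_space({
        "proteins": [{"id": "A", "sequence": _poly(5)},
                     {"id": "B", "sequence": _poly(4) + "A"}],
        "stoichiometry": {"min_subunits": 3, "max_subunits": 3},
    })
    masses = {p.protein_id: proteoform_mass(p)[0] for p in space.proteoforms}
    obs = 2 * masses["A"] + masses["B"]
    res = enumerate_candidates(space, obs, tol=0.001)
    assert len(res) == 1
    assert Counter(p.protein_id for p in res[0].complexoform.subunits) == \
        {"A": 2, "B": 1}
    assert res[0].error_da == pytest.approx(0.0, abs=1e-9)


def test_metalloprotein_dimer_with_cu_and_zn():
    space = expand_search_space({
        "proteins": [{"id": "S", "sequence": _poly(30, "A")}],
        "stoichiometry": {"min_subunits": 2, "max_subunits": 2},
        "metals": {"Cu": 1, "Zn": 1},
    })
    m = proteoform_mass(space.proteoforms[0])[0]
    res = enumerate_candidates(space, 2 * m + 122.827, tol=1.0)
    best = res[0]
    assert best.complexoform.oligomeric_order == 2
    assert dict(best.complexoform.metals) == {"Cu": 1, "Zn": 1}


def test_far_mass_gives_empty_list():
    space = expand_search_space({
        "proteins": [{"id": "A", "sequence": _poly(5)}],
    })
    assert enumerate_candidates(space, 1.0e6, tol=1.0) == []


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _oracle(space: SearchSpace, obs: float, tol: float):
    """Exhaustive enumeration over all subunit multisets and metal multisets."""
    found = set()
    metals = sorted(space.metal_max)
    metal_sets = list(itertools.product(
        *(range(space.metal_max[m] + 1) for m in metals)))
    n = len(space.proteoforms)
    masses = [proteoform_mass(p)[0] for p in space.proteoforms]
    for size in range(space.min_subunits, space.max_subunits + 1):
        for combo in itertools.combinations_with_replacement(range(n), size):
            counts = Counter(space.proteoforms[i].protein_id for i in combo)
            if any(counts[pid] > cap
                   for pid, cap in space.per_protein_max.items()):
                continue
            base = sum(masses[i] for i in combo)
            for mset in metal_sets:
                delta = sum(metal_adduct_delta(m) * k
                            for m, k in zip(metals, mset))
                if abs(base + delta - obs) <= tol:
                    found.add((combo, tuple(
                        (m, k) for m, k in zip(metals, mset) if k)))
    return found


def _match_key(space, match):
    idx = {p.mass_key(): i for i, p in enumerate(space.proteoforms)}
    combo = tuple(sorted(idx[p.mass_key()] for p in match.complexoform.subunits))
    return (combo, match.complexoform.metals)


def _random_space(rng) -> SearchSpace:
    n_prot = int(rng.integers(1, 4))
    proteins = []
    for i in range(n_prot):
        length = int(rng.integers(5, 60))
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        mods = []
        if rng.random() < 0.7:
            mods.append({"name": "acetyl", "max": int(rng.integers(1, 3))})
        if rng.random() < 0.4:
            mods.append({"name": "phospho", "max": 1})
        proteins.append({"id": f"P{i}", "sequence": seq, "mods": mods})
    cfg = {
        "proteins": proteins,
        "stoichiometry": {"min_subunits": 1,
                          "max_subunits": int(rng.integers(2, 4))},
    }
    if rng.random() < 0.5:
        cfg["metals"] = {"Cu": 1, "Zn": 1}
    return expand_search_space(cfg)


def test_oracle_equivalence_on_randomized_spaces():
    # exact set equality against exhaustive enumeration on 50 random spaces
    rng = np.random.default_rng(7)
    for trial in range(50):
        space = _random_space(rng)
        masses = [proteoform_mass(p)[0] for p in space.proteoforms]
        # target mass: a perturbed random multiset sum, so hits are plausible
        size = int(rng.integers(space.min_subunits, space.max_subunits + 1))
        pick = rng.integers(0, len(masses), size=size)
        obs = float(sum(masses[i] for i in pick) + rng.normal(0, 5.0))
        tol = float(rng.uniform(0.5, 30.0))
        got = {_match_key(space, m) for m in enumerate_candidates(space, obs, tol)}
        want = _oracle(space, obs, tol)
        assert got == want, f"trial {trial}"


def test_tolerance_monotonicity():
    rng = np.random.default_rng(8)
    space = _random_space(rng)
    masses = [proteoform_mass(p)[0] for p in space.proteoforms]
    obs = 2 * masses[0] + 0.3
    small = {_match_key(space, m) for m in enumerate_candidates(space, obs, 1.0)}
    large = {_match_key(space, m) for m in enumerate_candidates(space, obs, 20.0)}
    assert small <= large


def test_ranking_permutation_invariant():
    rng = np.random.default_rng(9)
    space = _random_space(rng)
    masses = [proteoform_mass(p)[0] for p in space.proteoforms]
    obs = float(np.sum(masses[:2]))
    a = enumerate_candidates(space, obs, 10.0)
    shuffled = SearchSpace(
        list(reversed(space.proteoforms)), space.min_subunits,
        space.max_subunits, space.per_protein_max, space.metal_max)
    b = enumerate_candidates(shuffled, obs, 10.0)
    assert [m.label for m in a] == [m.label for m in b]


def test_classify_tier():
    space = expand_search_space({"proteins": [{"id": "A", "sequence": _poly(8)}]})
    m = proteoform_mass(space.proteoforms[0])[0]
    match = enumerate_candidates(space, m, 1.0)[0]
    assert classify_tier(match, [1e-9]) == "mass_and_fragments"
    assert classify_tier(match, []) == "mass_only"
    assert classify_tier(match, [0.5]) == "mass_only"
    assert classify_tier(None) == "observed_mass_only"


def test_near_isobaric_ambiguity_sets():
    # trimethyl vs acetyl differ by 0.0364 Da: grouped, not resolved
    space = expand_search_space({
        "proteins": [{"id": "A", "sequence": "K" + _poly(9),
                      "mods": [{"name": "acetyl", "max": 1},
                               {"name": "trimethyl", "max": 1}]}],
    })
    m = proteoform_mass(space.proteoforms[0])[0]
    matches = enumerate_candidates(space, m + 42.03, tol=0.1)
    assert len(matches) == 2
    groups = ambiguity_sets(matches, tol=0.05)
    assert len(groups) == 1 and len(groups[0]) == 2
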