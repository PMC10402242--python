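"""Mass chemistry: compositions, modification deltas, metal adducts,
isotope distributions and the averagine model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntdp import chem
from ntdp.chem import (
    ElementalComposition,
    averagine_composition,
    composition_mass,
    isotope_distribution,
    metal_adduct_delta,
    mod_delta,
)


@pytest.mark.parametrize("formula, mono", [
    ({"H": 2, "O": 1}, 18.01056),
    ({}, 0.0),
    ({"C": 2, "H": 3, "N": 1, "O": 1}, 57.02146),  # glycine residue
])
def test_composition_mass(formula, mono):
    assert composition_mass(formula)[0] == pytest.approx(mono, abs=1e-5)


def test_unknown_element_is_named():
    with pytest.raises(KeyError, match="Xx"):
        ElementalComposition({"Xx": 1})


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ElementalComposition({"C": -1})
    with pytest.raises(ValueError):
        ElementalComposition({"C": 1}) - {"C": 2}


@pytest.mark.parametrize("name, mono", [
    ("acetyl", 42.01057),
    ("methyl", 14.01565),
    ("dimethyl", 28.03130),
    ("trimethyl", 42.04695),
    ("phospho", 79.96633),
    ("deamidation", 0.98402),
    ("nitrosyl", 28.99017),
    ("met_loss", -131.04049),
    ("disulfide", -2.01565),
])
def test_modification_registry_masses(name, mono):
    assert mod_delta(name).mono_mass == pytest.approx(mono, abs=1e-5)


def test_modification_arithmetic():
    # two acetylations accumulate; dimethyl - methyl is one CH2 unit
    assert 2 * mod_delta("acetyl").mono_mass == pytest.approx(84.02113, abs=1e-5)
    assert (mod_delta("dimethyl").mono_mass - mod_delta("methyl").mono_mass
            == pytest.approx(14.01565, abs=1e-5))


def test_registry_internally_consistent():
    # every delta registered with a formula agrees with that formula's mass
    for name, delta in chem.registry().items():
        if delta.formula is not None:
            mono, _ = chem.formula_mass(delta.formula)
            assert delta.mono_mass == pytest.approx(mono, abs=1e-4), name


def test_unknown_modification_lists_known_names():
    with pytest.raises(KeyError, match="acetyl"):
        mod_delta("frobnication")


def test_registry_extension_roundtrip(tmp_path):
    path = tmp_path / "mods.yaml"
    path.write_text(
        "- name: myristoyl\n  formula: {C: 14, H: 26, O: 1}\n  targets: [G]\n"
        "- name: unknown_shift\n  mono_mass: 123.4567\n")
    loaded = chem.load_modifications(str(path))
    assert len(loaded) == 2
    assert mod_delta("myristoyl").mono_mass == pytest.approx(210.19836, abs=1e-4)
    assert mod_delta("unknown_shift").mono_mass == 123.4567


@pytest.mark.parametrize("metal, displaced, delta", [
    ("Cu", None, 60.91395),  # divalent default: 2 displaced protons
    ("Zn", None, 61.91349),
    ("Cu", 0, 62.92960),
])
def test_metal_adduct_delta(metal, displaced, delta):
    assert metal_adduct_delta(metal, displaced) == pytest.approx(delta, abs=1e-5)


def test_unsupported_metal_rejected():
    with pytest.raises(KeyError, match="Pu"):
        metal_adduct_delta("Pu")


def test_isotope_distribution_water():
    d = isotope_distribution({"H": 2, "O": 1}, prune=0.0)
    assert d.base_peak_mass == pytest.approx(18.0106, abs=1e-3)
    assert d.abundances.max() > 0.99
    assert d.abundances.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(d.masses) > 0)


def test_isotope_distribution_c100_ratio():
    # one-13C over all-12C equals the binomial term ratio 100 * r
    d = isotope_distribution({"C": 100})
    expected = 100 * 0.0107 / 0.9893
    assert d.abundances[1] / d.abundances[0] == pytest.approx(expected, rel=1e-6)


@pytest.mark.parametrize("formula", [
    {"C": 50, "H": 80, "N": 10, "O": 15},
    {"C": 10, "H": 20, "S": 2},
])
def test_isotope_distribution_normalized(formula):
    d = isotope_distribution(formula)
    assert d.abundances.sum() == pytest.approx(1.0, abs=1e-9)


def test_isotope_convolution_associative():
    # distribution of a+b equals the convolution of the two distributions
    a = {"C": 6, "H": 12, "O": 6}
    b = {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1}
    joint = isotope_distribution(
        ElementalComposition(a) + ElementalComposition(b), prune=0.0)
    conv = chem.convolve_distributions(
        isotope_distribution(a, prune=0.0), isotope_distribution(b, prune=0.0))
    k = min(len(joint), len(conv))
    assert np.max(np.abs(joint.abundances[:k] - conv.abundances[:k])) < 1e-9


def test_isotope_distribution_bad_inputs():
    with pytest.raises(ValueError):
        isotope_distribution({})
    with pytest.raises(ValueError):
        isotope_distribution({"C": 10}, prune=1.0)


def test_averagine_unit_case():
    c = averagine_composition(111.1254, kind="average")
    assert c["C"] == 5 and c["N"] == 1
    assert c.average_mass == pytest.approx(111.1254, abs=1.0)


def test_averagine_scaled_masses():
    assert abs(averagine_composition(11112.54).mono_mass - 11112.54) < 0.5
    assert abs(averagine_composition(37000, kind="average").average_mass
               - 37000) < 1.0


@settings(max_examples=50, deadline=None)
@given(st.dictionaries(st.sampled_from("CHNOS"), st.integers(0, 50), max_size=5),
       st.dictionaries(st.sampled_from("CHNOS"), st.integers(0, 50), max_size=5))
def test_mass_additivity(fa, fb):
    a, b = ElementalComposition(fa), ElementalComposition(fb)
    ma, _ = composition_mass(a)
    mb, _ = composition_mass(b)
    mab, _ = composition_mass(a + b)
    assert mab == pytest.approx(ma + mb, abs=1e-6)
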