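"""Simulator: determinism, conservation laws, charge partitioning and the
standard fixture suite."""

import re

import pytest

from ntdp.deconv import deconvolve_series, mz_for
from ntdp.proteoform import complexoform_mass
from ntdp.simulate import (
    FIXTURES,
    make_fixture_suite,
    mif_like_spec,
    partition_charge,
    simulate_run,
    sod1_like_spec,
    tpi_like_spec,
)
from ntdp.spectra import read_peaklist, write_peaklist


def _noise_free(factory, seed=1):
    spec, cfg = factory(seed=seed, mz_noise_sigma=0.0,
                        intensity_noise_sigma=0.0, decoy_rate=0.0,
                        fragment_detectability=1.0)
    return spec, cfg


def test_same_seed_byte_identical(tmp_path):
    for which in (0, 1):
        spec, _ = sod1_like_spec(seed=9)
        spectra, truth = simulate_run(spec)
        write_peaklist(spectra, str(tmp_path / f"run{which}.txt"))
        (tmp_path / f"truth{which}.tsv").write_text(truth.to_tsv())
    assert (tmp_path / "run0.txt").read_bytes() == (tmp_path / "run1.txt").read_bytes()
    assert (tmp_path / "truth0.tsv").read_bytes() == (tmp_path / "truth1.tsv").read_bytes()


def test_different_seed_differs(tmp_path):
    a, _ = sod1_like_spec(seed=1)
    b, _ = sod1_like_spec(seed=2)
    pa = simulate_run(a)[0][0].peaks
    pb = simulate_run(b)[0][0].peaks
    assert pa != pb


@pytest.mark.parametrize("factory", sorted(FIXTURES.values(),
                                           key=lambda f: f.__name__))
def test_mass_and_charge_conservation(factory):
    # every simulated dissociation conserves neutral mass and charge exactly
    spec, _ = factory(seed=4)
    spectra, truth = simulate_run(spec)
    complexes = {s.complexoform.label: complexoform_mass(s.complexoform)[0]
                 for s in spec.species}
    ms2 = [s for s in spectra if s.ms_level == 2]
    for s in ms2:
        anns = truth.for_spectrum(s.id)
        monos = [a for a in anns if a.kind == "monomer"]
        rems = [a for a in anns if a.kind == "remnant"]
        z_prec = s.precursor.charge
        for mono in monos:
            rem = min(rems, key=lambda r: abs(
                r.neutral_mass + mono.neutral_mass - complexes[mono.species_label]))
            total = mono.neutral_mass + rem.neutral_mass
            assert total == pytest.approx(complexes[mono.species_label], abs=1e-9)
            assert mono.charge + rem.charge == z_prec


def test_trimer_ejects_six_plus_monomer():
    # 12+ trimer of ~1/3-mass subunits: the partition rule gives a 6+ monomer
    assert partition_charge(12, 12330.0, 37000.0, bonus=2) == 6
    spec, _ = mif_like_spec(seed=1)
    spectra, truth = simulate_run(spec)
    ms2_monomers = [a for a in truth.annotations
                    if a.kind == "monomer" and a.spectrum_id.endswith("ms2_0")]
    # the unmodified subunit (exactly 1/3 of the trimer mass) takes 6+;
    # modified subunits sit just above 1/3 and the ceiling rule gives 7+
    charges = sorted(a.charge for a in ms2_monomers)
    assert charges[0] == 6 and set(charges) <= {6, 7}


def test_ms1_peak_positions():
    spec, _ = _noise_free(mif_like_spec)
    spectra, truth = simulate_run(spec)
    ms1 = spectra[0]
    # the 12+ trimer envelope lands inside the m/z 3080-3100 window
    anns = [a for a in truth.for_spectrum(ms1.id) if a.charge == 12]
    assert anns
    for a in anns:
        assert 3080 < a.mz < 3100


def test_tpi_dimer_deconvolves_to_printed_mass():
    spec, _ = _noise_free(tpi_like_spec)
    spectra, _ = simulate_run(spec)
    series, left = deconvolve_series(spectra[0].peaks)
    assert not left
    assert series[0].neutral_mass == pytest.approx(53070.9, abs=0.01)
    assert sorted(series[0].charges) == [15, 16]


def test_sod1_metal_fragment_emission_pattern():
    # apo b ions stop before the first coordinating residue (46); holo b ions
    # start at the deepest one (120) and carry both metals
    spec, _ = _noise_free(sod1_like_spec)
    spectra, truth = simulate_run(spec)
    frag = [a for a in truth.annotations if a.kind == "fragment"]
    b_apo = [int(m.group(1)) for a in frag
             if (m := re.search(r"ion=b(\d+)$", a.detail))]
    b_holo = [int(m.group(1)) for a in frag
              if (m := re.search(r"ion=b(\d+)\+Cu\+Zn$", a.detail))]
    assert max(b_apo) < 46
    assert min(b_holo) >= 120
    # truth <-> peaks bijection for non-decoy annotations
    ms3 = next(s for s in spectra if s.ms_level == 3)
    assert len(truth.for_spectrum(ms3.id)) == len(ms3.peaks)


def test_fixture_suite_files_and_determinism(tmp_path):
    suite1 = make_fixture_suite(str(tmp_path / "a"), seed=6)
    suite2 = make_fixture_suite(str(tmp_path / "b"), seed=6)
    assert set(suite1) == {"tpi_like", "mif_like", "sod1_like", "nutf2_like"}
    for name in suite1:
        p1 = suite1[name]["paths"]["peaklist"]
        p2 = suite2[name]["paths"]["peaklist"]
        assert open(p1, "rb").read() == open(p2, "rb").read()
        back = read_peaklist(p1)
        assert [s.id for s in back] == [s.id for s in suite1[name]["spectra"]]


def test_detectability_thins_fragments():
    full, _ = _noise_free(tpi_like_spec)
    thin, _ = tpi_like_spec(seed=1, mz_noise_sigma=0.0,
                            intensity_noise_sigma=0.0, decoy_rate=0.0,
                            fragment_detectability=0.5)
    n_full = len(simulate_run(full)[0][-1].peaks)
    n_thin = len(simulate_run(thin)[0][-1].peaks)
    assert n_thin < n_full


def test_invalid_spec_rejected():
    from ntdp.proteoform import Proteoform, Complexoform
    from ntdp.simulate import SimulatedSpecies, SimulationSpec

    c = Complexoform((Proteoform("X", "GGG"),))
    with pytest.raises(ValueError):
        SimulatedSpecies(c, 0.0, (5,))
    with pytest.raises(ValueError):
        SimulatedSpecies(c, 1.0, (5,), metal_retention="sideways")
    with pytest.raises(ValueError):
        SimulationSpec([SimulatedSpecies(c, 1.0, (5,))],
                       fragment_detectability=1.5)
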