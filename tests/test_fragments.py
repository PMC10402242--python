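"""HCD b/y ladders, fragment matching, the Poisson P-score, PTM localization,
confidence levels, metal-site inference and coverage maps."""

import numpy as np
import pytest
from scipy import stats

from ntdp.chem import mod_delta
from ntdp.fragments import (
    FragmentIon,
    FragmentMatch,
    CharacterizationResult,
    characterization_level,
    coverage_and_map,
    generate_by_ladder,
    localize_mods,
    match_fragments,
    metal_localization,
    p_score,
)
from ntdp.proteoform import Proteoform, SiteMod, proteoform_mass
from conftest import random_proteoform


def _by(ladder):
    return {f.name: f.neutral_mass for f in ladder}


def test_diglycine_ladder_complementarity():
    lad = _by(generate_by_ladder(Proteoform("X", "GG")))
    assert lad["b1"] == pytest.approx(57.02146, abs=1e-5)
    assert lad["y1"] == pytest.approx(75.03203, abs=1e-5)
    assert lad["b1"] + lad["y1"] == pytest.approx(
        proteoform_mass(Proteoform("X", "GG"))[0], abs=1e-6)


def test_site_mod_shifts_downstream_fragments():
    base = _by(generate_by_ladder(Proteoform("X", "AKGLM")))
    mod = _by(generate_by_ladder(Proteoform(
        "X", "AKGLM", site_mods=(SiteMod(2, mod_delta("acetyl")),))))
    assert mod["b1"] == pytest.approx(base["b1"])
    for i in (2, 3, 4):
        assert mod[f"b{i}"] - base[f"b{i}"] == pytest.approx(42.01057, abs=1e-5)
    assert mod["y3"] == pytest.approx(base["y3"])  # span excludes position 2
    assert mod["y4"] - base["y4"] == pytest.approx(42.01057, abs=1e-5)


def test_disulfide_excludes_intra_loop_cleavages_and_shifts_spanning_ions():
    seq = "AAC" + "A" * 3 + "C" + "AA"  # C3, C7, length 9
    p = Proteoform("X", seq, disulfides=((3, 7),))
    lad = generate_by_ladder(p)
    b_idx = sorted(f.index for f in lad if f.series == "b")
    assert b_idx == [1, 2, 7, 8]  # bonds 3..6 are inside the intact loop
    reduced = _by(generate_by_ladder(p, reduced=True))
    assert _by(lad)["b8"] - reduced["b8"] == pytest.approx(-2.01565, abs=1e-5)
    # complementarity holds at every allowed cleavage
    m = proteoform_mass(p)[0]
    lookup = _by(lad)
    for i in b_idx:
        assert lookup[f"b{i}"] + lookup[f"y{9 - i}"] == pytest.approx(m, abs=1e-6)


def test_complementarity_over_randomized_proteoforms(rng):
    for _ in range(100):
        p = random_proteoform(rng)
        lad = _by(generate_by_ladder(p))
        m = proteoform_mass(p)[0]
        n = p.length
        for i in range(1, n):
            assert lad[f"b{i}"] + lad[f"y{n - i}"] == pytest.approx(m, abs=1e-6)


def test_unlocalized_mods_shift_intact_mass_only():
    p = Proteoform("X", "KAAAA",
                   site_mods=(SiteMod(0, mod_delta("acetyl"), False),))
    base = Proteoform("X", "KAAAA")
    assert (proteoform_mass(p)[0] - proteoform_mass(base)[0]
            == pytest.approx(42.01057, abs=1e-5))
    assert _by(generate_by_ladder(p)) == _by(generate_by_ladder(base))


def test_holo_ladder_enumeration():
    p = Proteoform("X", "A" * 6)
    lad = generate_by_ladder(p, metals={"Cu": 1, "Zn": 1})
    names = {f.name for f in lad}
    assert {"b1", "b1+Cu", "b1+Zn", "b1+Cu+Zn"} <= names
    holo = next(f for f in lad if f.name == "b2+Cu")
    apo = next(f for f in lad if f.name == "b2")
    assert holo.neutral_mass - apo.neutral_mass == pytest.approx(60.91395, abs=1e-5)


def test_match_exact_ladder_and_decoys():
    p = Proteoform("X", "PEPTIDEKSAMPLER")
    theo = generate_by_ladder(p)
    obs = [f.neutral_mass for f in theo]
    decoys = [m * (1 + 80e-6) for m in obs[:5]]  # 80 ppm off: unmatched
    matches = match_fragments(theo, obs + decoys, tol_ppm=10)
    assert len(matches) == len(obs)
    assert all(abs(m.ppm_error) < 1e-6 for m in matches)


def test_match_tie_breaks():
    # two theoreticals within tolerance of one observed: smaller |ppm| wins
    t1 = FragmentIon("b", 1, 1000.000)
    t2 = FragmentIon("b", 2, 1000.005)
    matches = match_fragments([t1, t2], [1000.001], tol_ppm=10)
    assert len(matches) == 1 and matches[0].fragment.index == 1
    # exact tie between apo and holo: apo preferred
    apo = FragmentIon("b", 1, 1000.0)
    holo = FragmentIon("b", 1, 1000.0, (("Cu", 1),))
    matches = match_fragments([holo, apo], [1000.0], tol_ppm=10)
    assert matches[0].fragment.metal_content == ()


# ---------------------------------------------------------------------------
# P-score
# ---------------------------------------------------------------------------


def test_p_score_zero_matches_is_one():
    assert p_score(0, 20, [500.0] * 50, 10, (200, 2000)) == 1.0


def test_p_score_monotone_in_tolerance():
    theo = list(np.linspace(300, 1800, 50))
    prev = 0.0
    for tol in (5, 10, 20, 40):
        p = p_score(5, 20, theo, tol, (200, 2000))
        assert p >= prev
        prev = p


def test_p_score_degenerate_window():
    with pytest.raises(ValueError):
        p_score(1, 5, [500.0], 10, (100, 100))


def test_p_score_against_monte_carlo_null():
    # independent null simulation: uniform observed masses, count hits in the
    # (non-overlapping) theoretical acceptance windows, tail at n_matched
    rng = np.random.default_rng(12345)
    theo = list(np.linspace(300.0, 1800.0, 50))
    window = (200.0, 2000.0)
    # tolerance sized so q ~ 0.005 (window sum / span)
    q_target = 0.005
    tol_ppm = q_target * (window[1] - window[0]) / sum(2e-6 * m for m in theo)
    n_obs, n_matched = 20, 2
    p_model = p_score(n_matched, n_obs, theo, tol_ppm, window)

    edges = []
    for m in theo:
        half = tol_ppm * 1e-6 * m
        edges.extend([m - half, m + half])
    edges = np.array(edges)
    reps = 100_000
    draws = rng.uniform(window[0], window[1], size=(reps, n_obs))
    inside = (np.searchsorted(edges, draws) % 2) == 1
    hits = inside.sum(axis=1)
    p_mc = float(np.mean(hits >= n_matched))
    se = np.sqrt(p_mc * (1 - p_mc) / reps)
    assert abs(p_model - p_mc) < 3 * se + 1e-4


def test_p_score_null_calibration():
    # fraction of null trials with p <= alpha stays below 1.5 alpha
    rng = np.random.default_rng(999)
    theo = list(np.linspace(300.0, 1800.0, 60))
    window = (200.0, 2000.0)
    tol_ppm = 50.0
    edges = []
    for m in theo:
        half = tol_ppm * 1e-6 * m
        edges.extend([m - half, m + half])
    edges = np.array(edges)
    n_obs = 30
    trials = 10_000
    draws = rng.uniform(window[0], window[1], size=(trials, n_obs))
    hits = ((np.searchsorted(edges, draws) % 2) == 1).sum(axis=1)
    q = min(1.0, sum(2e-6 * tol_ppm * m for m in theo) / (window[1] - window[0]))
    lam = n_obs * q
    pvals = stats.poisson.sf(hits - 1, lam)
    pvals[hits == 0] = 1.0
    for alpha in (0.05, 0.01):
        frac = float(np.mean(pvals <= alpha))
        assert frac <= 1.5 * alpha, (alpha, frac)


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------


def _planted_obs(p: Proteoform):
    return [f.neutral_mass for f in generate_by_ladder(p)]


def test_localize_bracketed_site():
    seq = "AAAAAAAAAKAAAAAAAAAA"
    truth = Proteoform("X", seq, site_mods=(SiteMod(10, mod_delta("acetyl")),))
    hyp = Proteoform("X", seq,
                     site_mods=(SiteMod(0, mod_delta("acetyl"), False),))
    out = localize_mods(hyp, {"acetyl": [5, 10, 15]}, _planted_obs(truth))
    assert out[0].status == "localized" and out[0].sites == (10,)


def test_localize_intact_shift_only():
    # shift present on the intact mass, but no fragments at all
    hyp = Proteoform("X", "KAAAAAAAAA",
                     site_mods=(SiteMod(0, mod_delta("methyl"), False),))
    out = localize_mods(hyp, {"methyl": [1]}, [])
    assert out[0].status == "not_localized"


def test_localize_ambiguous_pair_reported():
    # only b4 (unshifted) and b15 (shifted) bracket the modification between
    # bonds 4 and 15; candidates 8 and 12 both survive: report the set
    seq = "AAAAAAAKAAAKAAAAAAAA"
    truth = Proteoform("X", seq, site_mods=(SiteMod(8, mod_delta("acetyl")),))
    lad = {f.name: f.neutral_mass for f in generate_by_ladder(truth)}
    obs = [lad["b4"], lad["b15"]]
    hyp = Proteoform("X", seq,
                     site_mods=(SiteMod(0, mod_delta("acetyl"), False),))
    out = localize_mods(hyp, {"acetyl": [8, 12]}, obs)
    assert out[0].status == "ambiguous"
    assert set(out[0].sites) == {8, 12}


def test_localize_two_copies_of_one_modification():
    seq = "AANAAAAAAAAANAAAAAAA"  # N3 and N13
    truth = Proteoform("X", seq, site_mods=(
        SiteMod(3, mod_delta("deamidation")), SiteMod(13, mod_delta("deamidation"))))
    hyp = Proteoform("X", seq, site_mods=(
        SiteMod(0, mod_delta("deamidation"), False),
        SiteMod(0, mod_delta("deamidation"), False)))
    out = localize_mods(hyp, {"deamidation": [3, 13]}, _planted_obs(truth),
                        tol_ppm=5)
    assert out[0].status == "localized"
    assert out[0].sites == (3, 13)


def test_localization_exact_on_random_planted_cases(rng):
    # complete ladders + a single planted modification: always the exact site
    hits = 0
    cases = 0
    while cases < 100:
        p = random_proteoform(rng, min_len=12, max_len=30, p_mod=0.0)
        ks = [i + 1 for i, aa in enumerate(p.base_sequence) if aa == "K"]
        if not ks:
            continue
        cases += 1
        site = int(rng.choice(ks))
        truth = Proteoform(p.protein_id, p.base_sequence, p.nterm_mod,
                           site_mods=(SiteMod(site, mod_delta("acetyl")),))
        hyp = Proteoform(p.protein_id, p.base_sequence, p.nterm_mod,
                         site_mods=(SiteMod(0, mod_delta("acetyl"), False),))
        out = localize_mods(hyp, {"acetyl": ks}, _planted_obs(truth))
        if out[0].status == "localized" and out[0].sites == (site,):
            hits += 1
    assert hits == cases


# ---------------------------------------------------------------------------
# Characterization levels
# ---------------------------------------------------------------------------


def _result(**kw):
    defaults = dict(proteoform=Proteoform("X", "AAAA"), matches=[],
                    p_score=1e-9, coverage=0.9, localization=[])
    defaults.update(kw)
    return CharacterizationResult(**defaults)


def test_characterization_level_table():
    from ntdp.fragments import LocalizationStatus
    assert characterization_level(_result()) == "1"
    r = _result(localization=[LocalizationStatus("methyl", "not_localized", ())])
    assert characterization_level(r) == "2A"
    assert characterization_level(_result(ambiguous_candidates=True)) == "2B"
    assert characterization_level(_result(mods_uncertain=True)) == "3"
    assert characterization_level(_result(p_score=0.5)) == "4"
    assert characterization_level(_result(protein_only=True)) == "4"
    assert characterization_level(_result(mass_only=True)) == "5"


# ---------------------------------------------------------------------------
# Metal localization
# ---------------------------------------------------------------------------


def _fm(series, idx, metals=()):
    return FragmentMatch(FragmentIon(series, idx, 0.0, tuple(metals)), 0.0, 0.0)


def test_metal_interval_from_holo_and_apo_ions():
    # apo b through b50, holo b from b144: interval [51, 144]
    apo = [_fm("b", i) for i in range(1, 51)]
    holo = [_fm("b", i, (("Cu", 1),)) for i in range(144, 153)]
    out = metal_localization(apo, holo, 160)
    assert out["Cu"].interval == (51, 144)
    assert 120 in range(*out["Cu"].interval)  # contains the deepest site


def test_metal_unlocalized_without_holo_ions():
    out = metal_localization([_fm("b", 5)], [], 100)
    assert out == {}


def test_metal_contradiction_flagged():
    out = metal_localization([_fm("b", 20)], [_fm("b", 10, (("Cu", 1),))], 100)
    assert not out["Cu"].consistent
    assert out["Cu"].interval is None


def test_metal_interval_contains_planted_sites_noise_free():
    from ntdp.pipeline import identify
    from ntdp.search import expand_search_space
    from ntdp.simulate import SOD1_CU_SITES, SOD1_ZN_SITES, simulate_run, sod1_like_spec

    spec, cfg = sod1_like_spec(
        seed=2, mz_noise_sigma=0.0, intensity_noise_sigma=0.0,
        decoy_rate=0.0, fragment_detectability=1.0)
    spectra, _ = simulate_run(spec)
    bundle = identify(spectra, expand_search_space(cfg))
    intervals = bundle.results[0].metal_intervals
    for metal, sites in (("Cu", SOD1_CU_SITES), ("Zn", SOD1_ZN_SITES)):
        lo, hi = intervals[metal].interval
        assert all(lo <= s <= hi for s in sites)


# ---------------------------------------------------------------------------
# Coverage maps
# ---------------------------------------------------------------------------


def test_full_ladder_coverage_is_one():
    p = Proteoform("X", "PEPTIDEK")
    theo = generate_by_ladder(p)
    matches = match_fragments(theo, [f.neutral_mass for f in theo])
    fmap = coverage_and_map(p, matches)
    assert fmap.coverage == 1.0
    assert "coverage: 1.000" in fmap.to_text()


def test_half_ladder_coverage():
    p = Proteoform("X", "A" * 21)  # 20 bonds
    theo = [f for f in generate_by_ladder(p)
            if f.series == "b" and f.index <= 10]
    matches = match_fragments(theo, [f.neutral_mass for f in theo])
    fmap = coverage_and_map(p, matches)
    assert fmap.coverage == pytest.approx(0.5)


def test_disulfide_bonds_excluded_from_denominator():
    seq = "AAC" + "A" * 3 + "C" + "AA"
    p = Proteoform("X", seq, disulfides=((3, 7),))
    theo = generate_by_ladder(p)
    matches = match_fragments(theo, [f.neutral_mass for f in theo])
    assert coverage_and_map(p, matches).coverage == 1.0
    # counting the shielded bonds drops coverage below 1
    assert coverage_and_map(p, matches,
                            exclude_disulfide_bonds=False).coverage < 1.0
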