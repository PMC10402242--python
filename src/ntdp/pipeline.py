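"""End-to-end identification pipeline: native MS1 deconvolution ->
complexoform candidate search -> MS2 subunit-ejection mass accounting ->
MS3 proteoform characterization (P-score, coverage, PTM localization,
confidence level) -> metal localization -> reports.

Subunit-ejection evidence does real work here: complexoform candidates that
distribute the same modification total differently across subunits are
exactly isobaric at the complex level, so candidates are re-ranked by how
many of their distinct subunit masses are observed as ejected monomers or
complementary remnants in MS2 — the arrangement evidence the MS^n cascade
exists to provide. All candidates within tolerance are reported with ranks;
there is no silent winner-takes-all.
"""

from __future__ import annotations

import itertools
import logging
import os
from collections import Counter
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .chem import metal_adduct_delta
from .deconv import ChargeSeries, deconvolve_series, neutral_mass
from .fragments import (
    CharacterizationResult,
    MetalInterval,
    characterization_level,
    characterize,
    metal_localization,
)
from .proteoform import (
    Complexoform,
    Proteoform,
    StoichiometryRecord,
    proteoform_mass,
    serialize_proteoform,
)
from .search import (
    ComplexMatch,
    SearchSpace,
    classify_tier,
    enumerate_candidates,
    expand_search_space,
    match_report,
)
from .spectra import Spectrum, link_hierarchy, read_mzml, read_peaklist

logger = logging.getLogger("ntdp")

__all__ = [
    "RunConfig",
    "IdentificationResult",
    "ResultBundle",
    "run_pipeline",
    "identify",
    "differential_table",
    "report",
]


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through YAML."""

    input_paths: List[str]
    space_path: str
    complex_tol_da: float = 1.0
    subunit_tol_da: float = 1.0
    fragment_tol_ppm: float = 10.0
    alpha: float = 1e-4
    isotope_validation: bool = False
    output_dir: str = "ntdp_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("complex_tol_da", "subunit_tol_da", "fragment_tol_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not self.input_paths:
            raise ValueError("no input paths given")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RankedMatch:
    match: ComplexMatch
    ms2_support: int  # distinct subunit masses seen as MS2 products
    n_distinct_subunits: int
    ms3_support: int = 0  # subunits confirmed by MS3 characterization
    rank: int = 0


def _mod_signature(p: Proteoform) -> tuple:
    """Identity of a proteoform at the modification-multiset level (ignores
    whether the modifications are localized)."""
    mods = Counter(sm.delta.name for sm in p.site_mods)
    if p.nterm_mod:
        mods[f"nterm:{p.nterm_mod.name}"] += 1
    if p.cterm_mod:
        mods[f"cterm:{p.cterm_mod.name}"] += 1
    return (p.protein_id, p.base_sequence, frozenset(mods.items()))


@dataclass
class IdentificationResult:
    """One identified native species (one MS1 charge series)."""

    ms1_spectrum_id: str
    series: ChargeSeries
    candidates: List[RankedMatch]
    subunit_results: Dict[str, CharacterizationResult] = field(default_factory=dict)
    metal_intervals: Dict[str, MetalInterval] = field(default_factory=dict)
    tier: str = "observed_mass_only"
    note: str = ""
    #: labels of candidates near-isobaric with the best (incl. the best) —
    #: reported as a set, never silently resolved
    ambiguity_group: List[str] = field(default_factory=list)
    level_override: Optional[str] = None

    @property
    def best(self) -> Optional[RankedMatch]:
        return self.candidates[0] if self.candidates else None

    @property
    def level(self) -> Optional[str]:
        if self.level_override is not None:
            return self.level_override
        if not self.subunit_results:
            return None
        order = {"1": 0, "2A": 1, "2B": 2, "3": 3, "4": 4, "5": 5}
        return max((r.level for r in self.subunit_results.values() if r.level),
                   key=lambda lv: order[lv], default=None)


@dataclass
class ResultBundle:
    results: List[IdentificationResult]
    leftovers: Dict[str, List] = field(default_factory=dict)
    config: Optional[RunConfig] = None

    def by_label(self) -> Dict[str, IdentificationResult]:
        out = {}
        for r in self.results:
            if r.best is not None:
                out[r.best.match.label] = r
        return out


# ---------------------------------------------------------------------------
# MS2 product mass accounting
# ---------------------------------------------------------------------------


def ms2_product_masses(
    spectrum: Spectrum,
    precursor_mass: float,
    precursor_charge: int,
    tol_da: float,
) -> List[Tuple[float, int]]:
    """Neutral (mass, charge) of MS2 dissociation products, found by requiring
    that a product pair's masses sum to the precursor mass (within tol) while
    their charges sum to the precursor charge."""
    peaks = spectrum.peaks
    out: Dict[Tuple[int, int], Tuple[float, int]] = {}
    for i, pi in enumerate(peaks):
        for j, pj in enumerate(peaks):
            if i == j:
                continue
            for z_i in range(1, precursor_charge):
                z_j = precursor_charge - z_i
                m_i = neutral_mass(pi.mz, z_i)
                m_j = neutral_mass(pj.mz, z_j)
                if m_i <= 0 or m_j <= 0:
                    continue
                if abs(m_i + m_j - precursor_mass) <= tol_da:
                    out[(i, z_i)] = (m_i, z_i)
                    out[(j, z_j)] = (m_j, z_j)
    return sorted(set(out.values()))


def _subunit_support(match: ComplexMatch, product_masses: Sequence[float],
                     tol_da: float) -> Tuple[int, int]:
    """How many of a candidate's distinct subunit masses (with or without the
    complex's metals riding along) appear among MS2 product masses."""
    distinct: Dict[tuple, float] = {}
    for p in match.complexoform.subunits:
        distinct[p.mass_key()] = proteoform_mass(p)[0]
    metal_delta = sum(metal_adduct_delta(m) * k for m, k in match.complexoform.metals)
    supported = 0
    for mass_ in distinct.values():
        hit = any(abs(mass_ - om) <= tol_da or
                  (metal_delta and abs(mass_ + metal_delta - om) <= tol_da)
                  for om in product_masses)
        supported += hit
    return supported, len(distinct)


# ---------------------------------------------------------------------------
# Identification
# ---------------------------------------------------------------------------


def _refine_localized(p: Proteoform, res: CharacterizationResult
                      ) -> Optional[Proteoform]:
    """If localization placed every copy of some unlocalized modification,
    return the proteoform with those copies pinned to their sites (so its
    ladder gains the shifted fragments); None when nothing was placed."""
    from .proteoform import SiteMod

    placed = {ls.mod: ls.sites for ls in res.localization
              if ls.status == "localized"}
    if not placed:
        return None
    new_mods = []
    consumed: Counter = Counter()
    for sm in p.site_mods:
        name = sm.delta.name
        if not sm.localized and name in placed:
            sites = placed[name]
            if consumed[name] < len(sites):
                pos = sites[consumed[name]]
                consumed[name] += 1
                new_mods.append(SiteMod(pos, sm.delta, True))
                continue
        new_mods.append(sm)
    try:
        return Proteoform(p.protein_id, p.base_sequence, p.nterm_mod,
                          p.cterm_mod, tuple(new_mods), p.disulfides,
                          p.truncation)
    except ValueError:
        return None  # placement incompatible with residue targets


def _ms3_candidates(space: SearchSpace, monomer_mass: float, tol_da: float
                    ) -> List[Tuple[Proteoform, Dict[str, int]]]:
    """Proteoform (+ retained metal multiset) hypotheses for an isolated
    ejected monomer of the given neutral mass."""
    out = []
    metal_options: List[Dict[str, int]] = [{}]
    syms = sorted(space.metal_max)
    for counts in itertools.product(*(range(space.metal_max[s] + 1) for s in syms)):
        d = {s: k for s, k in zip(syms, counts) if k}
        if d:
            metal_options.append(d)
    for p in space.proteoforms:
        base = proteoform_mass(p)[0]
        for metals in metal_options:
            delta = sum(metal_adduct_delta(m) * k for m, k in metals.items())
            if abs(base + delta - monomer_mass) <= tol_da:
                out.append((p, metals))
    return out


def identify(
    spectra: Sequence[Spectrum],
    space: SearchSpace,
    complex_tol_da: float = 1.0,
    subunit_tol_da: float = 1.0,
    fragment_tol_ppm: float = 10.0,
    alpha: float = 1e-4,
) -> ResultBundle:
    """Run the full MS1 -> MS2 -> MS3 identification cascade."""
    tree = link_hierarchy(spectra)
    results: List[IdentificationResult] = []
    leftovers: Dict[str, List] = {}
    for root_id in tree.roots:
        root = tree.spectra[root_id]
        series_list, left = deconvolve_series(root.peaks)
        if left:
            leftovers[root_id] = left
        ms2_children = [c for c in tree.children_of(root_id) if c.ms_level == 2]
        for series in series_list:
            obs_mass = series.neutral_mass
            matches = enumerate_candidates(space, obs_mass, complex_tol_da)
            # MS2 spectra whose isolation window covers this series
            my_ms2 = []
            for c in ms2_children:
                pc = c.precursor
                if pc.isolation_mz is None:
                    continue
                width = pc.isolation_width or 4.0
                if any(abs(p.mz - pc.isolation_mz) <= width / 2 + 1e-6
                       for p in series.peaks):
                    my_ms2.append(c)
            product_masses: List[float] = []
            ms3_specs: List[Spectrum] = []
            for c in my_ms2:
                z = c.precursor.charge
                if z is None and c.precursor.isolation_mz is not None:
                    # recover charge from the matching series peak
                    for p, zz in zip(series.peaks, series.charges):
                        if abs(p.mz - c.precursor.isolation_mz) <= (c.precursor.isolation_width or 4.0) / 2:
                            z = zz
                            break
                if z is None:
                    continue
                product_masses.extend(
                    m for m, _ in ms2_product_masses(c, obs_mass, z, subunit_tol_da))
                ms3_specs.extend(s for s in tree.children_of(c.id) if s.ms_level == 3)
            # MS3 characterization of ejected monomers (done before complex
            # ranking: a characterized subunit proteoform is arrangement
            # evidence that breaks complex-level isobaric ties)
            subunit_results: Dict[str, CharacterizationResult] = {}
            metal_intervals: Dict[str, MetalInterval] = {}
            characterized_sigs: set = set()
            for ms3 in ms3_specs:
                pc = ms3.precursor
                if pc.isolation_mz is None or pc.charge is None:
                    logger.warning("MS3 %s lacks isolation/charge; skipped", ms3.id)
                    continue
                mono_mass = neutral_mass(pc.isolation_mz, pc.charge)
                observed = [neutral_mass(p.mz, 1) for p in ms3.peaks]
                cands = _ms3_candidates(space, mono_mass, subunit_tol_da)
                best: Optional[Tuple[float, float, CharacterizationResult,
                                     Proteoform, Dict[str, int]]] = None
                for p, metals in cands:
                    delta = sum(metal_adduct_delta(m) * k
                                for m, k in metals.items())
                    mass_err = abs(proteoform_mass(p)[0] + delta - mono_mass)
                    res = characterize(
                        p, observed, tol_ppm=fragment_tol_ppm, alpha=alpha,
                        metals=metals or None)
                    refined = _refine_localized(p, res)
                    if refined is not None:
                        res2 = characterize(
                            refined, observed, tol_ppm=fragment_tol_ppm,
                            alpha=alpha, metals=metals or None)
                        res2.localization = res.localization
                        if res2.p_score <= res.p_score:
                            res, p = res2, refined
                            res.level = characterization_level(res, alpha)
                    key = (res.p_score, mass_err)
                    if best is None or key < best[:2]:
                        best = (res.p_score, mass_err, res, p, metals)
                if best is not None:
                    _, _, best_result, best_p, best_metals = best
                    subunit_results[serialize_proteoform(best_p)] = best_result
                    if best_result.p_score <= alpha:
                        characterized_sigs.add(_mod_signature(best_p))
                    if best_metals:
                        apo = [m for m in best_result.matches
                               if not m.fragment.metal_content]
                        holo = [m for m in best_result.matches
                                if m.fragment.metal_content]
                        for metal, mi in metal_localization(
                                apo, holo, best_result.proteoform.length).items():
                            metal_intervals[metal] = mi

            ranked = []
            for m in matches:
                sup, n_dist = _subunit_support(m, product_masses, subunit_tol_da)
                sigs = {_mod_signature(p) for p in m.complexoform.subunits}
                ms3_sup = sum(1 for s in sigs if s in characterized_sigs)
                ranked.append(RankedMatch(m, sup, n_dist, ms3_sup))
            ranked.sort(key=lambda r: (
                -(r.ms2_support / r.n_distinct_subunits if r.n_distinct_subunits else 0),
                -r.ms3_support,
                abs(r.match.error_da), r.match.n_mods, r.match.n_metals,
                r.match.label))
            for i, r in enumerate(ranked, start=1):
                r.rank = i
            ambiguity_group: List[str] = []
            if ranked:
                top = ranked[0]
                ambiguity_group = [
                    r.match.label for r in ranked
                    if abs(r.match.theo_mass - top.match.theo_mass) <= 0.05
                    and r.ms2_support == top.ms2_support
                    and r.ms3_support == top.ms3_support
                ]
            pscores = [r.p_score for r in subunit_results.values()]
            tier = classify_tier(ranked[0].match if ranked else None, pscores, alpha)
            note = ""
            level_override = None
            if ranked and not ms3_specs and my_ms2:
                note = ("identification based on the mass shift of the MS2 "
                        "spectra; no MS3 fragment evidence")
                if ranked[0].match.n_mods:
                    # modifications identified by mass shift, nothing localized
                    level_override = "2A"
            results.append(IdentificationResult(
                ms1_spectrum_id=root_id,
                series=series,
                candidates=ranked,
                subunit_results=subunit_results,
                metal_intervals=metal_intervals,
                tier=tier,
                note=note,
                ambiguity_group=ambiguity_group,
                level_override=level_override,
            ))
    results.sort(key=lambda r: -r.series.total_intensity)
    return ResultBundle(results, leftovers)


def _read_inputs(paths: Sequence[str]) -> List[Spectrum]:
    spectra: List[Spectrum] = []
    for path in paths:
        if path.endswith(".mzML") or path.endswith(".mzml"):
            spectra.extend(read_mzml(path))
        else:
            spectra.extend(read_peaklist(path))
    return spectra


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Load inputs, expand the search space and identify; stage failures are
    logged and the pipeline continues with remaining items."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    space = expand_search_space(config.space_path)
    spectra = _read_inputs(config.input_paths)
    if not spectra:
        return ResultBundle([], {}, config)
    bundle = identify(
        spectra, space,
        complex_tol_da=config.complex_tol_da,
        subunit_tol_da=config.subunit_tol_da,
        fragment_tol_ppm=config.fragment_tol_ppm,
        alpha=config.alpha,
    )
    bundle.config = config
    return bundle


# ---------------------------------------------------------------------------
# Differential comparison and reports
# ---------------------------------------------------------------------------


def differential_table(
    bundle_a: ResultBundle,
    bundle_b: ResultBundle,
    names: Tuple[str, str] = ("run_a", "run_b"),
    mass_tol_da: float = 1.0,
) -> List[dict]:
    """Presence/absence and intensity ratio per complexoform across two runs
    (e.g. two cell states). Species are aligned by best-candidate label, with
    an observed-mass fallback for mass-only species."""
    a_by = bundle_a.by_label()
    b_by = bundle_b.by_label()
    rows = []
    for label in sorted(set(a_by) | set(b_by)):
        ra, rb = a_by.get(label), b_by.get(label)
        ia = ra.series.total_intensity if ra else 0.0
        ib = rb.series.total_intensity if rb else 0.0
        rows.append({
            "complexoform": label,
            f"present_{names[0]}": ra is not None,
            f"present_{names[1]}": rb is not None,
            f"intensity_{names[0]}": ia,
            f"intensity_{names[1]}": ib,
            "ratio": (ib / ia) if ia > 0 else (float("inf") if ib > 0 else 0.0),
        })
    return rows


def report(bundle: ResultBundle, out_dir: str) -> Dict[str, str]:
    """Write TSV tables, text fragment maps and a summary; returns the paths."""
    from .fragments import coverage_and_map

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    cx_path = os.path.join(out_dir, "complexoforms.tsv")
    with open(cx_path, "w") as fh:
        fh.write("ms1_spectrum\tobs_mass\trank\tlabel\ttheo_mass\terror_da"
                 "\tms2_support\ttier\tlevel\tnote\n")
        for r in bundle.results:
            if not r.candidates:
                fh.write(f"{r.ms1_spectrum_id}\t{r.series.neutral_mass:.4f}"
                         f"\t-\t-\t-\t-\t-\t{r.tier}\t-\t{r.note}\n")
            for rm in r.candidates:
                fh.write("\t".join([
                    r.ms1_spectrum_id, f"{r.series.neutral_mass:.4f}",
                    str(rm.rank), rm.match.label, f"{rm.match.theo_mass:.4f}",
                    f"{rm.match.error_da:+.4f}",
                    f"{rm.ms2_support}/{rm.n_distinct_subunits}",
                    r.tier, r.level or "-", r.note,
                ]) + "\n")
    paths["complexoforms"] = cx_path

    pf_path = os.path.join(out_dir, "proteoforms.tsv")
    with open(pf_path, "w") as fh:
        fh.write("proteoform\tp_score\tcoverage\tlevel\tlocalization\n")
        for r in bundle.results:
            for key, res in r.subunit_results.items():
                loc = ";".join(f"{ls.mod}:{ls.status}:{','.join(map(str, ls.sites))}"
                               for ls in res.localization) or "-"
                fh.write(f"{key}\t{res.p_score:.3e}\t{res.coverage:.3f}"
                         f"\t{res.level}\t{loc}\n")
    paths["proteoforms"] = pf_path

    maps_dir = os.path.join(out_dir, "maps")
    os.makedirs(maps_dir, exist_ok=True)
    for r in bundle.results:
        for i, (key, res) in enumerate(r.subunit_results.items()):
            fmap = coverage_and_map(res.proteoform, res.matches)
            fname = os.path.join(maps_dir, f"{r.ms1_spectrum_id}_sub{i}.map.txt")
            with open(fname, "w") as fh:
                fh.write(f"# {key}\n{fmap.to_text()}\n")
    paths["maps"] = maps_dir

    level_counts = Counter()
    for r in bundle.results:
        for res in r.subunit_results.values():
            level_counts[res.level] += 1
    tier_counts = Counter(r.tier for r in bundle.results)
    summary_path = os.path.join(out_dir, "summary.txt")
    with open(summary_path, "w") as fh:
        fh.write(f"identified species: {len(bundle.results)}\n")
        for tier, n in sorted(tier_counts.items()):
            fh.write(f"tier {tier}: {n}\n")
        for level, n in sorted(level_counts.items()):
            fh.write(f"characterization level {level}: {n}\n")
    paths["summary"] = summary_path
    return paths
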