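"""MS2/MS3 fragment evidence: HCD b/y ladders, fragment matching, the Poisson
P-score, PTM localization by bracketing fragments, the five-level
characterization-confidence taxonomy, and holo/apo metal-site inference.

Only b and y series are generated (HCD chemistry). Matching operates in
neutral monoisotopic mass space — observed fragment masses are assumed
decharged/deisotoped upstream — with a ppm tolerance (default 10, the
Orbitrap norm).

Disulfides: cleavage sites strictly inside an intact disulfide loop yield no
separable b/y pair, so those ions are excluded by default; fragments whose
span covers a whole bridge carry its -2.01565 Da. A ``reduced`` mode ignores
disulfides.

Metals: retention during HCD is modeled all-or-none per fragment — a holo
fragment carries the metal's full adduct delta, an apo fragment none.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as _stats

from .chem import ANYWHERE, metal_adduct_delta, mod_delta
from .proteoform import (
    DISULFIDE_MONO,
    Proteoform,
    SiteMod,
    WATER_MONO,
    proteoform_mass,
    residue_mono_mass,
)

__all__ = [
    "FragmentIon",
    "FragmentMatch",
    "CharacterizationResult",
    "generate_by_ladder",
    "match_fragments",
    "p_score",
    "localize_mods",
    "characterization_level",
    "metal_localization",
    "coverage_and_map",
    "characterize",
]

MetalContent = Tuple[Tuple[str, int], ...]


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    index: int  # ordinal: b144 has index 144
    neutral_mass: float
    metal_content: MetalContent = ()
    charge: Optional[int] = None

    @property
    def name(self) -> str:
        metals = "".join(f"+{m}" * k for m, k in self.metal_content)
        return f"{self.series}{self.index}{metals}"

    def span(self, n: int) -> Tuple[int, int]:
        """1-based residue span covered by this fragment on a length-n chain."""
        if self.series == "b":
            return (1, self.index)
        return (n - self.index + 1, n)


@dataclass(frozen=True)
class FragmentMatch:
    fragment: FragmentIon
    observed_mass: float
    ppm_error: float


def _excluded_sites(p: Proteoform, reduced: bool) -> Set[int]:
    """Cleavage sites (1-based: site k is between residues k and k+1) strictly
    inside an intact disulfide loop."""
    if reduced:
        return set()
    out: Set[int] = set()
    for i, j in p.disulfides:
        out.update(range(i, j))
    return out


def _metal_submultisets(metals: Mapping[str, int], cap: int
                        ) -> List[MetalContent]:
    """Non-empty submultisets of the allowed metals, up to ``cap`` total."""
    import itertools
    syms = sorted(metals)
    out: List[MetalContent] = []
    for counts in itertools.product(*(range(metals[s] + 1) for s in syms)):
        total = sum(counts)
        if 0 < total <= cap:
            out.append(tuple((s, k) for s, k in zip(syms, counts) if k))
    return out


def generate_by_ladder(
    p: Proteoform,
    metals: Optional[Mapping[str, int]] = None,
    max_holo_metals: int = 2,
    reduced: bool = False,
) -> List[FragmentIon]:
    """Theoretical neutral b/y fragment ions of a proteoform.

    b_i = sum(residues 1..i) + N-terminal mod + site mods at positions <= i;
    y_j = sum(last j residues) + H2O + C-terminal mod + site mods in the span.
    Unlocalized (ANYWHERE) site mods shift only the intact mass, never a
    fragment. When ``metals`` is given, each fragment is additionally emitted
    in holo forms carrying every allowed non-empty metal submultiset of size
    <= ``max_holo_metals``.
    """
    seq = p.base_sequence
    n = len(seq)
    excluded = _excluded_sites(p, reduced)
    nterm = p.nterm_mod.mono_mass if p.nterm_mod else 0.0
    cterm = p.cterm_mod.mono_mass if p.cterm_mod else 0.0
    shifts = np.zeros(n + 1)
    for sm in p.site_mods:
        if sm.position != ANYWHERE:
            shifts[sm.position] += sm.delta.mono_mass
    prefix_mod = np.cumsum(shifts)  # prefix_mod[i] = sum of site mods at pos <= i
    total_mod = prefix_mod[n]
    prefix_res = np.concatenate([[0.0], np.cumsum([residue_mono_mass(a) for a in seq])])
    # disulfide contribution to a prefix 1..i: bridges wholly inside the span
    def ss_delta_prefix(i: int) -> float:
        if reduced:
            return 0.0
        return DISULFIDE_MONO * sum(1 for a, b in p.disulfides if b <= i)

    def ss_delta_suffix(start: int) -> float:
        if reduced:
            return 0.0
        return DISULFIDE_MONO * sum(1 for a, b in p.disulfides if a >= start)

    holo_sets = _metal_submultisets(metals, max_holo_metals) if metals else []
    out: List[FragmentIon] = []
    for i in range(1, n):
        if i in excluded:
            continue
        b_mass = prefix_res[i] + nterm + prefix_mod[i] + ss_delta_prefix(i)
        y_idx = n - i
        y_mass = ((prefix_res[n] - prefix_res[i]) + WATER_MONO + cterm
                  + (total_mod - prefix_mod[i]) + ss_delta_suffix(i + 1))
        for series, idx, mass_ in (("b", i, b_mass), ("y", y_idx, y_mass)):
            out.append(FragmentIon(series, idx, mass_))
            for ms in holo_sets:
                delta = sum(metal_adduct_delta(m) * k for m, k in ms)
                out.append(FragmentIon(series, idx, mass_ + delta, ms))
    return out


def match_fragments(
    theoretical: Sequence[FragmentIon],
    observed_masses: Sequence[float],
    tol_ppm: float = 10.0,
) -> List[FragmentMatch]:
    """One-to-one greedy matching of observed neutral masses to theoretical
    fragments, by ascending |ppm error|; on exact ties an apo fragment is
    preferred over a holo one."""
    pairs: List[Tuple[float, int, int]] = []
    theo = sorted(theoretical, key=lambda f: f.neutral_mass)
    tmasses = [f.neutral_mass for f in theo]
    import bisect
    for oi, om in enumerate(observed_masses):
        tol = tol_ppm * 1e-6 * om
        lo = bisect.bisect_left(tmasses, om - tol)
        hi = bisect.bisect_right(tmasses, om + tol)
        for ti in range(lo, hi):
            ppm = (om - tmasses[ti]) / tmasses[ti] * 1e6
            pairs.append((abs(ppm), ti, oi))
    pairs.sort(key=lambda t: (t[0], len(theo[t[1]].metal_content), theo[t[1]].name))
    used_t: Set[int] = set()
    used_o: Set[int] = set()
    out: List[FragmentMatch] = []
    for _, ti, oi in pairs:
        if ti in used_t or oi in used_o:
            continue
        used_t.add(ti)
        used_o.add(oi)
        om = observed_masses[oi]
        out.append(FragmentMatch(theo[ti], om,
                                 (om - theo[ti].neutral_mass) / theo[ti].neutral_mass * 1e6))
    out.sort(key=lambda m: (m.fragment.series, m.fragment.index))
    return out


def p_score(
    n_matched: int,
    n_observed: int,
    theoretical_masses: Sequence[float],
    tol_ppm: float,
    mass_window: Tuple[float, float],
) -> float:
    """Probability of >= ``n_matched`` fragment matches arising by chance.

    Null model: each observed mass is placed uniformly over ``mass_window``;
    it hits some theoretical acceptance window with probability
    q = min(1, sum_f 2 * tol_ppm * 1e-6 * mass_f / |window|) (windows summed
    without overlap correction). The score is the Poisson tail
    P(X >= n_matched) with lambda = n_observed * q. Lower is more confident.
    """
    lo, hi = mass_window
    if hi <= lo:
        raise ValueError("mass window must have positive width")
    if n_matched > min(n_observed, len(theoretical_masses)):
        raise ValueError("n_matched exceeds the observed/theoretical counts")
    if n_matched == 0:
        return 1.0
    q = min(1.0, sum(2.0 * tol_ppm * 1e-6 * m for m in theoretical_masses) / (hi - lo))
    lam = n_observed * q
    return float(_stats.poisson.sf(n_matched - 1, lam))


# ---------------------------------------------------------------------------
# PTM localization
# ---------------------------------------------------------------------------


@dataclass
class LocalizationStatus:
    """Outcome for one unlocalized modification."""

    mod: str
    status: str  # 'localized' | 'ambiguous' | 'not_localized' | 'inconsistent'
    sites: Tuple[int, ...] = ()  # localized site, or the ambiguous candidate set


def localize_mods(
    p: Proteoform,
    candidate_sites: Mapping[str, Sequence[int]],
    observed_masses: Sequence[float],
    tol_ppm: float = 10.0,
    reduced: bool = False,
) -> List[LocalizationStatus]:
    """Place unlocalized modifications using bracketing fragment evidence.

    For each unlocalized modification (one copy each), every backbone cleavage
    site is classified as *shifted* (a matched b/y fragment on that side
    carries the modification mass) or *unshifted*. A site ``s`` is localized
    iff the matched fragments bracket it: fragments spanning ``s`` carry the
    shift while fragments stopping at the adjacent cleavage before ``s`` do
    not. Candidate sites that survive bracketing but cannot be separated are
    reported as an ambiguous set; no arbitrary choice is made.
    """
    n = p.length
    localized_only = Proteoform(
        p.protein_id, p.base_sequence, p.nterm_mod, p.cterm_mod,
        tuple(sm for sm in p.site_mods if sm.localized),
        p.disulfides, p.truncation,
    )
    base_ladder = generate_by_ladder(localized_only, reduced=reduced)
    base_b = {f.index: f.neutral_mass for f in base_ladder if f.series == "b"}
    base_y = {f.index: f.neutral_mass for f in base_ladder if f.series == "y"}
    obs = np.sort(np.asarray(observed_masses, dtype=float))

    def seen(mass_: float) -> bool:
        if len(obs) == 0:
            return False
        tol = tol_ppm * 1e-6 * mass_
        i = np.searchsorted(obs, mass_)
        for j in (i - 1, i):
            if 0 <= j < len(obs) and abs(obs[j] - mass_) <= tol:
                return True
        return False

    unloc = [sm for sm in p.site_mods if not sm.localized]
    results: List[LocalizationStatus] = []
    by_name = Counter(sm.delta.name for sm in unloc)
    for name, count in by_name.items():
        delta = mod_delta(name).mono_mass
        cands = tuple(sorted(candidate_sites.get(name, range(1, n + 1))))
        # cumulative-count evidence: cum[k] = number of copies on residues
        # 1..k, known where exactly one shift multiple of the fragment mass is
        # observed (from b_k directly, from y_{n-k} by complement)
        cum: Dict[int, int] = {0: 0, n: count}
        conflict = False
        for k in sorted(base_b):
            js = [j for j in range(count + 1) if seen(base_b[k] + j * delta)]
            if len(js) == 1:
                if k in cum and cum[k] != js[0]:
                    conflict = True
                cum.setdefault(k, js[0])
        for j_idx in sorted(base_y):
            js = [j for j in range(count + 1) if seen(base_y[j_idx] + j * delta)]
            if len(js) == 1:
                k = n - j_idx
                val = count - js[0]
                if k in cum and cum[k] != val:
                    conflict = True
                cum.setdefault(k, val)
        ks = sorted(cum)
        monotone = all(cum[a] <= cum[b] for a, b in zip(ks, ks[1:]))
        if conflict or not monotone:
            results.append(LocalizationStatus(name, "inconsistent", ()))
            continue
        if len(ks) == 2:  # only the trivial boundaries: no fragment evidence
            results.append(LocalizationStatus(name, "not_localized", cands))
            continue
        localized: List[int] = []
        ambiguous: List[int] = []
        impossible = False
        for a, b in zip(ks, ks[1:]):
            d = cum[b] - cum[a]
            if d == 0:
                continue
            sites_in = [s for s in cands if a < s <= b]
            if len(sites_in) == d:
                localized.extend(sites_in)
            elif len(sites_in) > d:
                ambiguous.extend(sites_in)
            else:  # more copies than candidate sites in the interval
                impossible = True
        if impossible:
            results.append(LocalizationStatus(name, "inconsistent", ()))
        elif not ambiguous and len(localized) == count:
            results.append(LocalizationStatus(name, "localized", tuple(localized)))
        elif not localized and not ambiguous:
            results.append(LocalizationStatus(name, "not_localized", cands))
        else:
            results.append(LocalizationStatus(
                name, "ambiguous", tuple(sorted(set(localized + ambiguous)))))
    return results


# ---------------------------------------------------------------------------
# Characterization levels
# ---------------------------------------------------------------------------


@dataclass
class CharacterizationResult:
    proteoform: Proteoform
    matches: List[FragmentMatch]
    p_score: float
    coverage: float
    localization: List[LocalizationStatus] = field(default_factory=list)
    ambiguous_candidates: bool = False  # near-isobaric proteoform set
    mods_uncertain: bool = False  # number of modifications not pinned down
    protein_only: bool = False  # protein identified, proteoform not
    mass_only: bool = False  # intact-mass observation with no candidate
    level: Optional[str] = None
    note: Optional[str] = None

    def __post_init__(self):
        if not (0.0 <= self.p_score <= 1.0):
            raise ValueError("p_score outside [0, 1]")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage outside [0, 1]")


def characterization_level(result: CharacterizationResult,
                           alpha: float = 1e-4) -> str:
    """Five-level confidence taxonomy.

    1: significant P-score and every modification localized; 2A: significant
    P-score with >= 1 modification identified by mass shift but not localized;
    2B: significant P-score but a near-isobaric candidate set remains; 3:
    sequence identified, modifications uncertain in number; 4: protein
    identified, proteoform not; 5: mass-only observation.
    """
    if result.mass_only:
        return "5"
    if result.protein_only:
        return "4"
    if result.mods_uncertain:
        return "3"
    significant = result.p_score <= alpha
    if not significant:
        return "4"
    if result.ambiguous_candidates:
        return "2B"
    if any(ls.status != "localized" for ls in result.localization):
        return "2A"
    return "1"


# ---------------------------------------------------------------------------
# Metal localization from holo/apo fragments
# ---------------------------------------------------------------------------


@dataclass
class MetalInterval:
    metal: str
    lower: Optional[int]
    upper: Optional[int]
    consistent: bool

    @property
    def interval(self) -> Optional[Tuple[int, int]]:
        if not self.consistent or self.lower is None or self.upper is None:
            return None
        return (self.lower, self.upper)


def metal_localization(
    apo_matches: Sequence[FragmentMatch],
    holo_matches: Sequence[FragmentMatch],
    sequence_length: int,
) -> Dict[str, MetalInterval]:
    """Bound each metal's coordinating region from holo/apo fragment evidence.

    Under all-or-none retention, a holo b_i proves all coordinating residues
    lie in 1..i (upper bound = smallest holo b index); an apo-only b_j proves
    at least one coordinating residue lies past j (lower bound = largest such
    j + 1). The y series contributes symmetrically in sequence coordinates.
    The intersection is reported per metal; an empty intersection is flagged
    inconsistent (contradictory evidence)."""
    n = sequence_length
    holo_by_metal: Dict[str, List[FragmentIon]] = {}
    for m in holo_matches:
        for sym, k in m.fragment.metal_content:
            holo_by_metal.setdefault(sym, []).append(m.fragment)
    apo_b = {m.fragment.index for m in apo_matches if m.fragment.series == "b"}
    apo_y = {m.fragment.index for m in apo_matches if m.fragment.series == "y"}
    out: Dict[str, MetalInterval] = {}
    for metal, frags in holo_by_metal.items():
        holo_b = {f.index for f in frags if f.series == "b"}
        holo_y = {f.index for f in frags if f.series == "y"}
        lower, upper = 1, n
        if holo_b:
            upper = min(upper, min(holo_b))
        if holo_y:
            lower = max(lower, n - min(holo_y) + 1)
        apo_only_b = apo_b - holo_b
        if apo_only_b:
            lower = max(lower, max(apo_only_b) + 1)
        apo_only_y = apo_y - holo_y
        if apo_only_y:
            upper = min(upper, n - max(apo_only_y))
        out[metal] = MetalInterval(metal, lower, upper, lower <= upper)
    return out


# ---------------------------------------------------------------------------
# Coverage and fragment maps
# ---------------------------------------------------------------------------


@dataclass
class FragmentMap:
    proteoform: Proteoform
    b_cleaved: Set[int]
    y_cleaved: Set[int]
    holo_sites: Set[int]
    countable_sites: List[int]
    coverage: float

    def to_text(self, width: int = 40) -> str:
        """Fixed-width map: one row of sequence per line, cleavage markers
        beneath (| = b and/or y evidence at that bond, * = holo evidence)."""
        seq = self.proteoform.base_sequence
        n = len(seq)
        lines = []
        for row in range(0, n, width):
            chunk = seq[row: row + width]
            marks = []
            for k in range(row + 1, row + len(chunk) + 1):
                if k > n - 1:
                    marks.append(" ")
                elif k in self.holo_sites:
                    marks.append("*")
                elif k in self.b_cleaved or k in self.y_cleaved:
                    marks.append("|")
                else:
                    marks.append(" ")
            lines.append(f"{row + 1:>5} {chunk}")
            lines.append("      " + "".join(marks))
        lines.append(f"coverage: {self.coverage:.3f}")
        return "\n".join(lines)

    def to_tsv(self) -> str:
        lines = ["bond\tb_cleaved\ty_cleaved\tholo"]
        for k in self.countable_sites:
            lines.append(f"{k}\t{int(k in self.b_cleaved)}"
                         f"\t{int(k in self.y_cleaved)}\t{int(k in self.holo_sites)}")
        return "\n".join(lines) + "\n"


def coverage_and_map(
    proteoform: Proteoform,
    matches: Sequence[FragmentMatch],
    exclude_disulfide_bonds: bool = True,
    reduced: bool = False,
) -> FragmentMap:
    """Per-bond cleavage evidence and the coverage fraction.

    Coverage = matched backbone bonds / countable bonds. Bonds strictly
    inside an intact disulfide loop cannot produce separable b/y ions and are
    omitted from the denominator by default (configurable)."""
    n = proteoform.length
    excluded = _excluded_sites(proteoform, reduced)
    countable = [k for k in range(1, n)
                 if not (exclude_disulfide_bonds and k in excluded)]
    b_cleaved: Set[int] = set()
    y_cleaved: Set[int] = set()
    holo: Set[int] = set()
    for m in matches:
        f = m.fragment
        site = f.index if f.series == "b" else n - f.index
        if f.series == "b":
            b_cleaved.add(site)
        else:
            y_cleaved.add(site)
        if f.metal_content:
            holo.add(site)
    covered = {k for k in countable if k in b_cleaved or k in y_cleaved}
    coverage = len(covered) / len(countable) if countable else 0.0
    return FragmentMap(proteoform, b_cleaved, y_cleaved, holo, countable, coverage)


# ---------------------------------------------------------------------------
# One-stop characterization
# ---------------------------------------------------------------------------


def characterize(
    proteoform: Proteoform,
    observed_masses: Sequence[float],
    tol_ppm: float = 10.0,
    alpha: float = 1e-4,
    metals: Optional[Mapping[str, int]] = None,
    candidate_sites: Optional[Mapping[str, Sequence[int]]] = None,
    mass_window: Optional[Tuple[float, float]] = None,
    ambiguous_candidates: bool = False,
    reduced: bool = False,
) -> CharacterizationResult:
    """Match, score, localize and grade one proteoform against MS3 evidence."""
    theo = generate_by_ladder(proteoform, metals=metals, reduced=reduced)
    matches = match_fragments(theo, observed_masses, tol_ppm)
    if mass_window is None:
        if len(observed_masses):
            mass_window = (min(observed_masses) * 0.9, max(observed_masses) * 1.1)
        else:
            mass_window = (0.0, proteoform_mass(proteoform)[0])
    theo_masses = [f.neutral_mass for f in theo]
    score = p_score(len(matches), len(observed_masses), theo_masses, tol_ppm,
                    mass_window) if len(observed_masses) else 1.0
    loc = localize_mods(proteoform, candidate_sites or {}, observed_masses,
                        tol_ppm, reduced=reduced)
    fmap = coverage_and_map(proteoform, matches, reduced=reduced)
    result = CharacterizationResult(
        proteoform=proteoform,
        matches=matches,
        p_score=score,
        coverage=fmap.coverage,
        localization=loc,
        ambiguous_candidates=ambiguous_candidates,
    )
    result.level = characterization_level(result, alpha)
    return result
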