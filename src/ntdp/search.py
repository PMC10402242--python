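"""Complexoform search: enumerate candidate assemblies whose theoretical mass
matches an observed native neutral mass within a tolerance (default +/- 1 Da,
applied at the complex level to the monoisotopic theoretical mass).

The search space is the cartesian expansion of a per-protein candidate
proteoform set (base sequence x allowed truncations x allowed modification
multisets) combined with stoichiometry bounds and allowed metal multisets.
Intact mass cannot distinguish positional isomers, so candidates carry their
modifications unlocalized; localization is deferred to fragment evidence.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .chem import ANYWHERE, metal_adduct_delta, mod_delta
from .proteoform import (
    Complexoform,
    Proteoform,
    SiteMod,
    complexoform_mass,
    proteoform_mass,
    serialize_proteoform,
)

__all__ = [
    "SearchSpace",
    "ComplexMatch",
    "SearchSpaceError",
    "expand_search_space",
    "enumerate_candidates",
    "classify_tier",
    "ambiguity_sets",
    "match_report",
]


class SearchSpaceError(ValueError):
    pass


@dataclass
class SearchSpace:
    """Expanded, finite candidate space.

    ``proteoforms`` is the deduplicated, mass-sorted list of candidate
    subunits across all proteins; stoichiometry bounds cap the subunit
    multiset; ``metal_max`` caps each metal's count per complex.
    """

    proteoforms: List[Proteoform]
    min_subunits: int = 1
    max_subunits: int = 6
    per_protein_max: Dict[str, int] = field(default_factory=dict)
    metal_max: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.proteoforms = sorted(self.proteoforms,
                                  key=lambda p: (proteoform_mass(p)[0], p.mass_key()))

    @property
    def size(self) -> int:
        return len(self.proteoforms)


def _read_sequence(entry: Mapping, base_dir: str = ".") -> str:
    if "sequence" in entry:
        return entry["sequence"].strip().upper()
    if "fasta" in entry:
        import os
        from pyteomics import fasta as _fasta
        path = entry["fasta"]
        if not os.path.isabs(path):
            path = os.path.join(base_dir, path)
        wanted = entry.get("fasta_id")
        with _fasta.read(path) as records:
            for header, seq in records:
                if wanted is None or wanted in header.split()[0]:
                    return seq.strip().upper()
        raise SearchSpaceError(f"no FASTA record matching {wanted!r} in {path}")
    raise SearchSpaceError(f"protein {entry.get('id')!r}: needs sequence or fasta")


def _expand_protein(entry: Mapping, cap: int, base_dir: str) -> List[Proteoform]:
    pid = entry.get("id", "?")
    canonical = _read_sequence(entry, base_dir)
    truncations: List[Optional[Tuple[int, int]]] = [None]
    for t in entry.get("truncations", []):
        truncations.append((int(t[0]), int(t[1])))
    nterm_options: List[Optional[str]] = [None] + list(entry.get("nterm_mods", []))
    mod_specs = [(m["name"], int(m.get("max", 1))) for m in entry.get("mods", [])]
    disulfides = tuple((int(i), int(j)) for i, j in entry.get("disulfides", []))

    count_ranges = [range(k + 1) for _, k in mod_specs]
    n_combos = (len(truncations) * len(nterm_options)
                * (1 if not count_ranges else
                   math.prod(len(r) for r in count_ranges)))
    if n_combos > cap:
        raise SearchSpaceError(
            f"protein {pid!r}: {n_combos} proteoform combinations exceed the "
            f"cap of {cap}; tighten truncation/modification bounds")

    out: List[Proteoform] = []
    seen = set()
    for trunc in truncations:
        if trunc is None:
            seq, trunc_rec = canonical, None
        else:
            start, end = trunc
            if not (1 <= start <= end <= len(canonical)):
                raise SearchSpaceError(
                    f"protein {pid!r}: truncation {trunc} outside canonical sequence")
            seq, trunc_rec = canonical[start - 1: end], (start, end)
        ss = tuple((i, j) for i, j in disulfides
                   if trunc_rec is None
                   or (trunc_rec[0] <= i and j <= trunc_rec[1]))
        if trunc_rec:
            ss = tuple((i - trunc_rec[0] + 1, j - trunc_rec[0] + 1) for i, j in ss)
        for nterm in nterm_options:
            for counts in itertools.product(*count_ranges):
                site_mods = []
                for (name, _), k in zip(mod_specs, counts):
                    d = mod_delta(name)
                    site_mods.extend(SiteMod(ANYWHERE, d, False) for _ in range(k))
                try:
                    p = Proteoform(
                        protein_id=pid,
                        base_sequence=seq,
                        nterm_mod=mod_delta(nterm) if nterm else None,
                        site_mods=tuple(site_mods),
                        disulfides=ss,
                        truncation=trunc_rec,
                    )
                except ValueError as e:
                    raise SearchSpaceError(f"protein {pid!r}: {e}") from None
                key = p.mass_key()
                if key not in seen:
                    seen.add(key)
                    out.append(p)
    return out


def expand_search_space(config, cap: int = 10 ** 6, base_dir: str = ".") -> SearchSpace:
    """Expand a search-space definition (path to YAML, or an equivalent dict).

    Expansion is deterministic, duplicate-free and mass-sorted; exceeding
    ``cap`` raises :class:`SearchSpaceError` naming the offending protein.
    """
    if isinstance(config, (str, bytes)):
        import os
        base_dir = os.path.dirname(os.path.abspath(config))
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or "proteins" not in config:
        raise SearchSpaceError("search-space config must map 'proteins' to a list")
    stoich = config.get("stoichiometry", {})
    proteoforms: List[Proteoform] = []
    for entry in config["proteins"]:
        proteoforms.extend(_expand_protein(entry, cap, base_dir))
    if len(proteoforms) > cap:
        raise SearchSpaceError(
            f"expanded space has {len(proteoforms)} proteoforms, above cap {cap}")
    return SearchSpace(
        proteoforms=proteoforms,
        min_subunits=int(stoich.get("min_subunits", 1)),
        max_subunits=int(stoich.get("max_subunits", 6)),
        per_protein_max={k: int(v) for k, v in stoich.get("per_protein", {}).items()},
        metal_max={k: int(v) for k, v in config.get("metals", {}).items()},
    )


@dataclass
class ComplexMatch:
    complexoform: Complexoform
    theo_mass: float
    obs_mass: float
    error_da: float  # theoretical - observed
    tier: str = "mass_only"  # mass_and_fragments | mass_only | observed_mass_only

    @property
    def n_mods(self) -> int:
        n = 0
        for p in self.complexoform.subunits:
            n += len(p.site_mods)
            n += (p.nterm_mod is not None) + (p.cterm_mod is not None)
        return n

    @property
    def n_metals(self) -> int:
        return sum(k for _, k in self.complexoform.metals)

    @property
    def label(self) -> str:
        if self.complexoform.label:
            return self.complexoform.label
        parts = [f"{p.protein_id}:{serialize_proteoform(p)}"
                 for p in self.complexoform.subunits]
        parts += [f"{m}x{k}" for m, k in self.complexoform.metals]
        return " + ".join(parts)


def _metal_multisets(metal_max: Mapping[str, int]) -> List[Tuple[Tuple[str, int], ...]]:
    metals = sorted(metal_max)
    out = []
    for counts in itertools.product(*(range(metal_max[m] + 1) for m in metals)):
        out.append(tuple((m, k) for m, k in zip(metals, counts) if k))
    return out


def enumerate_candidates(
    space: SearchSpace,
    obs_mass: float,
    tol: float = 1.0,
    mass_type: str = "mono",
) -> List[ComplexMatch]:
    """All complexoforms in ``space`` whose theoretical mass lies within
    ``+/- tol`` Da of ``obs_mass``, ranked by |error| (ties: fewer total
    modifications, then fewer metals, then lexical label).

    Implementation: branch-and-bound depth-first enumeration over the
    mass-sorted proteoform list with residual-mass pruning, per allowed metal
    multiset. Correctness is defined by exhaustive enumeration (see the test
    suite's brute-force oracle); the algorithm is an efficiency choice.
    """
    if obs_mass <= 0:
        raise ValueError("observed mass must be positive")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    which = {"mono": 0, "average": 1}[mass_type]
    masses = [proteoform_mass(p)[which] for p in space.proteoforms]
    n = len(masses)
    results: List[ComplexMatch] = []
    max_mass = max(masses) if masses else 0.0

    for metal_set in _metal_multisets(space.metal_max):
        metal_delta = sum(metal_adduct_delta(m) * k for m, k in metal_set)
        target = obs_mass - metal_delta
        lo, hi = target - tol, target + tol

        chosen: List[int] = []
        prot_counts: Counter = Counter()

        def rec(start: int, total: float) -> None:
            count = len(chosen)
            if count >= space.min_subunits and lo <= total <= hi:
                subunits = tuple(space.proteoforms[i] for i in chosen)
                c = Complexoform(subunits, metal_set)
                theo = total + metal_delta
                results.append(ComplexMatch(c, theo, obs_mass, theo - obs_mass))
            if count == space.max_subunits:
                return
            remaining_max = space.max_subunits - count
            for j in range(start, n):
                m = masses[j]
                need_more = max(0, space.min_subunits - count - 1)
                if total + m + need_more * m > hi:
                    break  # masses ascending: no later j can fit either
                if total + m + (remaining_max - 1) * max_mass < lo:
                    continue  # cannot reach the window even maximally filled
                pid = space.proteoforms[j].protein_id
                cap = space.per_protein_max.get(pid)
                if cap is not None and prot_counts[pid] >= cap:
                    continue
                chosen.append(j)
                prot_counts[pid] += 1
                rec(j, total + m)
                chosen.pop()
                prot_counts[pid] -= 1

        rec(0, 0.0)

    # subunit-permutation duplicates are already collapsed by the non-decreasing
    # index recursion; dedupe defensively on the canonical complexoform key
    seen = set()
    unique: List[ComplexMatch] = []
    for r in results:
        key = (tuple(p.mass_key() for p in r.complexoform.subunits),
               r.complexoform.metals)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    unique.sort(key=lambda r: (abs(r.error_da), r.n_mods, r.n_metals, r.label))
    return unique


def classify_tier(
    match: Optional[ComplexMatch],
    fragment_pscores: Sequence[float] = (),
    alpha: float = 1e-4,
) -> str:
    """Evidence tier of an identification.

    ``mass_and_fragments`` when MS3 evidence links at least one subunit
    (some fragment-level P-score is significant at ``alpha``); ``mass_only``
    when a theoretical candidate exists but no fragment support does;
    ``observed_mass_only`` when no candidate exists for a recurring observed
    mass (match is None).
    """
    if match is None:
        return "observed_mass_only"
    if any(p <= alpha for p in fragment_pscores):
        return "mass_and_fragments"
    return "mass_only"


def ambiguity_sets(matches: Sequence[ComplexMatch], tol: float = 0.05
                   ) -> List[List[ComplexMatch]]:
    """Group candidates whose theoretical masses are within ``tol`` Da of one
    another (near-isobaric sets, e.g. trimethyl vs acetyl at 0.0364 Da); the
    engine reports such sets rather than picking a winner."""
    ordered = sorted(matches, key=lambda m: m.theo_mass)
    groups: List[List[ComplexMatch]] = []
    for m in ordered:
        if groups and m.theo_mass - groups[-1][-1].theo_mass <= tol:
            groups[-1].append(m)
        else:
            groups.append([m])
    return groups


def match_report(matches: Sequence[ComplexMatch]) -> str:
    """Ranked TSV of candidate matches."""
    lines = ["rank\tlabel\ttheo_mass\tobs_mass\terror_da\tn_subunits\tmetals\ttier"]
    for rank, m in enumerate(matches, start=1):
        metals = ",".join(f"{el}x{k}" for el, k in m.complexoform.metals) or "-"
        lines.append("\t".join([
            str(rank), m.label, f"{m.theo_mass:.4f}", f"{m.obs_mass:.4f}",
            f"{m.error_da:+.4f}", str(m.complexoform.oligomeric_order),
            metals, m.tier,
        ]))
    return "\n".join(lines) + "\n"
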