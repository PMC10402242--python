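"""Proteoforms and complexoforms: the data model and mass arithmetic for the
molecular species this engine identifies.

A *proteoform* is one base sequence (the processed form actually observed,
after truncation / initial-Met cleavage) plus terminal and side-chain
modifications and intra-chain disulfides. A *complexoform* is a multiset of
proteoforms plus metal cofactors — the unit of identification: complexes of
the same proteins with different proteoforms are different complexoforms.

Residue numbering is 1-based on the observed (processed) sequence; an optional
truncation record maps back to canonical coordinates.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from pyteomics import mass as _pmass

from .chem import (
    ANYWHERE,
    ElementalComposition,
    MassDelta,
    element_average_mass,
    element_mono_mass,
    metal_adduct_delta,
    mod_delta,
)

__all__ = [
    "SiteMod",
    "Proteoform",
    "Complexoform",
    "StoichiometryRecord",
    "proteoform_mass",
    "complexoform_mass",
    "parse_proteoform",
    "serialize_proteoform",
    "residue_mono_mass",
    "WATER_MONO",
]

# Residue compositions from pyteomics (20 canonical + selenocysteine U;
# ambiguity codes like B/J/X/Z are rejected).
_CANONICAL = set("ACDEFGHIKLMNPQRSTVWYU")
_AA_COMP = {aa: comp for aa, comp in _pmass.std_aa_comp.items()
            if aa in _CANONICAL}
_RES_MONO: Dict[str, float] = {}
_RES_AVG: Dict[str, float] = {}
for aa, comp in _AA_COMP.items():
    _RES_MONO[aa] = sum(element_mono_mass(e) * n for e, n in comp.items())
    _RES_AVG[aa] = sum(element_average_mass(e) * n for e, n in comp.items())

WATER_MONO = 2 * element_mono_mass("H") + element_mono_mass("O")
WATER_AVG = 2 * element_average_mass("H") + element_average_mass("O")

DISULFIDE_MONO = mod_delta("disulfide").mono_mass  # -2.01565 per bridge
DISULFIDE_AVG = mod_delta("disulfide").avg_mass


def residue_mono_mass(aa: str) -> float:
    try:
        return _RES_MONO[aa]
    except KeyError:
        raise ValueError(f"unknown residue letter {aa!r}") from None


def residue_composition(aa: str) -> ElementalComposition:
    try:
        return ElementalComposition(_AA_COMP[aa])
    except KeyError:
        raise ValueError(f"unknown residue letter {aa!r}") from None


def _as_delta(m) -> MassDelta:
    return m if isinstance(m, MassDelta) else mod_delta(m)


@dataclass(frozen=True)
class SiteMod:
    """A side-chain modification at a 1-based position on the processed
    sequence; ``position == ANYWHERE`` (0) with ``localized=False`` marks a
    modification identified by mass shift but not placed on a residue."""

    position: int
    delta: MassDelta
    localized: bool = True

    def __post_init__(self):
        if self.position == ANYWHERE and self.localized:
            raise ValueError("a localized modification needs a real position")


@dataclass(frozen=True)
class Proteoform:
    protein_id: str
    base_sequence: str
    nterm_mod: Optional[MassDelta] = None
    cterm_mod: Optional[MassDelta] = None
    site_mods: Tuple[SiteMod, ...] = ()
    disulfides: Tuple[Tuple[int, int], ...] = ()
    truncation: Optional[Tuple[int, int]] = None  # canonical (start, end), 1-based

    def __post_init__(self):
        n = len(self.base_sequence)
        if n == 0:
            raise ValueError("empty sequence")
        for aa in self.base_sequence:
            if aa not in _RES_MONO:
                raise ValueError(f"unknown residue letter {aa!r}")
        object.__setattr__(self, "site_mods", tuple(
            sm if isinstance(sm, SiteMod) else SiteMod(*sm)
            for sm in self.site_mods))
        seen = set()
        for sm in self.site_mods:
            if sm.position == ANYWHERE:
                continue
            if not (1 <= sm.position <= n):
                raise ValueError(
                    f"modification position {sm.position} outside sequence (len {n})")
            aa = self.base_sequence[sm.position - 1]
            if sm.delta.targets and aa not in sm.delta.targets:
                raise ValueError(
                    f"{sm.delta.name} does not target residue {aa}{sm.position}")
            if (sm.position, sm.delta.name) in seen:
                raise ValueError(
                    f"duplicate modification {sm.delta.name} at {sm.position}")
            seen.add((sm.position, sm.delta.name))
        object.__setattr__(self, "disulfides", tuple(
            (min(i, j), max(i, j)) for i, j in self.disulfides))
        for i, j in self.disulfides:
            for k in (i, j):
                if not (1 <= k <= n) or self.base_sequence[k - 1] != "C":
                    raise ValueError(f"disulfide partner {k} is not a cysteine")
            if i == j:
                raise ValueError("disulfide cannot pair a cysteine with itself")

    @property
    def length(self) -> int:
        return len(self.base_sequence)

    def canonical_position(self, processed_pos: int) -> int:
        """Map a 1-based processed-sequence position to canonical coordinates."""
        offset = (self.truncation[0] - 1) if self.truncation else 0
        return processed_pos + offset

    def mass_key(self) -> tuple:
        """Hashable identity used for multiset semantics in complexoforms."""
        return (
            self.protein_id,
            self.base_sequence,
            self.nterm_mod.name if self.nterm_mod else None,
            self.cterm_mod.name if self.cterm_mod else None,
            tuple(sorted((sm.position, sm.delta.name, sm.localized)
                         for sm in self.site_mods)),
            self.disulfides,
        )


def proteoform_mass(p: Proteoform) -> Tuple[float, float]:
    """Neutral (mono, average) mass: residues + H2O + modification deltas
    + one -2H per disulfide."""
    mono = sum(_RES_MONO[aa] for aa in p.base_sequence) + WATER_MONO
    avg = sum(_RES_AVG[aa] for aa in p.base_sequence) + WATER_AVG
    for d in (p.nterm_mod, p.cterm_mod):
        if d is not None:
            mono += d.mono_mass
            avg += d.avg_mass
    for sm in p.site_mods:
        mono += sm.delta.mono_mass
        avg += sm.delta.avg_mass
    mono += DISULFIDE_MONO * len(p.disulfides)
    avg += DISULFIDE_AVG * len(p.disulfides)
    return mono, avg


@dataclass(frozen=True)
class Complexoform:
    """A multiset of proteoform subunits plus metal cofactors."""

    subunits: Tuple[Proteoform, ...]
    metals: Tuple[Tuple[str, int], ...] = ()
    label: Optional[str] = None

    def __post_init__(self):
        if not self.subunits:
            raise ValueError("a complexoform needs at least one subunit")
        object.__setattr__(self, "subunits", tuple(
            sorted(self.subunits, key=lambda p: p.mass_key())))
        metals = Counter()
        for m, k in dict(self.metals).items():
            if k < 0:
                raise ValueError("negative metal count")
            if k:
                metals[m] = k
        object.__setattr__(self, "metals", tuple(sorted(metals.items())))

    @property
    def oligomeric_order(self) -> int:
        return len(self.subunits)

    def metal_counter(self) -> Counter:
        return Counter(dict(self.metals))


def complexoform_mass(c: Complexoform) -> Tuple[float, float]:
    """Neutral (mono, average) mass: subunit masses + metal adduct deltas."""
    mono = avg = 0.0
    for p in c.subunits:
        pm, pa = proteoform_mass(p)
        mono += pm
        avg += pa
    for metal, k in c.metals:
        d = metal_adduct_delta(metal)
        mono += d * k
        avg += d * k  # adduct delta dominated by the metal; avg approximated by mono
    return mono, avg


@dataclass
class StoichiometryRecord:
    """Per-protein subunit counts, per-modification counts and metal counts
    summarizing one complexoform."""

    protein_counts: Dict[str, int]
    mod_counts: Dict[str, int]
    metal_counts: Dict[str, int]

    @classmethod
    def of(cls, c: Complexoform) -> "StoichiometryRecord":
        prot = Counter(p.protein_id for p in c.subunits)
        mods: Counter = Counter()
        for p in c.subunits:
            for d in (p.nterm_mod, p.cterm_mod):
                if d is not None:
                    mods[d.name] += 1
            for sm in p.site_mods:
                mods[sm.delta.name] += 1
            mods["disulfide"] += len(p.disulfides)
        if mods.get("disulfide") == 0:
            del mods["disulfide"]
        return cls(dict(prot), dict(mods), dict(c.metal_counter()))


# ---------------------------------------------------------------------------
# Text serialization (ProForma-inspired)
# ---------------------------------------------------------------------------
#
# Grammar:
#   proteoform := [ "{" modname "}" "-" ] residues [ "-" "{" modname "}" ]
#                 [ "|" clause (";" clause)* ]
#   residues   := ( RESIDUE [ "[" modname "]" ]* )+
#   clause     := "ss:" i "-" j          (disulfide)
#               | "unloc:" name ("," name)*   (unlocalized modifications)
#
# Example: "{acetyl}-AK[acetyl]G"   — N-terminal acetyl plus acetyl on K2.

_TOKEN_NTERM = re.compile(r"\{([A-Za-z0-9_\-]+)\}-")
_TOKEN_CTERM = re.compile(r"-\{([A-Za-z0-9_\-]+)\}$")


class ProteoformSyntaxError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


def parse_proteoform(text: str, protein_id: str = "") -> Proteoform:
    """Parse the documented proteoform grammar; errors carry a character offset."""
    original = text
    tail = ""
    if "|" in text:
        text, tail = text.split("|", 1)
    nterm = cterm = None
    m = _TOKEN_NTERM.match(text)
    if m:
        nterm = mod_delta(m.group(1))
        text = text[m.end():]
    m = _TOKEN_CTERM.search(text)
    if m:
        cterm = mod_delta(m.group(1))
        text = text[: m.start()]
    seq: List[str] = []
    site_mods: List[SiteMod] = []
    i = 0
    # character offsets in errors are relative to the original string
    consumed = original.find(text) if text else 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            end = text.find("]", i)
            if end < 0:
                raise ProteoformSyntaxError("unterminated '['", consumed + i)
            if not seq:
                raise ProteoformSyntaxError("modification before any residue",
                                            consumed + i)
            name = text[i + 1: end]
            try:
                delta = mod_delta(name)
            except KeyError as e:
                raise ProteoformSyntaxError(str(e), consumed + i + 1) from None
            site_mods.append(SiteMod(len(seq), delta, True))
            i = end + 1
        elif ch.isalpha() and ch.isupper():
            seq.append(ch)
            i += 1
        else:
            raise ProteoformSyntaxError(f"unexpected character {ch!r}", consumed + i)
    disulfides: List[Tuple[int, int]] = []
    if tail:
        for clause in tail.split(";"):
            clause = clause.strip()
            if clause.startswith("ss:"):
                m = re.fullmatch(r"ss:(\d+)-(\d+)", clause)
                if not m:
                    raise ProteoformSyntaxError("malformed ss: clause",
                                                original.find(clause))
                disulfides.append((int(m.group(1)), int(m.group(2))))
            elif clause.startswith("unloc:"):
                for name in clause[len("unloc:"):].split(","):
                    site_mods.append(SiteMod(ANYWHERE, mod_delta(name.strip()), False))
            else:
                raise ProteoformSyntaxError(f"unknown clause {clause!r}",
                                            original.find(clause))
    return Proteoform(
        protein_id=protein_id,
        base_sequence="".join(seq),
        nterm_mod=nterm,
        cterm_mod=cterm,
        site_mods=tuple(site_mods),
        disulfides=tuple(disulfides),
    )


def serialize_proteoform(p: Proteoform) -> str:
    by_pos: Dict[int, List[str]] = {}
    unloc: List[str] = []
    for sm in p.site_mods:
        if sm.localized:
            by_pos.setdefault(sm.position, []).append(sm.delta.name)
        else:
            unloc.append(sm.delta.name)
    parts: List[str] = []
    if p.nterm_mod:
        parts.append("{%s}-" % p.nterm_mod.name)
    for idx, aa in enumerate(p.base_sequence, start=1):
        parts.append(aa)
        for name in sorted(by_pos.get(idx, [])):
            parts.append(f"[{name}]")
    if p.cterm_mod:
        parts.append("-{%s}" % p.cterm_mod.name)
    clauses = [f"ss:{i}-{j}" for i, j in p.disulfides]
    if unloc:
        clauses.append("unloc:" + ",".join(sorted(unloc)))
    if clauses:
        parts.append("|" + ";".join(clauses))
    return "".join(parts)
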