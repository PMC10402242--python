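"""Exact mass chemistry: elemental compositions, modification and metal-adduct
mass deltas, and aggregated isotope distributions.

Monoisotopic masses are the primary currency throughout the package (the
assemblies of interest, <= 70 kDa, are isotopically resolved on Orbitrap
instruments); average masses are computed and carried alongside so either can
be selected for matching.

Element masses and isotope abundances come from the NIST tables shipped with
:mod:`pyteomics`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import yaml
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "ElementalComposition",
    "MassDelta",
    "IsotopeDistribution",
    "composition_mass",
    "formula_mass",
    "mod_delta",
    "register_modification",
    "load_modifications",
    "known_modifications",
    "metal_adduct_delta",
    "isotope_distribution",
    "averagine_composition",
    "AVERAGINE_UNIT",
]

#: Mass of a proton in Da, used for all charge arithmetic (positive-mode ESI).
PROTON_MASS = 1.0072765

_NIST = _pmass.nist_mass


def _check_element(symbol: str) -> None:
    if symbol not in _NIST:
        raise KeyError(f"unknown element symbol: {symbol!r}")


def element_mono_mass(symbol: str) -> float:
    """Monoisotopic (most abundant isotope) mass of one atom, in Da."""
    _check_element(symbol)
    return _NIST[symbol][0][0]


def element_average_mass(symbol: str) -> float:
    """Abundance-weighted average atomic mass, in Da."""
    _check_element(symbol)
    entries = [(m, ab) for k, (m, ab) in _NIST[symbol].items() if k != 0 and ab > 0]
    if not entries:  # synthetic elements: fall back to the reference isotope
        return _NIST[symbol][0][0]
    return sum(m * ab for m, ab in entries) / sum(ab for _, ab in entries)


def element_isotopes(symbol: str) -> List[Tuple[float, float]]:
    """(mass, abundance) pairs of the naturally occurring isotopes."""
    _check_element(symbol)
    iso = [(m, ab) for k, (m, ab) in _NIST[symbol].items() if k != 0 and ab > 0]
    if not iso:
        iso = [(_NIST[symbol][0][0], 1.0)]
    return sorted(iso)


class ElementalComposition(Dict[str, int]):
    """Element -> count mapping with non-negative counts.

    Addition and subtraction are element-wise; subtraction that would drive any
    count negative raises ``ValueError`` (a composition is a physical set of
    atoms, not a signed delta — signed deltas live in :class:`MassDelta`).
    """

    def __init__(self, counts: Optional[Mapping[str, int]] = None, **kw: int):
        super().__init__()
        merged: Dict[str, int] = dict(counts or {})
        merged.update(kw)
        for sym, n in merged.items():
            _check_element(sym)
            if n < 0:
                raise ValueError(f"negative count for element {sym}: {n}")
            if n:
                self[sym] = int(n)

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for sym, n in other.items():
            out[sym] = out.get(sym, 0) + n
        return ElementalComposition(out)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for sym, n in other.items():
            out[sym] = out.get(sym, 0) - n
            if out[sym] < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {sym}"
                )
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        if k < 0:
            raise ValueError("cannot scale a composition by a negative factor")
        return ElementalComposition({s: n * k for s, n in self.items()})

    __rmul__ = __mul__

    @property
    def mono_mass(self) -> float:
        return sum(element_mono_mass(s) * n for s, n in self.items())

    @property
    def average_mass(self) -> float:
        return sum(element_average_mass(s) * n for s, n in self.items())


def composition_mass(c: Mapping[str, int]) -> Tuple[float, float]:
    """Return ``(monoisotopic, average)`` mass in Da of a composition."""
    c = c if isinstance(c, ElementalComposition) else ElementalComposition(c)
    return c.mono_mass, c.average_mass


def formula_mass(formula: Mapping[str, int]) -> Tuple[float, float]:
    """(mono, average) mass of a *signed* element-count delta, in Da."""
    mono = sum(element_mono_mass(s) * n for s, n in formula.items())
    avg = sum(element_average_mass(s) * n for s, n in formula.items())
    return mono, avg


# ---------------------------------------------------------------------------
# Modification registry
# ---------------------------------------------------------------------------

#: Sentinel position for a modification identified by mass shift but not
#: localized to a residue ("anywhere").
ANYWHERE = 0

N_TERM = "N-term"
C_TERM = "C-term"


@dataclass(frozen=True)
class MassDelta:
    """A named mass shift (PTM, truncation artifact, disulfide, ...).

    ``formula`` is a signed element-count delta when the chemistry is known;
    deltas may also be registered by bare mass. When a formula is present the
    stored monoisotopic mass must agree with it to 1e-4 Da.
    """

    name: str
    mono_mass: float
    avg_mass: float
    formula: Optional[Mapping[str, int]] = None
    targets: frozenset = frozenset()

    def __post_init__(self):
        if self.formula is not None:
            mono, _ = formula_mass(self.formula)
            if abs(mono - self.mono_mass) > 1e-4:
                raise ValueError(
                    f"modification {self.name!r}: stated mono mass "
                    f"{self.mono_mass} disagrees with formula mass {mono:.5f}"
                )


def _delta(name, formula, targets):
    mono, avg = formula_mass(formula)
    return MassDelta(name, mono, avg, formula, frozenset(targets))


# Built-in vocabulary: the PTMs observed on the complexes this engine targets
# (acetylation, mono/di/tri-methylation, phosphorylation, deamidation,
# S-nitrosylation, oxidation) plus processing events (initial-Met cleavage,
# disulfide formation).
_REGISTRY: Dict[str, MassDelta] = {}
for d in [
    _delta("acetyl", {"C": 2, "H": 2, "O": 1}, ["K", "S", "T", "C", N_TERM]),
    _delta("methyl", {"C": 1, "H": 2}, ["K", "R"]),
    _delta("dimethyl", {"C": 2, "H": 4}, ["K", "R"]),
    _delta("trimethyl", {"C": 3, "H": 6}, ["K"]),
    _delta("phospho", {"H": 1, "P": 1, "O": 3}, ["S", "T", "Y"]),
    _delta("deamidation", {"H": -1, "N": -1, "O": 1}, ["N", "Q"]),
    _delta("nitrosyl", {"N": 1, "O": 1, "H": -1}, ["C"]),
    _delta("ox", {"O": 1}, ["M", "W", "C"]),
    _delta("met_loss", {"C": -5, "H": -9, "N": -1, "O": -1, "S": -1}, [N_TERM]),
    _delta("disulfide", {"H": -2}, ["C"]),
    _delta("amide", {"N": 1, "H": 1, "O": -1}, [C_TERM]),
]:
    _REGISTRY[d.name] = d

_ALIASES = {
    "acetylation": "acetyl",
    "methylation": "methyl",
    "dimethylation": "dimethyl",
    "trimethylation": "trimethyl",
    "phosphorylation": "phospho",
    "phosphate": "phospho",
    "deamidated": "deamidation",
    "nitrosylation": "nitrosyl",
    "s-nitrosylation": "nitrosyl",
    "oxidation": "ox",
    "initial_met_cleavage": "met_loss",
}


def mod_delta(name: str) -> MassDelta:
    """Look up a modification by name (case-insensitive; common synonyms OK)."""
    key = name.lower()
    key = _ALIASES.get(key, key)
    try:
        return _REGISTRY[key]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise KeyError(
            f"unknown modification {name!r}; known modifications: {known}"
        ) from None


def known_modifications() -> List[str]:
    return sorted(_REGISTRY)


def register_modification(
    name: str,
    formula: Optional[Mapping[str, int]] = None,
    mono_mass: Optional[float] = None,
    avg_mass: Optional[float] = None,
    targets: Iterable[str] = (),
) -> MassDelta:
    """Add (or replace) a modification in the registry.

    Either ``formula`` or ``mono_mass`` must be given; average mass defaults to
    the formula's average mass, or to the mono mass when only a mass is known.
    """
    if formula is not None:
        mono, avg = formula_mass(formula)
        if mono_mass is not None and abs(mono - mono_mass) > 1e-4:
            raise ValueError(
                f"{name!r}: given mono_mass {mono_mass} disagrees with formula"
            )
        d = MassDelta(name.lower(), mono, avg_mass if avg_mass is not None else avg,
                      formula, frozenset(targets))
    elif mono_mass is not None:
        d = MassDelta(name.lower(), mono_mass,
                      avg_mass if avg_mass is not None else mono_mass,
                      None, frozenset(targets))
    else:
        raise ValueError("register_modification needs a formula or a mono_mass")
    _REGISTRY[d.name] = d
    return d


def load_modifications(path: str) -> List[MassDelta]:
    """Extend the registry from a YAML file.

    Schema: a list of entries, each with ``name`` and either ``formula``
    (element -> signed count mapping) or ``mono_mass``; optional ``avg_mass``
    and ``targets`` (residue letters, ``N-term``, ``C-term``).
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    return [
        register_modification(
            e["name"],
            formula=e.get("formula"),
            mono_mass=e.get("mono_mass"),
            avg_mass=e.get("avg_mass"),
            targets=e.get("targets", ()),
        )
        for e in entries
    ]


def registry() -> Mapping[str, MassDelta]:
    return dict(_REGISTRY)


# ---------------------------------------------------------------------------
# Metal adducts
# ---------------------------------------------------------------------------

#: Supported metal cofactors -> default number of protons displaced on binding.
#: Divalent cations displace two protons (charge-compensated binding), which
#: keeps the observed charge of an ion equal to its protonation count.
METAL_DEFAULT_DISPLACEMENT: Dict[str, int] = {
    "Cu": 2, "Zn": 2, "Fe": 2, "Mg": 2, "Ca": 2, "Ni": 2, "Mn": 2,
}


def metal_adduct_delta(metal: str, displaced_protons: Optional[int] = None) -> float:
    """Monoisotopic neutral-mass shift of binding one metal cofactor.

    delta = M(metal) - displaced_protons * M(H atom). ``displaced_protons``
    defaults to the per-metal convention (2 for the supported divalents).
    """
    if metal not in METAL_DEFAULT_DISPLACEMENT:
        raise KeyError(
            f"unsupported metal {metal!r}; supported: "
            + ", ".join(sorted(METAL_DEFAULT_DISPLACEMENT))
        )
    if displaced_protons is None:
        displaced_protons = METAL_DEFAULT_DISPLACEMENT[metal]
    if displaced_protons < 0:
        raise ValueError("displaced_protons must be >= 0")
    return element_mono_mass(metal) - displaced_protons * element_mono_mass("H")


def metal_formula_delta(metal: str, displaced_protons: Optional[int] = None) -> Dict[str, int]:
    """Signed element delta of a metal adduct (for isotope modeling)."""
    if displaced_protons is None:
        displaced_protons = METAL_DEFAULT_DISPLACEMENT[metal]
    return {metal: 1, "H": -displaced_protons}


# ---------------------------------------------------------------------------
# Isotope distributions
# ---------------------------------------------------------------------------


@dataclass
class IsotopeDistribution:
    """Aggregated (nominal-mass-binned) isotope distribution.

    ``masses`` are abundance-weighted mean masses per nominal-mass bin,
    strictly increasing; ``abundances`` sum to 1 after normalization.
    """

    masses: np.ndarray
    abundances: np.ndarray
    prune: float = 0.0

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)

    def normalized(self) -> "IsotopeDistribution":
        s = self.abundances.sum()
        return IsotopeDistribution(self.masses, self.abundances / s, self.prune)

    @property
    def base_peak_mass(self) -> float:
        return float(self.masses[int(np.argmax(self.abundances))])

    def __len__(self) -> int:
        return len(self.masses)


def _single_atom(symbol: str) -> Tuple[np.ndarray, np.ndarray]:
    iso = element_isotopes(symbol)
    m0 = round(iso[0][0])
    nbins = round(iso[-1][0]) - m0 + 1
    p = np.zeros(nbins)
    m = np.zeros(nbins)
    for mass_i, ab in iso:
        k = round(mass_i) - m0
        p[k] += ab
        m[k] += ab * mass_i
    nz = p > 0
    m[nz] /= p[nz]
    return p, m


def _convolve(a: Tuple[np.ndarray, np.ndarray], b: Tuple[np.ndarray, np.ndarray],
              prune: float) -> Tuple[np.ndarray, np.ndarray]:
    pa, ma = a
    pb, mb = b
    p = np.convolve(pa, pb)
    # mass-weighted cross terms: m[k] = sum_{i+j=k} pa_i pb_j (ma_i + mb_j) / p[k]
    w = np.convolve(pa * ma, pb) + np.convolve(pa, pb * mb)
    nz = p > 0
    m = np.zeros_like(p)
    m[nz] = w[nz] / p[nz]
    if prune > 0:
        keep = p >= prune * p.max()
        # keep a contiguous span so nominal-mass spacing stays interpretable
        idx = np.nonzero(keep)[0]
        p, m = p[idx[0]: idx[-1] + 1], m[idx[0]: idx[-1] + 1]
    return p, m


def isotope_distribution(
    c: Mapping[str, int], prune: float = 1e-6
) -> IsotopeDistribution:
    """Aggregated isotope distribution of a composition.

    Computed by iterative (binary-exponentiation) convolution of per-element
    single-atom distributions, binned at nominal-mass (unit) resolution.
    ``prune`` drops isotopologue bins below that fraction of the base peak
    between convolutions; the result is renormalized to sum 1.
    """
    c = c if isinstance(c, ElementalComposition) else ElementalComposition(c)
    if not c:
        raise ValueError("cannot compute an isotope distribution of nothing")
    if not (0 <= prune < 1):
        raise ValueError("prune must be in [0, 1)")
    acc: Optional[Tuple[np.ndarray, np.ndarray]] = None
    for sym, n in sorted(c.items()):
        base = _single_atom(sym)
        power = None
        k = n
        while k:
            if k & 1:
                power = base if power is None else _convolve(power, base, prune)
            k >>= 1
            if k:
                base = _convolve(base, base, prune)
        acc = power if acc is None else _convolve(acc, power, prune)
    p, m = acc
    nz = p > 0
    p, m = p[nz], m[nz]
    order = np.argsort(m)
    p, m = p[order], m[order]
    return IsotopeDistribution(m, p / p.sum(), prune)


def convolve_distributions(
    a: IsotopeDistribution, b: IsotopeDistribution
) -> IsotopeDistribution:
    """Convolution of two aggregated distributions (for property checks)."""
    p, m = _convolve((a.abundances, a.masses), (b.abundances, b.masses), 0.0)
    nz = p > 0
    return IsotopeDistribution(m[nz], p[nz] / p[nz].sum())


# ---------------------------------------------------------------------------
# Averagine
# ---------------------------------------------------------------------------

#: The average elemental composition per 111.1254 Da (average) of protein.
AVERAGINE_UNIT: Dict[str, float] = {
    "C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417,
}
AVERAGINE_UNIT_MASS = 111.1254


def averagine_composition(mass: float, kind: str = "mono") -> ElementalComposition:
    """Model composition of an unknown protein-like species of a given mass.

    Scales the averagine unit to the target, rounds the heavy-element counts,
    and balances the remainder with hydrogens so the composition's ``kind``
    mass ("mono" or "average") lands within half a hydrogen of the target.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if kind not in ("mono", "average"):
        raise ValueError("kind must be 'mono' or 'average'")
    scale = mass / AVERAGINE_UNIT_MASS
    counts = {s: max(0, round(f * scale)) for s, f in AVERAGINE_UNIT.items() if s != "H"}
    heavy = ElementalComposition(counts)
    heavy_mass = heavy.mono_mass if kind == "mono" else heavy.average_mass
    h_mass = element_mono_mass("H") if kind == "mono" else element_average_mass("H")
    n_h = max(0, round((mass - heavy_mass) / h_mass))
    return heavy + {"H": n_h}
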