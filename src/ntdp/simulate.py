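"""Ground-truthed synthetic native MS1/MS2/MS3 data.

The generator emulates the MS^n cascade of a native top-down experiment on
intact assemblies <= 70 kDa: MS1 charge envelopes of complexoforms, subunit
ejection upon HCD with asymmetric charge partitioning (MS2), and b/y fragment
ladders of isolated ejected monomers (MS3), with metal-adduct retention,
detectability thinning, m/z and intensity noise, and uniform decoy peaks.
Every non-decoy peak is annotated with its source, so each pipeline stage can
be tested against planted truth.

All randomness flows from the spec's seed; the same seed gives byte-identical
output.

Bookkeeping is exact: in every simulated dissociation the product neutral
masses sum to the precursor neutral mass and the product charges sum to the
precursor charge. Metal retention during HCD is all-or-none: a fragment whose
span contains a metal's whole coordinating set is emitted holo, one whose
span contains none of it apo, and one straddling the set — neither cleanly
apo nor holo — is suppressed.

The fixture-suite sequences are synthetic: they are engineered to the masses,
modification sites and metal-site positions the worked examples need (a
53,070.9 Da deamidated dimer, a ~37 kDa trimer whose 12+ ion falls at
m/z 3080-3100, a disulfide-bridged metalloprotein dimer, a Lys-rich monomer
with combinatorial PTMs), not copies of any human protein.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chem import ANYWHERE, PROTON_MASS, metal_adduct_delta, mod_delta
from .deconv import mz_for
from .fragments import generate_by_ladder
from .proteoform import (
    Complexoform,
    Proteoform,
    SiteMod,
    complexoform_mass,
    proteoform_mass,
)
from .spectra import Peak, Precursor, Spectrum, write_peaklist

__all__ = [
    "SimulatedSpecies",
    "SimulationSpec",
    "TruthRecord",
    "simulate_run",
    "make_fixture_suite",
    "write_mzml",
    "tpi_like_spec",
    "mif_like_spec",
    "sod1_like_spec",
    "nutf2_like_spec",
]


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSpecies:
    """One planted complexoform and how it appears in the run."""

    complexoform: Complexoform
    abundance: float
    ms1_charges: Tuple[int, ...]
    #: metal -> coordinating residue positions on the subunit that carries it
    metal_sites: Mapping[str, Tuple[int, ...]] = field(default_factory=dict)
    #: where metals go on subunit ejection: "remnant" (default) or "monomer"
    metal_retention: str = "remnant"
    #: emit MS3 spectra for the ejected monomers (False emulates species
    #: identified from the MS2 mass shift only)
    include_ms3: bool = True
    #: override the partition rule's ejected-monomer charge
    ejected_charge: Optional[int] = None

    def __post_init__(self):
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.metal_retention not in ("remnant", "monomer"):
            raise ValueError("metal_retention must be 'remnant' or 'monomer'")


@dataclass
class SimulationSpec:
    """Study conditions for one simulated run.

    Defaults model a well-behaved Orbitrap native run: 2 mTh centroid m/z
    noise, 5% multiplicative intensity noise, 95% per-fragment detectability,
    five uniform decoy peaks per MS^n spectrum, and the +2 asymmetric charge
    bonus for ejected monomers that reproduces the 12+ trimer -> 6+ monomer
    pattern.
    """

    species: List[SimulatedSpecies]
    charge_bonus: int = 2
    fragment_detectability: float = 0.95
    mz_noise_sigma: float = 0.002  # Th
    intensity_noise_sigma: float = 0.05  # multiplicative
    decoy_rate: float = 5.0  # expected decoys per MS^n spectrum
    seed: int = 0
    run_id: str = "sim"

    def __post_init__(self):
        if not (0.0 <= self.fragment_detectability <= 1.0):
            raise ValueError("fragment_detectability must be in [0, 1]")


@dataclass
class TruthAnnotation:
    spectrum_id: str
    mz: float
    kind: str  # precursor | monomer | remnant | fragment | decoy
    species_label: str
    detail: str
    neutral_mass: float
    charge: int


@dataclass
class TruthRecord:
    annotations: List[TruthAnnotation] = field(default_factory=list)

    def for_spectrum(self, sid: str) -> List[TruthAnnotation]:
        return [a for a in self.annotations if a.spectrum_id == sid]

    def non_decoy(self) -> List[TruthAnnotation]:
        return [a for a in self.annotations if a.kind != "decoy"]

    def to_tsv(self) -> str:
        lines = ["spectrum_id\tmz\tkind\tspecies\tdetail\tneutral_mass\tcharge"]
        for a in self.annotations:
            lines.append("\t".join([
                a.spectrum_id, f"{a.mz:.6f}", a.kind, a.species_label,
                a.detail, f"{a.neutral_mass:.6f}", str(a.charge),
            ]))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------


def partition_charge(z_complex: int, monomer_mass: float, complex_mass: float,
                     bonus: int = 2) -> int:
    """Charge taken by an ejected monomer: ceil(z * mass fraction + bonus),
    clamped to [1, z_complex - 1]. Ejected monomers carry a disproportionate
    share of the charge (asymmetric partitioning)."""
    import math
    z = math.ceil(z_complex * (monomer_mass / complex_mass) + bonus)
    return max(1, min(z_complex - 1, z))


def _distinct_subunits(c: Complexoform) -> List[Proteoform]:
    seen = set()
    out = []
    for p in c.subunits:
        if p.mass_key() not in seen:
            seen.add(p.mass_key())
            out.append(p)
    return out


def _fragment_metal_fate(frag_span: Tuple[int, int],
                         metal_sites: Mapping[str, Tuple[int, ...]],
                         metals_present: Mapping[str, int],
                         ) -> Optional[Tuple[Tuple[str, int], ...]]:
    """Metal content of a fragment under all-or-none retention, or None when
    the fragment straddles a coordinating set and must be suppressed."""
    lo, hi = frag_span
    content: List[Tuple[str, int]] = []
    for metal, count in sorted(metals_present.items()):
        if count == 0:
            continue
        sites = metal_sites.get(metal, ())
        if not sites:
            continue  # sites unknown: metal never retained on fragments
        inside = sum(1 for s in sites if lo <= s <= hi)
        if inside == len(sites):
            content.append((metal, count))
        elif inside > 0:
            return None  # straddles the coordinating set
    return tuple(content)


def simulate_run(spec: SimulationSpec) -> Tuple[List[Spectrum], TruthRecord]:
    """Generate the linked MS1/MS2/MS3 spectra for a simulation spec."""
    rng = np.random.default_rng(spec.seed)
    truth = TruthRecord()
    spectra: List[Spectrum] = []
    rid = spec.run_id

    def jitter_mz(mz: float) -> float:
        if spec.mz_noise_sigma > 0:
            return mz + rng.normal(0.0, spec.mz_noise_sigma)
        return mz

    def jitter_intensity(i: float) -> float:
        if spec.intensity_noise_sigma > 0:
            return max(1e-6, i * (1.0 + rng.normal(0.0, spec.intensity_noise_sigma)))
        return i

    def add_decoys(peaks: List[Peak], sid: str) -> None:
        if spec.decoy_rate <= 0 or not peaks:
            return
        n = int(rng.poisson(spec.decoy_rate))
        lo = min(p.mz for p in peaks)
        hi = max(p.mz for p in peaks)
        med = float(np.median([p.intensity for p in peaks]))
        for _ in range(n):
            mz = float(rng.uniform(lo, hi))
            peaks.append(Peak(mz, jitter_intensity(0.5 * med)))
            truth.annotations.append(TruthAnnotation(
                sid, mz, "decoy", "", "", 0.0, 0))

    # --- MS1 ---------------------------------------------------------------
    ms1_id = f"{rid}_ms1"
    ms1_peaks: List[Peak] = []
    for si, sp in enumerate(spec.species):
        cmass = complexoform_mass(sp.complexoform)[0]
        label = sp.complexoform.label or f"species{si}"
        for z in sp.ms1_charges:
            mz = jitter_mz(mz_for(cmass, z))
            inten = jitter_intensity(sp.abundance)
            ms1_peaks.append(Peak(mz, inten))
            truth.annotations.append(TruthAnnotation(
                ms1_id, mz, "precursor", label, f"z={z}", cmass, z))
    ms1_peaks.sort()
    spectra.append(Spectrum(ms1_id, 1, ms1_peaks))

    # --- MS2: subunit ejection ----------------------------------------------
    for si, sp in enumerate(spec.species):
        cmass = complexoform_mass(sp.complexoform)[0]
        label = sp.complexoform.label or f"species{si}"
        metals = dict(sp.complexoform.metals)
        metal_delta = sum(metal_adduct_delta(m) * k for m, k in metals.items())
        z_iso = sp.ms1_charges[0]
        ms2_id = f"{rid}_ms2_{si}"
        peaks: List[Peak] = []
        ejections: List[Tuple[Proteoform, float, int, Dict[str, int]]] = []
        for p in _distinct_subunits(sp.complexoform):
            pmass = proteoform_mass(p)[0]
            mono_metals: Dict[str, int] = {}
            mono_mass = pmass
            if sp.metal_retention == "monomer":
                mono_metals = metals
                mono_mass = pmass + metal_delta
            rem_mass = cmass - mono_mass
            z_m = (sp.ejected_charge if sp.ejected_charge is not None
                   else partition_charge(z_iso, mono_mass, cmass, spec.charge_bonus))
            z_r = z_iso - z_m
            mz_m = jitter_mz(mz_for(mono_mass, z_m))
            peaks.append(Peak(mz_m, jitter_intensity(sp.abundance)))
            truth.annotations.append(TruthAnnotation(
                ms2_id, mz_m, "monomer", label,
                f"subunit={p.protein_id} z={z_m}", mono_mass, z_m))
            if z_r >= 1 and rem_mass > 0:
                mz_r = jitter_mz(mz_for(rem_mass, z_r))
                peaks.append(Peak(mz_r, jitter_intensity(0.8 * sp.abundance)))
                truth.annotations.append(TruthAnnotation(
                    ms2_id, mz_r, "remnant", label,
                    f"complement_of={p.protein_id} z={z_r}", rem_mass, z_r))
            ejections.append((p, mono_mass, z_m, mono_metals))
        add_decoys(peaks, ms2_id)
        peaks.sort()
        spectra.append(Spectrum(
            ms2_id, 2, peaks,
            precursor=Precursor(ms1_id, mz_for(cmass, z_iso), 4.0, z_iso),
            activation="HCD",
        ))

        # --- MS3: fragment ladders of each ejected monomer -------------------
        if not sp.include_ms3:
            continue
        for ei, (p, mono_mass, z_m, mono_metals) in enumerate(ejections):
            ms3_id = f"{rid}_ms3_{si}_{ei}"
            n = p.length
            base = [f for f in generate_by_ladder(p) if not f.metal_content]
            fpeaks: List[Peak] = []
            for f in base:
                if rng.random() > spec.fragment_detectability:
                    continue
                content = _fragment_metal_fate(f.span(n), sp.metal_sites,
                                               mono_metals)
                if content is None:
                    continue
                fmass = f.neutral_mass + sum(
                    metal_adduct_delta(m) * k for m, k in content)
                mz = jitter_mz(fmass + PROTON_MASS)  # rendered singly protonated
                name = f.name + "".join(f"+{m}" * k for m, k in content)
                fpeaks.append(Peak(mz, jitter_intensity(
                    0.3 * sp.abundance * (1.0 + 0.5 * rng.random()))))
                truth.annotations.append(TruthAnnotation(
                    ms3_id, mz, "fragment", label,
                    f"subunit={p.protein_id} ion={name}", fmass, 1))
            add_decoys(fpeaks, ms3_id)
            fpeaks.sort()
            spectra.append(Spectrum(
                ms3_id, 3, fpeaks,
                precursor=Precursor(ms2_id, mz_for(mono_mass, z_m), 3.0, z_m),
                activation="HCD",
            ))
    return spectra, truth


# ---------------------------------------------------------------------------
# Minimal mzML writer
# ---------------------------------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(values: Sequence[float]) -> str:
    raw = struct.pack("<" + "d" * len(values), *values)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(spectra: Sequence[Spectrum], path: str, run_id: str = "run",
               profile: bool = False) -> None:
    """Write spectra as minimal standard-conforming mzML (uncompressed 64-bit
    base64 arrays). ``profile=True`` marks spectra profile-mode (used to test
    the reader's rejection path)."""
    mode_param = ('<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
                  if profile else
                  '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>')
    chunks = [_MZML_HEADER.format(run_id=run_id, count=len(spectra))]
    for idx, s in enumerate(spectra):
        mzs = [p.mz for p in s.peaks]
        intens = [p.intensity for p in s.peaks]
        pre = ""
        if s.precursor is not None:
            pc = s.precursor
            ref = f' spectrumRef="{pc.parent_id}"' if pc.parent_id else ""
            iso = ""
            if pc.isolation_mz is not None:
                half = (pc.isolation_width or 0.0) / 2.0
                iso = f"""
            <isolationWindow>
              <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{pc.isolation_mz:.6f}"/>
              <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{half:.6f}"/>
              <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{half:.6f}"/>
            </isolationWindow>"""
            charge = (f'\n                <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{pc.charge}"/>'
                      if pc.charge is not None else "")
            sel_mz = pc.isolation_mz if pc.isolation_mz is not None else 0.0
            act = ('<cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/>'
                   if s.activation == "HCD" else "")
            pre = f"""
        <precursorList count="1">
          <precursor{ref}>{iso}
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{sel_mz:.6f}"/>{charge}
              </selectedIon>
            </selectedIonList>
            <activation>{act}</activation>
          </precursor>
        </precursorList>"""
        faims = ""
        if s.faims_cv is not None:
            faims = (f'\n        <cvParam cvRef="MS" accession="MS:1001581" '
                     f'name="FAIMS compensation voltage" value="{s.faims_cv}"/>')
        chunks.append(f"""      <spectrum index="{idx}" id="{s.id}" defaultArrayLength="{len(mzs)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>
        {mode_param}{faims}{pre}
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(_b64(mzs))}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{_b64(mzs)}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(_b64(intens))}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{_b64(intens)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""")
    chunks.append(_MZML_FOOTER)
    with open(path, "w") as fh:
        fh.write("".join(chunks))


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

# Synthetic fixture sequences (engineered, not human proteins; see module
# docstring). Positions of interest are part of the engineering.

#: 235 residues; deamidation sites planted at N15 and N71; the dimer of the
#: doubly deamidated monomer has monoisotopic mass 53,070.9 Da (15+/16+ at
#: m/z ~3319/~3539).
TPI_LIKE_SEQUENCE = (
    "YTHPPTRQNWTQTHNQASYHYSSAVESCNTITHWTTSLWQHNLVWRPAYAQLNDNEEWAPDFDIVEASCW"
    "NFHGPPMAGNQLLQSPGQAVDEDASTQQPQVSLPSGRFLHVAGQLVETFQAIYSTIPELLASVFQGSPYC"
    "STLEQQVRGDSSTQAVQYARTLDTPNGWLPQGMQRPYEYQHAGSPDCNPLEGGGYQTFAGPVPLEHSGHR"
    "HQPFETDIEQWRQIPFDHVFQAARQ"
)

#: 111 residues; acetylation site K77, nitrosylation site C80; trimer
#: combinations fall in the 12+ m/z window 3080-3100.
MIF_LIKE_SEQUENCE = (
    "PDVNYDKLFSIQTPELFITSEMVSEQWTWLDQNITSPFKSARLPIQCFNGAAEQTKMGAAWNLRTWNVWT"
    "PAVTDIKLYCTAPCQCKGRGSGFSTSALFIAFSATKDSTGT"
)

#: 153 residues; cysteines only at 57 and 111 (one disulfide); His/Asp metal
#: sites: Cu at 46, 48, 63, 120 and Zn at 63, 71, 80, 83.
SOD1_LIKE_SEQUENCE = (
    "SMFHGISAISSNDHTGRKTEHHIDESAIAKAASESGSKQGEPAKEHDHALVSLVLGCSDPTGHDAQKVVS"
    "HQSGGSTAFHTMDLKKLTTVSAGGDGTKAIEIKGKAIKGACARLTQAAAHEEIAGRPSGDSTLGSEYFSQ"
    "PQAAQNFTTSDTI"
)
SOD1_CU_SITES = (46, 48, 63, 120)
SOD1_ZN_SITES = (63, 71, 80, 83)

#: canonical 127 residues (initial Met at 1); after Met cleavage the lysines
#: of interest sit at processed positions 4, 55 and 63.
NUTF2_LIKE_CANONICAL = (
    "MCFRKPFEYMLQHAVDWKSPTWSALRPVVLVVADCWTYNMIVATAVFATTWLDKKKSSTTWAHKTLVWTW"
    "KEGDLSSNNAETLLKSKAQMVFVAALNTSQHGAPRHPVMDFGVVFYYDVSLNYKGIS"
)
NUTF2_LIKE_SEQUENCE = NUTF2_LIKE_CANONICAL[1:]


def _mods(*pairs) -> Tuple[SiteMod, ...]:
    return tuple(SiteMod(pos, mod_delta(name), pos != ANYWHERE)
                 for pos, name in pairs)


def tpi_like_spec(seed: int = 0, **noise) -> Tuple[SimulationSpec, dict]:
    """Deamidated homodimer at 15+/16+ (dimer mono mass 53,070.9 Da)."""
    monomer = Proteoform("TPI_L", TPI_LIKE_SEQUENCE,
                         site_mods=_mods((15, "deamidation"), (71, "deamidation")))
    dimer = Complexoform((monomer, monomer), label="tpi_like_dimer")
    spec = SimulationSpec(
        species=[SimulatedSpecies(dimer, 100.0, (15, 16))],
        seed=seed, run_id="tpi_like", **noise)
    space = {
        "proteins": [{
            "id": "TPI_L",
            "sequence": TPI_LIKE_SEQUENCE,
            "mods": [{"name": "deamidation", "max": 2},
                     {"name": "phospho", "max": 1}],
        }],
        "stoichiometry": {"min_subunits": 1, "max_subunits": 2},
    }
    return spec, space


def mif_like_spec(seed: int = 0, **noise) -> Tuple[SimulationSpec, dict]:
    """Trimers assembled from unmodified, acetylated (K77) and nitrosylated
    (C80) monomer proteoforms; 12+ falls in m/z 3080-3100."""
    unmod = Proteoform("MIF_L", MIF_LIKE_SEQUENCE)
    acetyl = Proteoform("MIF_L", MIF_LIKE_SEQUENCE, site_mods=_mods((77, "acetyl")))
    nitros = Proteoform("MIF_L", MIF_LIKE_SEQUENCE, site_mods=_mods((80, "nitrosyl")))
    t1 = Complexoform((unmod, acetyl, nitros), label="mif_like_trimer_uan")
    t2 = Complexoform((unmod, unmod, acetyl), label="mif_like_trimer_uua")
    spec = SimulationSpec(
        species=[SimulatedSpecies(t1, 100.0, (12, 13)),
                 SimulatedSpecies(t2, 60.0, (12, 13))],
        seed=seed, run_id="mif_like", **noise)
    space = {
        "proteins": [{
            "id": "MIF_L",
            "sequence": MIF_LIKE_SEQUENCE,
            "mods": [{"name": "acetyl", "max": 1}, {"name": "nitrosyl", "max": 1}],
        }],
        "stoichiometry": {"min_subunits": 1, "max_subunits": 3},
    }
    return spec, space


def sod1_like_spec(seed: int = 0, **noise) -> Tuple[SimulationSpec, dict]:
    """Disulfide-bridged, N-terminally acetylated homodimer binding one Cu and
    one Zn; the ejected 6+ monomer carries both metals into MS3."""
    monomer = Proteoform("SOD1_L", SOD1_LIKE_SEQUENCE,
                         nterm_mod=mod_delta("acetyl"),
                         disulfides=((57, 111),))
    dimer = Complexoform((monomer, monomer), (("Cu", 1), ("Zn", 1)),
                         label="sod1_like_dimer")
    spec = SimulationSpec(
        species=[SimulatedSpecies(
            dimer, 100.0, (11, 12),
            metal_sites={"Cu": SOD1_CU_SITES, "Zn": SOD1_ZN_SITES},
            metal_retention="monomer",
            ejected_charge=6,
        )],
        seed=seed, run_id="sod1_like", **noise)
    space = {
        "proteins": [{
            "id": "SOD1_L",
            "sequence": SOD1_LIKE_SEQUENCE,
            "nterm_mods": ["acetyl"],
            "disulfides": [[57, 111]],
            "mods": [{"name": "methyl", "max": 1}],
        }],
        "stoichiometry": {"min_subunits": 1, "max_subunits": 2},
        "metals": {"Cu": 1, "Zn": 1},
    }
    return spec, space


def nutf2_like_spec(seed: int = 0, **noise) -> Tuple[SimulationSpec, dict]:
    """Met-cleaved monomer PTM combinatorics: an acetylated heterodimer with
    MS3 evidence, plus a triply modified dimer identified only from its MS2
    mass shift (including the acetyl-vs-trimethyl near-isobaric ambiguity)."""
    seq = NUTF2_LIKE_SEQUENCE
    trunc = (2, len(NUTF2_LIKE_CANONICAL))
    unmod = Proteoform("NUTF2_L", seq, truncation=trunc)
    k4ac = Proteoform("NUTF2_L", seq, site_mods=_mods((4, "acetyl")),
                      truncation=trunc)
    triple = Proteoform("NUTF2_L", seq,
                        site_mods=_mods((4, "acetyl"), (55, "methyl"),
                                        (63, "acetyl")),
                        truncation=trunc)
    d1 = Complexoform((unmod, k4ac), label="nutf2_like_dimer_ac")
    d2 = Complexoform((unmod, triple), label="nutf2_like_dimer_triple")
    spec = SimulationSpec(
        species=[
            SimulatedSpecies(d1, 100.0, (10, 11)),
            SimulatedSpecies(d2, 40.0, (10, 11), include_ms3=False),
        ],
        seed=seed, run_id="nutf2_like", **noise)
    space = {
        "proteins": [{
            "id": "NUTF2_L",
            "sequence": NUTF2_LIKE_CANONICAL,
            "truncations": [[2, len(NUTF2_LIKE_CANONICAL)]],
            "mods": [{"name": "acetyl", "max": 3},
                     {"name": "methyl", "max": 1},
                     {"name": "dimethyl", "max": 1},
                     {"name": "trimethyl", "max": 1}],
        }],
        "stoichiometry": {"min_subunits": 1, "max_subunits": 2},
    }
    return spec, space


FIXTURES = {
    "tpi_like": tpi_like_spec,
    "mif_like": mif_like_spec,
    "sod1_like": sod1_like_spec,
    "nutf2_like": nutf2_like_spec,
}


def make_fixture_suite(out_dir: str, seed: int = 1) -> Dict[str, dict]:
    """Write the standard fixture suite (peak lists, truth TSVs, search-space
    YAMLs) and return {name: {"spectra": ..., "truth": ..., "space": ...,
    "paths": ...}}. Deterministic under a fixed seed."""
    import os

    import yaml

    os.makedirs(out_dir, exist_ok=True)
    out: Dict[str, dict] = {}
    for i, (name, factory) in enumerate(sorted(FIXTURES.items())):
        spec, space = factory(seed=seed + i)
        spectra, truth = simulate_run(spec)
        paths = {
            "peaklist": os.path.join(out_dir, f"{name}.peaklist.txt"),
            "truth": os.path.join(out_dir, f"{name}.truth.tsv"),
            "space": os.path.join(out_dir, f"{name}.space.yaml"),
        }
        write_peaklist(spectra, paths["peaklist"])
        with open(paths["truth"], "w") as fh:
            fh.write(truth.to_tsv())
        with open(paths["space"], "w") as fh:
            yaml.safe_dump(space, fh, sort_keys=True)
        out[name] = {"spec": spec, "spectra": spectra, "truth": truth,
                     "space": space, "paths": paths}
    return out
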