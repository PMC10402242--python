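"""Spectrum containers and I/O, including the MS1 -> MS2 -> MS3 provenance
chain that drives identification.

Two formats are supported: a bespoke, documented plain-text peak-list format
(lossless round trip) and standard mzML (read via pyteomics; a minimal writer
lives in :mod:`ntdp.simulate`). Input is assumed centroided — profile data is
rejected, not centroided.

Peak-list format::

    # spectrum
    id=ms2_1
    ms_level=2
    precursor_id=ms1
    isolation_mz=3084.500000
    isolation_width=10.000000
    charge=12
    activation=HCD
    faims_cv=-40.0
    mz intensity
    1234.567890 100.000000
    ...

Blocks are separated by blank lines; metadata keys other than ``id`` and
``ms_level`` are optional. FAIMS compensation voltage is carried as metadata
only — spectra at different CVs are processed independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

__all__ = [
    "Peak",
    "Precursor",
    "Spectrum",
    "SpectrumTree",
    "read_peaklist",
    "write_peaklist",
    "read_mzml",
    "link_hierarchy",
]


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class Precursor:
    parent_id: Optional[str]
    isolation_mz: Optional[float] = None
    isolation_width: Optional[float] = None
    charge: Optional[int] = None  # None = unknown, never guessed


@dataclass
class Spectrum:
    id: str
    ms_level: int
    peaks: List[Peak]
    precursor: Optional[Precursor] = None
    activation: Optional[str] = None
    faims_cv: Optional[float] = None

    def __post_init__(self):
        if self.ms_level not in (1, 2, 3):
            raise ValueError(f"spectrum {self.id}: ms_level must be 1, 2 or 3")
        if self.ms_level >= 2 and self.precursor is None:
            raise ValueError(f"spectrum {self.id}: MS{self.ms_level} needs a precursor")
        self.peaks = [Peak(float(m), float(i)) for m, i in self.peaks]
        for p in self.peaks:
            if p.mz <= 0:
                raise ValueError(f"spectrum {self.id}: non-positive m/z {p.mz}")
            if p.intensity < 0:
                raise ValueError(f"spectrum {self.id}: negative intensity")
        if any(b.mz < a.mz for a, b in zip(self.peaks, self.peaks[1:])):
            raise ValueError(f"spectrum {self.id}: peaks not sorted by m/z")

    @property
    def mz_array(self):
        import numpy as np
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self):
        import numpy as np
        return np.array([p.intensity for p in self.peaks])


# ---------------------------------------------------------------------------
# Peak-list text format
# ---------------------------------------------------------------------------

_META_KEYS = ("precursor_id", "isolation_mz", "isolation_width", "charge",
              "activation", "faims_cv")


class PeaklistFormatError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _build(meta: Dict[str, str], peaks: List[Peak], line: int) -> Spectrum:
    if "id" not in meta or "ms_level" not in meta:
        raise PeaklistFormatError("block missing id= or ms_level=", line)
    precursor = None
    if any(k in meta for k in ("precursor_id", "isolation_mz", "charge")):
        precursor = Precursor(
            parent_id=meta.get("precursor_id"),
            isolation_mz=float(meta["isolation_mz"]) if "isolation_mz" in meta else None,
            isolation_width=float(meta["isolation_width"]) if "isolation_width" in meta else None,
            charge=int(meta["charge"]) if "charge" in meta else None,
        )
    try:
        return Spectrum(
            id=meta["id"],
            ms_level=int(meta["ms_level"]),
            peaks=peaks,
            precursor=precursor,
            activation=meta.get("activation"),
            faims_cv=float(meta["faims_cv"]) if "faims_cv" in meta else None,
        )
    except ValueError as e:
        raise PeaklistFormatError(str(e), line) from None


def read_peaklist(path: str) -> List[Spectrum]:
    spectra: List[Spectrum] = []
    meta: Dict[str, str] = {}
    peaks: List[Peak] = []
    block_start = 0
    in_block = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                if in_block:
                    spectra.append(_build(meta, peaks, block_start))
                    meta, peaks, in_block = {}, [], False
                continue
            if line.startswith("#"):
                if not in_block:
                    in_block = True
                    block_start = lineno
                continue
            if not in_block:
                in_block = True
                block_start = lineno
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                meta[key.strip()] = value.strip()
            elif line.lower().startswith("mz"):
                continue  # column header
            else:
                fields = line.split()
                if len(fields) != 2:
                    raise PeaklistFormatError(
                        f"expected 'mz intensity', got {line!r}", lineno)
                try:
                    mz, inten = float(fields[0]), float(fields[1])
                except ValueError:
                    raise PeaklistFormatError(
                        f"non-numeric peak values {line!r}", lineno) from None
                if mz <= 0:
                    raise PeaklistFormatError(f"non-positive m/z {mz}", lineno)
                if inten < 0:
                    raise PeaklistFormatError(f"negative intensity {inten}", lineno)
                if peaks and mz < peaks[-1].mz:
                    raise PeaklistFormatError(
                        f"peaks not sorted: {mz} after {peaks[-1].mz}", lineno)
                peaks.append(Peak(mz, inten))
    if in_block:
        spectra.append(_build(meta, peaks, block_start))
    return spectra


def write_peaklist(spectra: Iterable[Spectrum], path: str) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("# spectrum\n")
            fh.write(f"id={s.id}\n")
            fh.write(f"ms_level={s.ms_level}\n")
            if s.precursor is not None:
                pc = s.precursor
                if pc.parent_id is not None:
                    fh.write(f"precursor_id={pc.parent_id}\n")
                if pc.isolation_mz is not None:
                    fh.write(f"isolation_mz={pc.isolation_mz:.6f}\n")
                if pc.isolation_width is not None:
                    fh.write(f"isolation_width={pc.isolation_width:.6f}\n")
                if pc.charge is not None:
                    fh.write(f"charge={pc.charge}\n")
            if s.activation is not None:
                fh.write(f"activation={s.activation}\n")
            if s.faims_cv is not None:
                fh.write(f"faims_cv={s.faims_cv}\n")
            fh.write("mz intensity\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.6f}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _cv_params(element) -> Dict[str, str]:
    """name -> value of the cvParams directly under an element."""
    out: Dict[str, str] = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            out[child.get("name", "")] = child.get("value", "")
    return out


def _decode_binary_array(bda) -> List[float]:
    import base64
    import struct
    import zlib

    params = _cv_params(bda)
    text = ""
    for child in bda:
        if _local(child.tag) == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    width = 4 if "32-bit float" in params else 8
    fmt = "<" + ("f" if width == 4 else "d") * (len(raw) // width)
    return list(struct.unpack(fmt, raw))


def read_mzml(path: str, centroided_only: bool = True) -> List[Spectrum]:
    """Read an mzML file into Spectrum records.

    MS levels, precursor isolation windows and (when present) FAIMS
    compensation voltage are mapped; m/z and intensity arrays may be 32- or
    64-bit, plain or zlib-compressed base64. Precursor charge is recorded
    only when the file states it — never guessed. Profile-mode spectra raise
    ``ValueError`` when ``centroided_only`` (centroid upstream; no
    peak-picking is implemented here).
    """
    from lxml import etree

    tree = etree.parse(path)
    out: List[Spectrum] = []
    for spec_el in tree.iter():
        if _local(spec_el.tag) != "spectrum":
            continue
        sid = spec_el.get("id", "")
        params = _cv_params(spec_el)
        if centroided_only and "profile spectrum" in params:
            raise ValueError(
                f"spectrum {sid!r} is profile-mode; centroid the data "
                "before reading (no peak-picking is performed)")
        ms_level = int(params.get("ms level", 1))
        mzs: List[float] = []
        intens: List[float] = []
        precursor = None
        activation = None
        faims_cv = None
        if "FAIMS compensation voltage" in params:
            faims_cv = float(params["FAIMS compensation voltage"])
        for el in spec_el.iter():
            tag = _local(el.tag)
            if tag == "binaryDataArray":
                p = _cv_params(el)
                if "m/z array" in p:
                    mzs = _decode_binary_array(el)
                elif "intensity array" in p:
                    intens = _decode_binary_array(el)
            elif tag == "precursor":
                parent = el.get("spectrumRef")
                iso_mz = width = charge = None
                for sub in el.iter():
                    stag = _local(sub.tag)
                    if stag == "isolationWindow":
                        p = _cv_params(sub)
                        if "isolation window target m/z" in p:
                            iso_mz = float(p["isolation window target m/z"])
                        lo = p.get("isolation window lower offset")
                        hi = p.get("isolation window upper offset")
                        if lo is not None and hi is not None:
                            width = float(lo) + float(hi)
                    elif stag == "selectedIon":
                        p = _cv_params(sub)
                        if iso_mz is None and "selected ion m/z" in p:
                            iso_mz = float(p["selected ion m/z"])
                        if "charge state" in p:
                            charge = int(float(p["charge state"]))
                    elif stag == "activation":
                        p = _cv_params(sub)
                        if ("beam-type collision-induced dissociation" in p
                                or "HCD" in p):
                            activation = "HCD"
                precursor = Precursor(parent, iso_mz, width, charge)
            elif tag == "scan":
                p = _cv_params(el)
                if faims_cv is None and "FAIMS compensation voltage" in p:
                    faims_cv = float(p["FAIMS compensation voltage"])
        peaks = sorted(Peak(float(m), float(i)) for m, i in zip(mzs, intens))
        out.append(Spectrum(
            id=sid, ms_level=ms_level, peaks=peaks,
            precursor=precursor, activation=activation, faims_cv=faims_cv,
        ))
    return out


# ---------------------------------------------------------------------------
# MS^n hierarchy
# ---------------------------------------------------------------------------


@dataclass
class SpectrumTree:
    """MS1 roots with their MS2/MS3 descendants; orphans are spectra whose
    precursor chain does not reach an MS1."""

    spectra: Dict[str, Spectrum]
    children: Dict[str, List[str]]
    roots: List[str]
    orphans: List[str]

    def children_of(self, sid: str) -> List[Spectrum]:
        return [self.spectra[c] for c in self.children.get(sid, [])]

    def root_of(self, sid: str) -> str:
        seen = set()
        while True:
            s = self.spectra[sid]
            if s.precursor is None or s.precursor.parent_id is None:
                return sid
            if sid in seen:
                raise ValueError(f"cycle through spectrum {sid!r}")
            seen.add(sid)
            sid = s.precursor.parent_id


def link_hierarchy(spectra: Sequence[Spectrum]) -> SpectrumTree:
    """Build the MS1 -> MS2 -> MS3 tree from precursor references.

    Dangling or cyclic precursor references raise ``ValueError`` naming the
    offending spectrum ids; MS^n spectra whose chain does not terminate at an
    MS1 are reported as orphans.
    """
    by_id: Dict[str, Spectrum] = {}
    for s in spectra:
        if s.id in by_id:
            raise ValueError(f"duplicate spectrum id {s.id!r}")
        by_id[s.id] = s
    dangling = [s.id for s in spectra
                if s.precursor is not None and s.precursor.parent_id is not None
                and s.precursor.parent_id not in by_id]
    if dangling:
        raise ValueError(
            "dangling precursor references from spectra: " + ", ".join(dangling))
    children: Dict[str, List[str]] = {}
    for s in spectra:
        if s.precursor is not None and s.precursor.parent_id is not None:
            children.setdefault(s.precursor.parent_id, []).append(s.id)
    # cycle check + root resolution
    roots, orphans = [], []
    state: Dict[str, str] = {}
    for s in spectra:
        path = []
        sid = s.id
        while True:
            if sid in path:
                raise ValueError(
                    "cyclic precursor references among spectra: "
                    + ", ".join(path[path.index(sid):]))
            path.append(sid)
            sp = by_id[sid]
            if sp.precursor is None or sp.precursor.parent_id is None:
                state[s.id] = sid
                break
            sid = sp.precursor.parent_id
    for s in spectra:
        top = state[s.id]
        if s.id == top:
            if s.ms_level == 1:
                roots.append(s.id)
            else:
                orphans.append(s.id)
        elif by_id[top].ms_level != 1:
            orphans.append(s.id)
    return SpectrumTree(by_id, children, roots, orphans)
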