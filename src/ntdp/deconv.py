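"""Native ESI charge-state deconvolution: infer integer charges and neutral
masses from the low, narrow charge-state series of intact assemblies and of
monomers ejected from them.

Native spectra of the species this engine targets (<= 70 kDa) show a handful of
well-separated envelopes, so a greedy intensity-first search over charge
hypotheses suffices; full spectral deconvolution with harmonic suppression is
out of scope. Charging is by protons only (positive mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chem import PROTON_MASS
from .spectra import Peak

__all__ = [
    "ChargeSeries",
    "mz_for",
    "neutral_mass",
    "infer_charge_pair",
    "collapse_envelopes",
    "deconvolve_series",
    "series_report",
]


def mz_for(mass: float, z: int) -> float:
    """m/z of a neutral mass carrying z protons."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * PROTON_MASS) / z


def neutral_mass(mz: float, z: int) -> float:
    """Neutral mass implied by an m/z at charge z."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return z * (mz - PROTON_MASS)


def infer_charge_pair(mz_low: float, mz_high: float,
                      max_round_dev: float = 0.15) -> Tuple[int, int]:
    """Charges of two adjacent peaks of one species at consecutive charge
    states; returns ``(z_high, z_low)`` where ``z_high`` belongs to the
    lower-m/z peak.

    z_low = round((mz_low - p) / (mz_high - mz_low)); rejected when the
    unrounded value deviates from an integer by more than ``max_round_dev``
    charge units.
    """
    if not mz_low < mz_high:
        raise ValueError("mz_low must be strictly below mz_high")
    z_exact = (mz_low - PROTON_MASS) / (mz_high - mz_low)
    z_low = round(z_exact)
    if z_low < 1 or abs(z_exact - z_low) > max_round_dev:
        raise ValueError(
            f"no consecutive-charge solution for ({mz_low}, {mz_high}): "
            f"implied charge {z_exact:.3f} is not near an integer")
    return z_low + 1, z_low


@dataclass
class ChargeSeries:
    """A set of peaks explained as one neutral species at several charges."""

    neutral_mass: float
    charges: List[int]
    peaks: List[Peak]
    residual: float  # RMS of per-peak neutral-mass deviations, Da

    @property
    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)


def collapse_envelopes(peaks: Sequence[Peak], window: float = 1.0) -> List[Peak]:
    """Collapse isotopic envelopes to their most intense centroid.

    Peaks closer than ``window`` Th to their neighbor are clustered; each
    cluster is represented by its most intense member carrying the cluster's
    summed intensity. Series assembly then operates at charge-envelope
    resolution.
    """
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: p.mz)
    out: List[Peak] = []
    cluster = [ordered[0]]
    for p in ordered[1:]:
        if p.mz - cluster[-1].mz < window:
            cluster.append(p)
        else:
            top = max(cluster, key=lambda q: q.intensity)
            out.append(Peak(top.mz, sum(q.intensity for q in cluster)))
            cluster = [p]
    top = max(cluster, key=lambda q: q.intensity)
    out.append(Peak(top.mz, sum(q.intensity for q in cluster)))
    return out


def deconvolve_series(
    peaks: Sequence[Peak],
    max_charge: int = 30,
    tol_da: float = 1.0,
    min_members: int = 2,
    collapse_window: Optional[float] = None,
) -> Tuple[List[ChargeSeries], List[Peak]]:
    """Greedy charge-series extraction.

    Repeatedly takes the most intense unexplained peak, tries every charge
    hypothesis ``z`` for it, collects neighboring peaks matching
    ``mz_for(M, z +/- k)`` within ``tol_da`` (on the neutral-mass scale), and
    accepts the hypothesis with the most members (ties: lowest residual).
    Each peak belongs to at most one series; series need ``min_members``
    peaks (a single peak is charge-ambiguous). Returns ``(series, leftovers)``.
    """
    if collapse_window:
        peaks = collapse_envelopes(peaks, collapse_window)
    remaining: List[Peak] = sorted(peaks, key=lambda p: p.mz)
    series_out: List[ChargeSeries] = []
    skipped: List[Peak] = []
    while remaining:
        seed = max(remaining, key=lambda p: p.intensity)
        best: Optional[Tuple[int, float, List[Tuple[Peak, int]]]] = None
        for z in range(1, max_charge + 1):
            m_hyp = neutral_mass(seed.mz, z)
            members: List[Tuple[Peak, int]] = [(seed, z)]
            for direction in (-1, +1):
                k = 1
                while True:
                    zz = z + direction * k
                    if zz < 1 or zz > max_charge:
                        break
                    target = mz_for(m_hyp, zz)
                    cands = [p for p in remaining
                             if p is not seed and abs(neutral_mass(p.mz, zz) - m_hyp) <= tol_da]
                    cands = [p for p in cands if abs(p.mz - target) <= tol_da / zz + 1e-9]
                    if not cands:
                        break
                    pick = min(cands, key=lambda p: abs(p.mz - target))
                    members.append((pick, zz))
                    k += 1
            if len(members) < min_members:
                continue
            masses = np.array([neutral_mass(p.mz, zz) for p, zz in members])
            weights = np.array([p.intensity for p, _ in members])
            m_est = float(np.average(masses, weights=weights))
            resid = float(np.sqrt(np.mean((masses - m_est) ** 2)))
            key = (len(members), -resid)
            if best is None or key > (len(best[2]), -best[1]):
                best = (z, resid, members)
                best_mass = m_est
        if best is None:
            # seed cannot anchor a series (charge-ambiguous); set it aside
            skipped.append(seed)
            remaining = [p for p in remaining if p is not seed]
            continue
        _, resid, members = best
        member_peaks = [p for p, _ in members]
        charges = [zz for _, zz in members]
        order = np.argsort(charges)[::-1]
        series_out.append(ChargeSeries(
            neutral_mass=best_mass,
            charges=[charges[i] for i in order],
            peaks=[member_peaks[i] for i in order],
            residual=resid,
        ))
        remaining = [p for p in remaining if p not in member_peaks]
    leftovers = sorted(remaining + skipped, key=lambda p: p.mz)
    series_out.sort(key=lambda s: -s.total_intensity)
    return series_out, leftovers


def series_report(series: Sequence[ChargeSeries]) -> str:
    """TSV report: neutral mass, charges, member m/z values, residual."""
    lines = ["neutral_mass\tcharges\tmember_mz\tresidual_da"]
    for s in series:
        lines.append("\t".join([
            f"{s.neutral_mass:.4f}",
            ",".join(str(z) for z in s.charges),
            ",".join(f"{p.mz:.4f}" for p in s.peaks),
            f"{s.residual:.4f}",
        ]))
    return "\n".join(lines) + "\n"
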