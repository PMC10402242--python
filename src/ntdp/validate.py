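"""Isotopic-distribution validation: overlay the theoretical isotope envelope
of a hypothesized ion (exact composition when the sequence is known, averagine
otherwise) on observed centroids and score the fit.

The default fit metric is a normalized RMS on matched isotopologue
intensities with a least-squares scale factor — scale-invariant, 1.0 for a
noiseless self-generated pattern, and decreasing under a mass-shifted (wrong)
hypothesis. Cosine and chi-square alternatives are exposed for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    PROTON_MASS,
    ElementalComposition,
    IsotopeDistribution,
    averagine_composition,
    isotope_distribution,
    metal_formula_delta,
)
from .spectra import Spectrum

__all__ = ["IonHypothesis", "IsotopeFit", "fit_isotopes", "compare_hypotheses",
           "fit_report"]


@dataclass(frozen=True)
class IonHypothesis:
    """A proposed identity for an isotopic cluster.

    Provide ``composition`` when the fragment/protein composition is known;
    otherwise ``neutral_mass`` invokes the averagine model. Metal content is
    folded into the composition (metal atoms in, displaced protons out)."""

    charge: int
    composition: Optional[Mapping[str, int]] = None
    neutral_mass: Optional[float] = None
    metal_content: Tuple[Tuple[str, int], ...] = ()
    label: str = ""

    def full_composition(self) -> ElementalComposition:
        if self.composition is not None:
            comp = ElementalComposition(self.composition)
        elif self.neutral_mass is not None:
            comp = averagine_composition(self.neutral_mass)
        else:
            raise ValueError("hypothesis needs a composition or a neutral mass")
        for metal, k in self.metal_content:
            delta = metal_formula_delta(metal)
            for _ in range(k):
                add = {e: n for e, n in delta.items() if n > 0}
                sub = {e: -n for e, n in delta.items() if n < 0}
                comp = comp + add - sub
        return comp


@dataclass
class IsotopeFit:
    hypothesis: IonHypothesis
    scale: float
    fit_score: float
    detected: bool
    theoretical_mz: np.ndarray
    theoretical_intensity: np.ndarray  # scaled
    observed_intensity: np.ndarray  # matched observed (0 where unmatched)
    residuals: np.ndarray

    @property
    def n_isotopologues(self) -> int:
        return len(self.theoretical_mz)


def _match_observed(spectrum: Spectrum, mz_theo: np.ndarray, mz_tol: float
                    ) -> np.ndarray:
    mzs = spectrum.mz_array
    intens = spectrum.intensity_array
    out = np.zeros(len(mz_theo))
    if len(mzs) == 0:
        return out
    for i, mz in enumerate(mz_theo):
        lo = np.searchsorted(mzs, mz - mz_tol)
        hi = np.searchsorted(mzs, mz + mz_tol)
        if hi > lo:
            j = lo + int(np.argmax(intens[lo:hi]))
            out[i] = intens[j]
    return out


def fit_isotopes(
    spectrum: Spectrum,
    hypothesis: IonHypothesis,
    mz_tol: float = 0.02,
    prune: float = 1e-3,
    metric: str = "rms",
) -> IsotopeFit:
    """Score a hypothesized ion's isotope envelope against observed centroids.

    The theoretical distribution is charged into m/z space; each isotopologue
    above ``prune`` (relative abundance) is matched to the most intense
    observed centroid within ``mz_tol``; unmatched isotopologues count as
    zero-intensity observations. Intensity scale is least-squares. If no
    observed peak matches the base isotopologue the ion is flagged not
    detected and scores 0."""
    z = hypothesis.charge
    if z < 1:
        raise ValueError("charge must be >= 1")
    dist = isotope_distribution(hypothesis.full_composition(), prune=prune)
    keep = dist.abundances >= prune * dist.abundances.max() if prune else slice(None)
    masses = dist.masses[keep]
    abund = dist.abundances[keep]
    mz_theo = (masses + z * PROTON_MASS) / z
    obs = _match_observed(spectrum, mz_theo, mz_tol)
    base = int(np.argmax(abund))
    if obs[base] == 0.0:
        return IsotopeFit(hypothesis, 0.0, 0.0, False, mz_theo,
                          np.zeros_like(abund), obs, -obs)
    scale = float(obs @ abund / (abund @ abund))
    theo_scaled = scale * abund
    resid = theo_scaled - obs
    if metric == "rms":
        score = 1.0 - np.linalg.norm(resid) / np.linalg.norm(theo_scaled)
    elif metric == "cosine":
        denom = np.linalg.norm(theo_scaled) * np.linalg.norm(obs)
        score = float(theo_scaled @ obs / denom) if denom > 0 else 0.0
    elif metric == "chi2":
        with np.errstate(divide="ignore", invalid="ignore"):
            chi = np.where(theo_scaled > 0, resid ** 2 / theo_scaled, 0.0).sum()
        score = 1.0 / (1.0 + chi / max(theo_scaled.sum(), 1e-300))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    score = float(min(1.0, max(0.0, score)))
    return IsotopeFit(hypothesis, scale, score, True, mz_theo, theo_scaled,
                      obs, resid)


def compare_hypotheses(
    spectrum: Spectrum,
    hypotheses: Sequence[IonHypothesis],
    mz_tol: float = 0.02,
    prune: float = 1e-3,
    metric: str = "rms",
    tie_tol: float = 1e-6,
) -> Tuple[List[IsotopeFit], List[List[int]]]:
    """Fit several hypotheses against one cluster and rank them.

    Returns the fits sorted by descending score and groups of rank indices
    whose scores are indistinguishable (within ``tie_tol``) — ties are
    flagged, never silently broken."""
    if len(hypotheses) < 2:
        raise ValueError("need at least two hypotheses to compare")
    fits = [fit_isotopes(spectrum, h, mz_tol, prune, metric) for h in hypotheses]
    order = sorted(range(len(fits)), key=lambda i: -fits[i].fit_score)
    ranked = [fits[i] for i in order]
    ties: List[List[int]] = []
    group = [0]
    for r in range(1, len(ranked)):
        if abs(ranked[r].fit_score - ranked[group[0]].fit_score) <= tie_tol:
            group.append(r)
        else:
            if len(group) > 1:
                ties.append(group)
            group = [r]
    if len(group) > 1:
        ties.append(group)
    return ranked, ties


def fit_report(fits: Sequence[IsotopeFit]) -> str:
    """TSV fit report (one row per hypothesis)."""
    lines = ["label\tcharge\tfit_score\tscale\tdetected\tn_isotopologues"]
    for f in fits:
        lines.append("\t".join([
            f.hypothesis.label or "-", str(f.hypothesis.charge),
            f"{f.fit_score:.6f}", f"{f.scale:.6g}", str(int(f.detected)),
            str(f.n_isotopologues),
        ]))
    return "\n".join(lines) + "\n"
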