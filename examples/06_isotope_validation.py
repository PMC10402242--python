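"""Validate an ion hypothesis by overlaying its theoretical isotope envelope.

A holo (metal-bearing) fragment hypothesis is fitted against a simulated
isotopic cluster and compared with the apo alternative; the copper isotope
pattern (63/65) reshapes the envelope enough to separate the two.
"""

from ntdp.chem import PROTON_MASS, isotope_distribution
from ntdp.spectra import Peak, Spectrum
from ntdp.validate import IonHypothesis, compare_hypotheses, fit_report

base = {"C": 700, "H": 1100, "N": 190, "O": 210, "S": 4}
holo = IonHypothesis(charge=14, composition=base, metal_content=(("Cu", 1),),
                     label="b144+Cu")
apo = IonHypothesis(charge=14, composition=base, label="b144 (apo)")

# observed cluster: generated from the holo composition
dist = isotope_distribution(holo.full_composition(), prune=1e-3)
keep = dist.abundances >= 1e-3 * dist.abundances.max()
peaks = sorted(Peak((m + 14 * PROTON_MASS) / 14, a * 1e6)
               for m, a in zip(dist.masses[keep], dist.abundances[keep]))
spectrum = Spectrum("cluster", 1, peaks)

ranked, ties = compare_hypotheses(spectrum, [apo, holo], mz_tol=0.02)
print(fit_report(ranked))
print("ties:", ties or "none")
# fit_score 1.0 for the holo hypothesis (the data were generated from it);
# the apo hypothesis misses the +60.9 Da envelope entirely and scores 0.
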