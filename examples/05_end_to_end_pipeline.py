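"""Simulate a full native MS1/MS2/MS3 run and identify it end to end.

The simulator plants a disulfide-bridged metalloprotein homodimer with one
Cu and one Zn; the pipeline deconvolves the MS1 envelope, searches the
+/- 1 Da candidate space, checks the MS2 subunit-ejection mass accounting,
characterizes the ejected monomer from its MS3 b/y ladder and bounds the
metal-binding region.
"""

from ntdp import identify
from ntdp.search import expand_search_space
from ntdp.simulate import simulate_run, sod1_like_spec

spec, space_cfg = sod1_like_spec(seed=1)
spectra, truth = simulate_run(spec)
print(f"simulated {len(spectra)} linked spectra "
      f"({[s.ms_level for s in spectra]} MS levels)")

bundle = identify(spectra, expand_search_space(space_cfg))
for r in bundle.results:
    best = r.best
    print(f"\nobserved {r.series.neutral_mass:.2f} Da at charges {r.series.charges}")
    print(f"rank-1: {best.match.label}")
    print(f"  mass error {best.match.error_da:+.4f} Da; "
          f"MS2 support {best.ms2_support}/{best.n_distinct_subunits} subunits; "
          f"tier {r.tier}; level {r.level}")
    for res in r.subunit_results.values():
        print(f"  subunit P-score {res.p_score:.2e}, coverage {res.coverage:.3f}")
    for metal, mi in r.metal_intervals.items():
        print(f"  {metal} bound within residues {mi.lower}..{mi.upper}")
# The planted dimer + Cu + Zn is recovered at rank 1 with a significant
# P-score, and both metal intervals contain the planted coordinating sites.
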