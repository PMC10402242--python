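"""Characterize a proteoform from MS3 b/y fragments: P-score, coverage,
and localization of a PTM by bracketing fragment pairs.

A lysine-acetylated monomer is fragmented; the acetyl site is pinned by the
unshifted fragment ending just before the residue and the shifted fragment
covering it.
"""

from ntdp import characterize, generate_by_ladder
from ntdp.chem import mod_delta
from ntdp.proteoform import Proteoform, SiteMod

seq = "MKWVTFISLLFLFSSAYSRGVFRRDAHK"
truth = Proteoform("DEMO", seq, site_mods=(SiteMod(2, mod_delta("acetyl")),))
observed = [f.neutral_mass for f in generate_by_ladder(truth)]

# hypothesis: the acetyl is known from the intact mass but not yet placed
hypothesis = Proteoform("DEMO", seq,
                        site_mods=(SiteMod(0, mod_delta("acetyl"), False),))
result = characterize(hypothesis, observed, tol_ppm=10,
                      candidate_sites={"acetyl": [2, 28]})

print(f"P-score:  {result.p_score:.3e}   (probability the {len(result.matches)} "
      "matches arise by chance)")
print(f"coverage: {result.coverage:.3f}  (fraction of backbone bonds with evidence)")
for ls in result.localization:
    print(f"{ls.mod}: {ls.status} at {ls.sites}")
print(f"characterization level: {result.level}")
# Level 1 = significant P-score with every modification localized; had the
# acetyl been seen only on the intact mass, the result would be level 2A.
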