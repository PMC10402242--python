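"""Match an observed native mass against a complexoform search space.

A metalloprotein homodimer binding one Cu2+ and one Zn2+: the search space is
a base sequence with an optional N-terminal acetylation, an optional methyl,
a fixed disulfide, stoichiometry up to 2, and up to one Cu and one Zn. The
engine enumerates every subunit/metal multiset whose theoretical mass falls
within +/- 1 Da of the observation and ranks by mass error.
"""

from ntdp import enumerate_candidates, expand_search_space
from ntdp.search import match_report
from ntdp.simulate import sod1_like_spec
from ntdp.proteoform import complexoform_mass

spec, space_cfg = sod1_like_spec(seed=1)
space = expand_search_space(space_cfg)
print(f"expanded search space: {space.size} candidate proteoforms")

observed = complexoform_mass(spec.species[0].complexoform)[0]
print(f"observed neutral mass: {observed:.2f} Da")

matches = enumerate_candidates(space, observed, tol=1.0)
print(match_report(matches))
# The unique rank-1 candidate is the acetylated, disulfide-bridged homodimer
# carrying Cu x1 + Zn x1 with ~0 Da error; tier is upgraded to
# mass_and_fragments once MS3 evidence is attached (see example 05).
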