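# Methods

## Scope and model

`ntdp` identifies protein complexoforms from native MS^n data in three tiers
of evidence: intact mass (MS¹), subunit-ejection mass accounting (MS²), and
backbone fragmentation of ejected monomers (MS³). The object of
identification is the complexoform — a multiset of proteoforms plus metal
cofactors — not the protein complex: complexes of the same proteins with
different modification arrangements are distinct complexoforms and are
reported as such.

### Mass bookkeeping

Monoisotopic masses are the primary currency: the targeted species (≤ 70 kDa)
are isotopically resolved on Orbitrap-class instruments. Average masses are
computed alongside and every matching step accepts `mass_type="average"`,
because published ±1 Da intact-mass matching does not state which mass type
it uses. Element masses and isotope abundances come from the NIST tables
bundled with pyteomics; residue compositions likewise (20 canonical residues
plus selenocysteine; ambiguity codes are rejected).

Metal binding is charge-compensated by default: a divalent cation displaces
two protons, so the neutral-form mass shift is M(metal) − 2·M(H) (Cu²⁺:
+60.91395 Da, Zn²⁺: +61.91349 Da) and the observed charge of an ion remains
its protonation count. The displacement count is configurable per call.
Positive-mode proton charging uses p = 1.0072765 Da; no other charge
carriers are modeled.

### Isotope distributions

Aggregated distributions are computed by convolution of per-element
single-atom vectors binned at nominal (unit) mass, using binary
exponentiation over atom counts with optional relative-abundance pruning
between convolutions; each bin carries the abundance-weighted mean mass.
Unit-resolution aggregation matches how validation overlays are read at
isotopic (not hyperfine) resolution; there is no fine-structure mode. When a
fragment's exact composition is unknown the averagine model
(C₄.₉₃₈₄H₇.₇₅₈₃N₁.₃₅₇₇O₁.₄₇₇₃S₀.₀₄₁₇ per 111.1254 Da) is scaled to the
target, heavy elements rounded, and hydrogens balanced; the balancing target
(`kind="mono"` or `"average"`) is a parameter because both conventions are
useful — mono for decharged fragment masses, average for intact-mass
descriptions.

## Search

The search space is declared per protein (sequence or FASTA, allowed
truncations, allowed modifications with per-modification maxima, disulfide
topology, optional N-terminal modifications) plus global stoichiometry bounds
and per-metal maxima. Expansion is mass-level: modification *counts* define a
candidate; positions are deliberately left unlocalized because intact mass
cannot distinguish positional isomers. Expansion is deterministic,
duplicate-free, and capped (default 10⁶; exceeding the cap is an error naming
the offending protein).

Candidate enumeration over subunit multisets uses depth-first branch-and-bound
on the mass-sorted proteoform list: at each level the remaining-mass window
prunes both directions (the smallest eligible mass already overshoots → cut
the branch; the largest possible completion cannot reach the window → skip).
Metal multisets are enumerated outermost. Correctness is defined by
exhaustive enumeration — the test suite checks exact set equality against a
brute-force oracle on randomized spaces — and the algorithm is purely an
efficiency choice; with the stoichiometries relevant here (≤ 6 subunits)
branch-and-bound is simpler than meet-in-the-middle partial-sum tables and
fast enough by orders of magnitude.

Ranking is by |mass error|, ties broken by fewer total modifications, fewer
metals, then label. In the full pipeline two evidence terms precede the mass
error: the fraction of a candidate's distinct subunit masses observed as MS²
ejection products, and the number of its subunits confirmed by significant
MS³ characterizations. These do real work: candidates distributing the same
modification total differently across subunits are *exactly* isobaric at the
complex level and only ejection/fragment evidence separates them.

Near-isobaric candidates (e.g. trimethyl vs acetyl, Δ = 0.0364 Da) are never
silently resolved: candidates whose theoretical masses lie within 0.05 Da of
the top candidate at equal MS²/MS³ support are reported as an ambiguity
group. Intact-mass-only data cannot separate such pairs at realistic
native-MS mass accuracy, and pretending otherwise would overstate confidence;
MS³ fragments (66 ppm apart at b₄ for that pair) do separate them when
available, via the localization-refinement step below.

## Fragmentation model

Only b/y series are generated (HCD). Cleavage sites strictly inside an
intact disulfide loop are excluded by default — both backbone pieces remain
tethered — and fragments spanning a whole bridge carry its −2.0157 Da;
`reduced=True` ignores disulfides. Matching is one-to-one greedy by
ascending |ppm| (default tolerance 10 ppm, the Orbitrap norm) in neutral
monoisotopic mass space; observed fragment masses are assumed decharged
upstream (the simulator emits singly protonated fragments and the pipeline
decharges accordingly). On exact ties an apo assignment is preferred over a
holo one.

### P-score

The confidence score is the Poisson tail P(X ≥ n_matched) with
λ = n_observed · q, where q = min(1, Σ_f 2·tol·10⁻⁶·m_f / |window|) sums each
theoretical fragment's relative acceptance window over the observed mass
range, without overlap correction. The score is calibrated only as an upper
tail bound under a uniform null — the suite verifies the false-positive
fraction stays ≤ 1.5α at α ∈ {0.05, 0.01} over 10⁴ simulated null trials and
that the closed form agrees with a Monte-Carlo null within Monte-Carlo error
in a regime where the tail is measurable. The significance default is
α = 10⁻⁴.

### PTM localization

A modification carried as "anywhere" is placed by bracketing evidence,
generalized to multiple copies: each cleavage site k at which exactly one
shift multiple j·Δ of the base fragment mass is observed contributes a known
cumulative count cum(k) = j (b series directly, y series by complement).
Boundaries contribute cum(0) = 0 and cum(n) = count. If the merged profile is
monotone, every interval over which the count increments by d localizes d
copies: to exact sites when the interval contains exactly d candidate sites,
otherwise to a reported ambiguous set. Conflicting or non-monotone profiles
are flagged inconsistent; an intact-mass-only shift with no fragment evidence
is identified-not-localized. After localization succeeds, the pipeline
re-characterizes the proteoform with the modifications pinned, which adds the
shifted fragments to the theoretical ladder (improving P-score and coverage)
and is what separates near-isobaric alternatives at the MS³ level.

### Characterization levels

Level 1: significant P-score, all modifications localized. 2A: significant
P-score, ≥ 1 modification identified by mass shift but not localized (also
assigned to species identified only from their MS² ejection mass shifts,
which are additionally flagged in the result note). 2B: significant P-score
but a near-isobaric candidate set remains. 3: sequence identified,
modification count uncertain. 4: protein identified, proteoform not (also
the fallback for insignificant P-scores). 5: mass-only observation.

### Metal localization

Metal retention during HCD is modeled all-or-none per fragment. A holo bᵢ
implies every coordinating residue of that metal lies in 1..i (upper bound =
min holo b index); an apo-only bⱼ implies at least one coordinating residue
lies in j+1..n (lower bound = max such j + 1); y-series evidence maps
symmetrically into sequence coordinates. The per-metal intersection is
reported, or flagged inconsistent when empty. The interval is a bound on the
binding *region*, not an enumeration of sites.

## Simulator

The generator emulates the native MS^n cascade: MS¹ charge envelopes at
(M + z·p)/z collapsed to one centroid per charge state; MS² subunit ejection
with exact mass/charge conservation and asymmetric charge partitioning
(z_monomer = ⌈z·(m/M) + 2⌉, clamped — the +2 bonus reproduces the observed
12+ trimer → 6+ monomer pattern; a per-species override exists because a
dimer ejecting at 6+ from 11+ sits below the rule's output); MS³ b/y ladders
of each distinct ejected monomer thinned by a per-fragment detectability
probability, with decoy peaks drawn uniformly over each spectrum's m/z range.

Fragments that straddle a metal's coordinating set — span a non-empty strict
subset of it — are suppressed entirely: under all-or-none retention such ions
are neither cleanly apo nor holo. This is also what makes the holo/apo
interval logic self-consistent for spatially spread coordination sets (a
complete apo ladder up to a site would otherwise push the lower bound past
shallower sites).

Default study conditions: m/z noise σ = 0.002 Th (Orbitrap centroid
precision; at MS³ fragments this is ~2 ppm, at native MS¹ charges it leaves
the envelope-averaged neutral mass well inside ±1 Da), 5% multiplicative
intensity noise, fragment detectability 0.95, 5 expected decoys per MS^n
spectrum. All randomness flows from one seed; identical seeds give
byte-identical outputs.

The four standard fixtures are built from **synthetic sequences engineered to
the worked-example geometry** (they are not the human proteins): a 235-residue
monomer whose doubly deamidated homodimer has monoisotopic mass 53,070.9 Da
(15+/16+ at m/z ≈ 3319/3539) with deamidation sites at N15/N71; a 111-residue
monomer whose trimer combinations fall in the 12+ m/z 3080–3100 window, with
an acetylation site at K77 and a nitrosylation site at C80; a 153-residue
metalloprotein with cysteines only at 57/111 (one disulfide), Cu sites at
His 46/48/63/120 and Zn sites at 63/71/80/83, simulated with metals riding
the ejected 6+ monomer; and a 126-residue Met-cleaved monomer with lysines at
processed positions 4/55/63 carrying combinatorial
acetyl/methyl/dimethyl/trimethyl options, one planted dimer of which is
simulated without MS³ to exercise the MS²-shift-only (level 2A) path and the
acetyl-vs-trimethyl ambiguity reporting.

What the simulator does *not* emulate: profile peak shapes and detector
saturation, chromatographic/FAIMS separation (compensation voltage is carried
as metadata only), electrospray adducts other than protons, metal scrambling
or partial retention, internal fragments and neutral losses, and realistic
intensity structure of fragment ladders. Passing tests therefore demonstrate
the correctness of the inference logic under the stated noise model, not
instrument-grade robustness on raw data.

## Numerical choices and edge cases

- Deconvolution is greedy intensity-first over charge hypotheses with a
  neutral-mass consistency tolerance; a single peak is charge-ambiguous and
  is returned as a leftover rather than assigned. Isotopic envelopes can be
  collapsed to their top centroid with a configurable window before series
  assembly. At m/z noise σ = 0.05 Th the per-peak neutral-mass noise is
  z·σ (~0.9 Da at z = 18), so mass accuracy is quoted as the envelope
  average; the Monte-Carlo mean error stays below 1 Da for ≤ 70 kDa species
  while individual replicates can exceed it — an arithmetic fact about the
  noise model, not an algorithmic limit.
- Consecutive-charge inference rejects pairs whose implied charge deviates
  from an integer by more than 0.15 charge units.
- The isotope-fit score is 1 − ‖s·t − o‖/‖s·t‖ with least-squares scale s,
  clamped to [0, 1]; it is scale-invariant, exactly 1 on self-generated
  noiseless patterns, and 0 with a "not detected" flag when the base
  isotopologue has no matching centroid. Cosine and χ² metrics are available
  as alternatives. Hypotheses within a configurable score difference are
  flagged indistinguishable rather than tie-broken.
- Residue numbering is 1-based on the observed (processed) sequence after
  truncation/Met cleavage, with `canonical_position()` mapping back; this
  matches how modification sites on processed proteins are reported, and the
  dual coordinates resolve off-by-one disagreements with literature numbering
  without taking sides.
- Profile-mode mzML is rejected with an explicit error; no peak-picking is
  implemented. mzML reading is implemented directly over lxml (spectrum
  walk, cvParam names, base64/zlib 32/64-bit arrays) and validated against
  the package's own standard-conforming writer.

## Known limitations

- Fragment charge states: MS³ matching assumes decharged neutral masses; no
  internal deisotoping/decharging of multiply charged fragments is provided.
- Multiple unlocalized copies of *different* co-occurring modifications are
  localized independently per modification name; interactions between
  simultaneous unknown placements are not modeled.
- The P-score null ignores window overlap and intensity information.
- Quantitation is presence/absence plus raw intensity ratios across runs; no
  normalization.
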