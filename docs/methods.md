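# Methods

## The design problem

Arrayed deterministic mutagenesis builds each variant of a gene as its own
linear transcription unit (promoter → CDS(s) → polyA signal) by two rounds
of PCR, so that variant identity is tracked purely by well position. One or
more *target regions* (TRs) — a codon or a cluster of nearby codons within
a 12-nt span — are replaced by enumerated payloads. The package models the
whole pipeline: oligo design, reaction planning, plate bookkeeping,
in-silico verification of every product, and scoring of the downstream
multiwell screen.

## Primer design rules

A forward mutagenic primer is `5'-flank + payload + 3'-anneal arm`: the 5'
flank copies the template immediately upstream of the TR, the payload
encodes the edit, and the 3' arm matches the template immediately
downstream. Its non-mutagenic counter primer is the reverse complement of
the template window ending immediately 5' of the TR, so the counter's
reverse complement is a prefix of every sibling mutagenic primer in a
saturation array — that shared region is the overlap that fuses adjacent
amplicons in the secondary PCR. The mirror-image (reverse-mutagenic)
orientation is supported and used at the right-hand end of per-permutation
middle segments.

Arm lengths are either explicit or chosen automatically: start at 18 nt and
grow one base at a time until the duplex melting temperature of the
flank/overlap reaches the 60 °C floor of the 60–66 °C window; lengths above
24 nt raise a warning and set a `tm_extended` flag on the primer (published
arrays themselves use a 30-nt AT-rich arm where annealing demands it), and
40 nt is a hard stop. A window violation on the high side at minimum length
warns rather than errors — arms are never shortened below 18 nt. The window
is applied to the counter/mutagenic overlap and to the 3' anneal arm
independently. One caveat of auto mode: the overlap between two adjacent
amplicons joins exactly when the counter window and the partner's 5' flank
have consistent lengths, which auto mode guarantees by deriving both from
the same template window; when lengths are given explicitly, give the
counter at least the partner's flank length.

Melting temperatures use the unified nearest-neighbor parameter set with an
entropic monovalent-salt correction (50 mM monovalent cation, 500 nM oligo,
the primer-in-excess convention). The protocol's source does not state
buffer conditions for its Tm window, so method and concentrations are
configurable and recorded in run metadata. Payload codons come from an
explicit 20-entry codon-choice table; the default (`midas-paper`) is the
codon set read off the published D108/L560 saturation arrays. Degenerate
codons are deliberately out of scope — the method's point is enumeration.

### Tags and monotemplated designs

When all primary PCRs share one plasmid template, the outer primers of the
secondary PCR would also amplify residual plasmid carried over from the
unpurified primaries, regenerating parent genes. The fix is a 5' tag on the
Fo and/or Ro outer primer — a sequence absent from every template — plus
nested primers (Fo'/Ro') that prime only on the tag. Generated tags are
seeded 23-mers at 40–60 % GC screened by exhaustive substring match: no
exact shared substring of ≥ 12 nt with either template strand. Nested
primers default to exactly the tag, with an optional inward extension. The
synthetic-template generator rejection-samples templates containing the
default tag so uniqueness tests are meaningful.

## Assembly schemes

For *i* TRs too far apart to share an oligo, the **per-segment** scheme
runs *i*+1 segments (one constant leftmost segment, one mutagenic segment
per TR) and forms secondaries from the cross product of per-TR amplicon
choices: primary count = 1 + Σ|variants|, secondary count = Π|variants|.
The **per-permutation** scheme instead builds one middle primary per full
permutation, carrying the left TR's payload in its forward primer and the
right TR's payload in its reverse primer, flanked by two constant segments:
Π|variants| primaries, one-to-one secondaries. Both schemes provably
produce the same final sequence set (a property test asserts it); they
trade primary-PCR count against combinatorial liquid handling. The
implementation limits per-permutation planning to two TRs, the case the
scheme was described for. TRs closer than 60 nt cannot carry independent
primer pairs and are merged into a single TR-spanning payload set (cross
product of the two payload lists) when the merged span permits.

## In-silico PCR

Priming requires an exact match of the primer's 3'-terminal *k* bases
(default 15) to the template; the product carries the full primer at each
end, which is how payload mismatches and 5' tags enter products.
Mismatch-tolerant priming is out of scope: outside payloads, all primers
are template-exact by construction. All distinct products over all
primer-site pairs are returned, so multi-site priming surfaces as multiple
products instead of being silently resolved. Amplicons join by unique
maximal exact suffix–prefix overlap of ≥ 18 nt (searched below a 200-nt
cap); an end that could join two different partners raises an error.
Residual plasmid in a secondary reaction is modeled as a boolean (the
wet-lab dilution factor has no in-silico analogue): with it on, untagged
outer primers yield both the assembled mutant and the reamplified parent,
while tag-nested primers yield only the mutant and produce nothing from raw
plasmid.

## Library economics

The chance that error-prone PCR delivers a specific multi-base codon change
in a still-functional clone is modeled as
`(rate × functional)ⁿ × Π(aᵢ/4) × m`: per-nucleotide mutagenesis rate times
the functional fraction at that rate, raised to the number of required
changes, times the probability each mutated base lands on an acceptable
base, times the number of distinct codon paths. The published convention
takes the base-choice probability as aᵢ/4; an optional strict mode uses
aᵢ/3 (a mutation cannot reproduce the original base) and is clearly labeled
as a sensitivity variant. "1 in N" figures are rounded to one significant
figure below 10⁵ and two above, matching how such numbers are quoted; both
raw and rounded values are returned. Degenerate (NNS/NNK) library sizing is
`32ᴾ × oversampling` (default ×10 for ~99 % coverage against Poisson
sampling); arrayed well counts are the plain product (combinatorial) or sum
(independent sites) of substitution-set sizes. Fold figures are returned
exact, rounded, and floored, since quoted "x-fold" values use either
convention.

## Screen scoring

Raw well signals are first divided by a co-expressed reference-reporter
signal from the same well; because both reporters ride the same transfected
product, per-well transfection-efficiency differences cancel exactly (the
simulator plants such a confounder to prove it). Responses are expressed
against the vehicle control as fold change or percent increase
(percent = (fold − 1) × 100). Technical replicates are averaged after
normalization.

Per-site mutational tolerance is the mean and the sum of the 20 variant
activities relative to wild type; the mean is the headline (scale-free),
the sum is reported alongside, and the wild-type identity cell is included
by default because it appears in the arrays as the identity payload (a flag
excludes it). Specificity analysis censors any variant whose activity is
*strictly* below 25 % of parent on any substrate — low-signal wells have
high CVs, and ratios of noisy small numbers propagate error — then scores
preference of substrate X over Y as the ratio (default; a difference
statistic is available) of parent-relative activities. Preferences are
antisymmetric (pref(X,Y)·pref(Y,X) = 1). A variant is *called* as
preferring X when its preference over every other substrate exceeds a call
threshold; the default (1) flags any imbalance, and recovery tests raise it
to the geometric midpoint between the null ratio and the smallest planted
effect so chance calls among equivalent variants are suppressed.

Dose-response data are fit with the variable-slope four-parameter logistic
on log dose, `y = bottom + (top − bottom)/(1 + 10^((log₁₀EC₅₀ − log₁₀x)·h))`,
by bounded least squares. Initialization: bottom/top from the response
extremes, EC₅₀ at the dose nearest the half-range crossing, hill = 1; EC₅₀
is bounded three decades beyond the sampled range. Non-convergence is
reported in the result object, never swallowed. Zero-dose (vehicle) wells
are handled by normalization upstream, not passed to the fitter.

## Synthetic data: what it does and does not emulate

The generator produces random transcription units (ATG-initiated, stop-free
CDS, seeded, default 900-nt CDS with 200-nt promoter and 100-nt polyA
regions) and can embed a published local-template fragment so that
designing on the synthetic unit regenerates printed oligos byte-for-byte —
the round-trip that anchors the design code to real reagents. Screen
simulations plant per-variant true activities (tolerant sites ~1,
intolerant ~0, others intermediate), per-substrate scale factors, per-well
lognormal transfection multipliers (σ = 0.3), and lognormal measurement
noise at a chosen CV (default 5 %, 3 technical replicates, 4 parent-control
wells — plates routinely carry a control column, and averaging it keeps
parent-normalization noise below per-variant noise). Problem sizes used in
tests and the acceptance script (a 20 × 20 two-site design, 10-site
screens) were chosen as representative working scales for this class of
experiment. The simulators do not emulate luminescence photon statistics,
plate-reader drift, edge effects, or PCR failure modes; passing recovery
tests therefore shows the scoring pipeline is correct and noise-robust at
assay-like CVs, not that any particular wet-lab screen will reach the same
power. Published biological constants (a 898 µM dissociation constant, 22 %
→ 640 % responsivity) appear only as scenario constants in simulations and
documentation examples; the raw well data behind them are not public, so
they are never asserted as computed outputs.

## Known limitations

* Forward-strand, intron-free CDS features only; no multi-exon coordinate
  mapping.
* No primer-dimer/hairpin screening and no thermodynamic PCR kinetics —
  priming is a boolean exact-match model.
* Per-permutation planning covers one or two TRs.
* The printed D108W array member is one template base short of its 19
  siblings; the fixture stores the regularized sequence, keeps the verbatim
  string, and flags the discrepancy rather than reproducing it.
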