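# Methods

## Likelihood-ratio calibration

A truth dataset pairs each variant with a prediction score in [0, 1] and
a binary spliceogenicity label (variants with intermediate or
uninterpretable assay outcomes are excluded before calibration).  For a
score bin the likelihood ratio of spliceogenicity is the ratio of in-bin
proportions between the spliceogenic and non-spliceogenic classes.  The
95% interval uses the log method for diagnostic likelihood ratios
(Simel-style): `se(ln LR) = √((1−p⁺)/n⁺_in + (1−p⁻)/n⁻_in)` with
z = 1.96.  This estimator reproduces, from the published bin counts of
the 8-gene curated truth set (2246 non-spliceogenic / 491 spliceogenic),
all six printed confidence bounds of the three-bin calibration table, so
it is adopted as the reference method.  One display caveat: the middle
bin computes (38/491)/(175/2246) = 0.993, which is reported elsewhere as
1.00; the package reports the computed value.

When either in-bin count is zero a 0.5 continuity correction is added to
all four cells (in/out for both classes) and the result is flagged; a
band with no records in either class returns an undefined, flagged
result rather than a number.

### Strength mapping

LRs map to ACMG/AMP categories through odds-of-pathogenicity boundaries
at a prior of 0.10: Very Strong 350, Strong 350^(1/2) ≈ 18.71, Moderate
350^(1/4) ≈ 4.33, Supporting 350^(1/8) ≈ 2.08; benign boundaries are the
exact reciprocals.  Pathogenic categories are inclusive at their lower
boundary and benign categories at their upper boundary, matching the
"≥ high / ≤ low" bin conventions.  An optional conservative gate demotes
a category one level when the relevant CI bound (lower for pathogenic,
upper for benign) does not clear the next weaker category's boundary;
for Supporting the floor is 1.0 and the demotion lands on Uninformative.
The boundaries are configurable through `StrengthThresholds`.

### Cut-off optimization

`optimize_cutoffs` searches the full (low, high) grid (step 0.01 by
default) minimising

```
w_fn · FN_rate + w_fp · FP_rate + w_uninf · uninformative_fraction
```

where FN_rate is the fraction of spliceogenic variants scoring ≤ low,
FP_rate the fraction of non-spliceogenic variants scoring ≥ high, and
the uninformative fraction is pooled over all variants.  Default weights
are (1, 1, 0.5).  The uninformative weight is strictly below the error
weights deliberately: this is a reject-option classification, and with a
rejection cost equal to the misclassification cost the reject region is
degenerate (Chow's condition).  Concretely, the middle score band of a
calibrated predictor has LR ≈ 1 by construction, so under equal weights
the marginal cost of moving a cut through that band is ≈ 0 and the
argmin is decided by sampling noise; at 0.5 the published cut-offs
(0.1, 0.2) are a strict optimum on bin-consistent data with comfortable
per-step margins.  Exact ties break toward the wider uninformative zone
(more conservative), then toward the smaller low cut.  On uniform
within-bin resamples of the truth table the recovered cut-offs still
carry about one grid step of sampling noise — an inherent property of
the near-flat objective, not of the search.

### Sensitivity bands and stratification

`band_lrs` evaluates LRs over arbitrary non-overlapping score intervals
(closed; records on a shared edge go to the first matching band), used
for sensitivity analysis near the cut-offs.  `stratified_calibration`
repeats the three-bin calibration per stratum (by default the splice
region category) at fixed cuts; strata with no usable records are
skipped with a warning.  The narrow-band LRs and region-stratified
sensitivity/specificity published for the full curated dataset require
the underlying per-variant dataset and are therefore not reproduced by
the bundled fixture, which only encodes the printed three-bin margins.

## Region classification

Coordinates are 1-based fully closed (GTF convention); offsets are
HGVS-style in transcript orientation (donor: last exonic base −1, first
intronic +1; acceptor: first exonic base +1, adjacent intronic −1).
Windows default to U2-type GT-AG introns — canonical ±1,2; standard
donor 3 exonic + 6 intronic, acceptor 1 exonic + 20 intronic; minimal
acceptor 3 intronic — and are configurable per intron (e.g. a 1 + 9
donor window for U12-type introns).  Classification tests membership in
the windows on *both* flanks of an intron, not just the nearest, so a
position at donor +12 of a 30-nt intron is correctly recognised as
acceptor −19 standard-region.  Multi-nucleotide variants take the class
of the most motif-proximal affected base (a deletion spanning a
canonical dinucleotide is canonical); insertions affect their anchor
base and the base following it.  Terminal exons have no donor
(last exon) or acceptor (first exon) side; a single-exon transcript
reports side NONE.  Exact donor/acceptor ties resolve to the donor side.

BP7 position eligibility: intronic at or beyond +7 / −21 (standard mode;
−4 in minimal mode) and outside the designated region, or synonymous
exonic outside the first base and last three bases of the exon.
Conservation is intentionally not an input.

## PVS1 decision tree

Ordering of the checks: loss-of-function mechanism gate (raises,
pointing to PM4, when LoF is not established) → no-impact prediction →
UTR-confined outcome → rescue transcript → start-loss → frame logic.
Out-of-frame with predicted NMD scores full PVS1; NMD uses the 50-nt
last-junction rule upstream of the engine (the prediction carries an
`nmd_predicted` flag rather than re-deriving it).  Without NMD, and for
in-frame outcomes, the weight is Strong when the removed/truncated
region is critical or exceeds the protein-size threshold (default 10%),
Moderate otherwise, and upweights to full PVS1 when the removed critical
region contains a Pathogenic missense variant or the complementary
splice site of the same exon carries Pathogenic variation.  Criticality
can be asserted as a flag or derived from coding-coordinate overlap with
configured critical domains; with only the flag, the context's
domain-level missense annotations are taken to describe the asserted
region.  Start-loss outcomes score Moderate, upgraded to Strong only via
an explicit per-gene flag (alternative-start-frame inference is out of
scope).  A rescue transcript voids the code when it skips (at least) the
affected exons, encodes a functional protein, and is expressed at or
above the operational threshold of 10% of gene expression; all three
conditions are configurable.

## RNA assay evidence

A read-out with no aberrant transcripts relative to matched controls
yields a BP7_Strong(RNA) signal.  Otherwise each observed aberration is
scored through the tree and pooled: grouping transcripts by strength and
walking from the strongest group down, the overall strength is the group
at which the cumulative aberrant contribution first reaches the
complete/near-complete threshold (default 0.90 of variant-allele
expression; gene- and assay-specific refinement is expected).  If the
aberrant transcripts never reach the threshold the read-out is leaky and
the strongest aberrant strength is demoted one level with a LEAKY flag —
the conservative reading when full-length transcript dominates, chosen
over returning a blanket N/A so that near-threshold profiles are not
discarded outright.  Construct-only evidence (minigene/MPRA, or controls
not from matched tissue) demotes one further level.  Demotions floor at
N/A.

## Code assignment and combination

PP3/BP4 use the calibrated cut-offs on the maximum delta score and are
applied at supporting weight by default even though the calibration
reaches moderate (the conservative application; moderate is selectable).
Computational BP7 requires BP4 plus position eligibility.  PS1 transfers
evidence from a comparator variant only when the predicted events match
exactly (type, exons, cryptic position) and the VUA's prediction is
within a 0.05 score tolerance of the comparator's (the similarity
requirement is not quantified at source; 0.05 on a [0, 1] score is this
package's choice and is configurable).  The weight matrix depends on the
VUA's location (canonical vs not), its baseline PVS1 weight, the
comparator's relative position, and the comparator's classification;
Likely Pathogenic comparators at canonical positions require an explicit
clinical-support flag.  "Within the same motif" is asserted by the
caller (two region classes alone cannot identify the physical site).

Combination: canonical variants follow the PVS1 path only (PP3/BP4
suppressed with reasons); an assay-derived PVS1(RNA) replaces PP3/BP4; a
no-impact assay yields BP7_Strong(RNA) and supersedes computational
BP4/BP7 for intronic and synonymous variants, but for missense/in-frame
variants without protein-level functional data the splicing result is
recorded as text only and the most deleterious prediction is retained;
PS3/BS3 are always suppressed for splicing evidence.  Contradictory RNA
inputs raise an error rather than emit codes.  Every suppression carries
its reason and is logged.

## Synthetic data

The generator draws class-conditional scores from Beta distributions
fitted once to the curated truth set's three-zone margins — negatives
Beta(0.22, 5.40), positives Beta(0.58, 0.43), reproducing 87%/95% of
negatives below 0.1/0.2 and 15%/22% of positives — plus a deterministic
fixture that reproduces the printed zone counts exactly (scores evenly
spaced inside each zone, closed edges included) and a resampled variant
that keeps the counts but draws scores uniformly within zones.
`generate_from_bin_probs` gives datasets with a known generating LR per
bin for estimator-recovery checks.  These instruments emulate the truth
set's class balance and zone structure only; they do not model
motif-position effects, gene identity, score clumping at 0/1 beyond the
Beta shapes, or correlated assay errors, so passing tests demonstrate
estimator and rule correctness, not predictor performance on real data.

## Problem sizes and numerics

The estimator-recovery runs use 200 replicates of n = 10,000 (1800
spliceogenic / 8200 non-spliceogenic, the truth set's class mix), sized
to estimate a ~95% coverage rate to about ±1.5 points while keeping the
whole suite fast.  Tie-breaking, boundary inclusivity and degenerate
inputs are handled as above; LR/CI values are reported to 2 decimals in
summaries, full precision in code.  Seeds derive from a single
user-supplied seed and stay below 2³¹.

## Known limitations

Intron-type detection (U12, GC-AG) is out of scope — window overrides
are manual.  NMD escape beyond the boundary flag, automatic
critical-domain discovery, tissue-expression retrieval and final 5-tier
classification are out of scope by design.  The PS1 motif identity and
the "same aberration type and level" matching for transferring
experimental PVS1 weights are exact-match rules; biological similarity
judgements remain with the curator.
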