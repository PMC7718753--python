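# Methods

## Model

The package encodes three findings about dCas9-activator recruitment at
promoters as a deterministic scoring rule over candidate SpCas9 guides:

1. **Placement relative to the TSS dominates.** Activation is strongest for
   guides landing between -450 and -150 bp upstream of the TSS, moderate in
   the flanking stretches (down to -600 bp and from -150 bp up to the TSS),
   and absent beyond -600 bp or downstream of the TSS. The position score is
   therefore piecewise constant — 1.0 / 0.5 / 0.0 — and multiplies the rest
   of the score, so a guide past the cutoff scores zero regardless of its
   other properties (a 75%-GC guide beyond -600 bp still scores 0).
2. **Spacer GC content correlates monotonically with activation**, and the
   arrangement of G/C bases within the spacer does not matter. The GC score
   is the GC fraction itself; no intra-spacer positional weighting is
   offered, deliberately mirroring that negative result.
3. **Guides whose spacer pairs with the non-template strand outperform
   template-strand guides**, so NT-class candidates receive an additive
   bonus inside the weighted sum.

Composite: `S = P(d) * (w0 + w_gc*gc + w_nt*nt)` with nonnegative weights
summing to 1. The underlying evidence is ordinal (phenotype classes,
relative luminescence), not metric, so the flank value 0.5 and the default
weights (0.2, 0.6, 0.2) are design choices, constrained to make the three
findings hold structurally: dominance (P = 0 forces S = 0, and any placed
candidate scores at least 0.5 * w0 = 0.1), strict GC monotonicity wherever
P > 0 (slope P * w_gc), and a strict NT margin of P * w_nt. All three are
exposed in `DesignConfig` and property-tested rather than fitted.

A smooth positional kernel was considered and rejected: the evidence
supports a window plus an optimum, not a functional form. The -200 bp
optimum enters only as the ranking tie-break (smaller |d + 200| wins at
equal score), followed by GC, NT-before-T, contig coordinate, and strand —
a total order, so output is independent of input order.

## GC-to-fold calibration

`predicted_fold_activation` interpolates log-linearly between two measured
anchor points — 2-fold activation at GC 0 and 35-fold at GC 0.9:
`fold(g) = 2 * (35/2)^(g/0.9)`. Log-linear because fold-changes are
ratio-scale quantities and two anchors are the only reliable numbers
available; intermediate values are indicative, not fitted, and values above
GC 0.9 are extrapolations flagged `extrapolated_gc`. The curve is reported
alongside the score, never used for ranking.

## Conventions

* Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
  and BED (0-based half-open) are converted at the I/O boundary only. The
  TSS of a minus-strand GFF3 feature is its `end` coordinate.
* Distance d is measured to the PAM-proximal base of the protospacer. No
  published reference point exists for this axis; any fixed choice differs
  by at most 22 bp, small against the 150-300 bp granularity of the score.
  `midpoint` and `five_prime` are available via `distance_reference`.
* Strand classes name the DNA strand the spacer base-pairs with: NT means
  the spacer hybridizes with the non-template (coding) strand, which puts
  the protospacer on the template strand. The opposite ("protospacer
  identity") reading would invert the labels; the convention is echoed in
  the report metadata to prevent silent misuse.
* Each distinct TSS of a gene gets an independent design run; distances are
  only meaningful per-TSS.
* Candidates are enumerated in a window of `upstream_bp + downstream_bp`
  around the TSS plus a margin of `spacer_len + |PAM| - 1` bp so
  protospacers straddling the boundary are found; after annotation,
  candidates outside `[-upstream_bp, +downstream_bp]` are discarded.
  Windows clipped at contig edges are flagged `truncated_window`.
* Spacers containing N are dropped (undefined GC, unsynthesizable);
  spacers containing TTTT are flagged by default (`polyt_filter=flag`),
  because U6-driven cassettes terminate at T runs — flagging informs
  without second-guessing; `drop` and `off` are available.

## Synthetic fixtures

`make_fixture` builds one contig per gene (strands alternate) and plants
protospacers with exact distance, GC count and strand class. Background
sequence is i.i.d. with P(G) = P(C) = background_gc/2 (default panels use
0.4, a typical promoter-region composition), but GG and CC dinucleotides
are rejected, so no incidental NGG PAM — on either strand — exists outside
the planted footprints. Planted spacers alternate G/C and A/T for the same
reason; since GC placement within the spacer is scoring-irrelevant, any
arrangement with the intended count is a faithful plant. Junction bases
that would complete a PAM are neutralized to A, and every gene is verified
by re-scanning with the production scanner; a collision triggers background
resampling (25 attempts, then a hard error). The result is exact ground
truth: the re-scan finds the planted candidates and nothing else.

What the fixtures do **not** emulate: real promoter composition (CpG
skew, repeats), overlapping genes, chromatin accessibility, measurement
noise, or off-target sites elsewhere in the genome. Passing tests
demonstrate that the implementation applies the stated criteria exactly —
not that the criteria themselves generalize beyond the system they were
measured in.

`make_panel` derives three sub-seeds (below 2^31) from one seed and emits
the canonical comparisons: a five-step GC ladder in the optimal window
(GC counts 2–18), an in-window 45%-GC guide versus a 75%-GC guide at
-700 bp scanned with an 800 bp window so the decoy is enumerated and scored
zero, and an NT/T pair of equal GC at -190/-210 bp.

## Numerical and degenerate-input choices

* Weight-sum validation uses a 1e-9 tolerance; calibration anchors are
  reproduced exactly (pure closed-form evaluation, no fitting).
* The optimal window is a closed interval; d = 0 (the TSS base) scores 0,
  taking the downstream finding over flank membership for that single point.
* Per-gene failures (missing contig, no PAM in window, all candidates
  dropped) produce explicit per-record entries and never abort a batch run;
  the CLI exits nonzero only when no gene succeeds. An empty genome set is
  a hard error.
* TSV/BED output is byte-deterministic: fixed column order, fixed decimal
  formatting (GC and composite to 4 decimals, fold to 2), rows ordered by
  the ranking's total order, genes by sorted TSS record.

## Problem sizes

The test suite scans 200 random 1-kb windows against an independent regex
oracle, checks dominance on 1000 random candidate pairs, and re-derives the
panel outcomes on 100 seeded replicates (300 panels); the whole suite runs
in well under a minute on one CPU. These sizes give exhaustive coverage of
the piecewise score's breakpoints and dense coverage of the scanner's input
space while keeping the suite fast to iterate on.

## Known limitations

* No off-target or genome-wide uniqueness assessment — candidates are
  judged only within their promoter window.
* No machine-learned on-target efficacy model, secondary-structure/ΔG
  term, or chromatin-accessibility features; the score is deliberately the
  minimal rule set the evidence supports.
* Only NGG-class PAMs via the IUPAC `pam` field; extended PAM sets are a
  config knob, not a default.
* The fold-activation calibration carries the measurement system it came
  from (luciferase reporter, S2 cells); treat it as an ordering hint, not a
  prediction for arbitrary loci.
* Whether the two flank regions differ in efficacy is unresolved; both
  receive the same `flank_score`.
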