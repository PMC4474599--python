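# Methods

## Candidate-substrate calling

The screen's discovery rule is deterministic presence/absence, and the
package reproduces it as such (no SAINT/CompPASS-style probabilistic
scoring): a protein is a candidate iff it is *identified* in at least
`min_bait_runs` bait purifications and in zero negative-control
purifications. "Identified" is operationalized as TSC ≥
`presence_threshold` (default 1): the upstream search pipeline already
imposed a two-unique-peptide, <5% peptide-FDR identification filter
before counts were summarized, so presence in the matrix is presence
of an identification. The threshold is exposed for stricter
reanalysis. Control detection uses its own threshold (default 1 —
any control evidence disqualifies).

Family exclusion generalizes the HLA rule (two HLA alleles were
dropped because *other* HLA alleles appeared in controls): exclusion
groups are user-supplied protein-id sets; if any member is
control-detected, every member is excluded with the reason recorded.
The behavior is defined only by that example, so groups are explicit
input rather than inferred homology.

Runs carry a condition label (e.g. MG132 / noMG132). Calling defaults
to pooling all runs of the named bait, matching the main three-run
analysis; a `condition` filter in `CallingConfig` restricts to one
label. Whether background averaging should span all control runs or
per-bait controls is not prescribed; the default uses all control
runs, which is also what the enrichment score assumes.

With zero control runs the control-absence clause is vacuously true;
this degraded mode warns rather than failing, because the fixture's
printed table (bait columns only) is a legitimate input.

### Enrichment score and NSAF

The enrichment score is mean(bait TSC) / mean(control TSC). A zero
background would divide by zero; the control mean is floored at a
pseudocount (default 0.5, i.e. "less than one count over two control
runs"). Pseudocount 0 requests the flagged-infinite behavior
("unique to bait") instead of an error.

NSAF for protein *i* in a run is (SpC_i/L_i) normalized over all
proteins with nonzero counts in that run, ×10⁵ for readability.
Conservation (sum = 10⁵ per run) is exact up to floating-point
summation and is property-tested at 10⁻⁶ relative tolerance.

Candidate ranking sorts by total bait TSC (descending), then
enrichment score, then protein id — a stable, permutation-invariant
order matching the abundance ordering of the printed table.

## Degron model

The relaxed βTRCP consensus is DpSG-X(1–4)-pS with acidic residues
tolerated in place of phosphoserines. No numeric score exists in the
source material; the weighted class model here is this package's own
construction, chosen so the canonical DSG…S arrangement outranks
acidic variants (DDG/SDG/SSG…), which is the qualitative ordering
implied by which motifs are described as near-consensus. Weights:

| position | class | weights |
|---|---|---|
| p1 | D, E, S, T | 1.0, 0.8, 0.6, 0.6 |
| p2 | S, T, D, E | 1.0, 0.9, 0.8, 0.8 |
| p3 | G (anchor) | required, not scored |
| spacer | any, length 1–4 | +0.05 per D/E/S/T residue, capped +0.2 |
| p_last | S, T, D, E | as p2 |

Scores are bounded by 3.2. Windows overlapping in sequence are all
reported; a span readable under more than one grammar is reported once
under its best interpretation.

Two printed degrons fall outside the glycine-anchored grammar:
DGDFFSYT (ALDH2, a false positive — glycine transposed into position
2) and DTTFLLD (UBE4B — no glycine at all). The default model
therefore also admits **glycine-less windows** (p1-p2-spacer-p_last) at
a flat 1.0 penalty, reported as class `relaxed`. The penalty exceeds
the largest possible bonus spread, so a relaxed window can never
outscore a glycine-anchored window over the same neighborhood, and
poly-degenerate background sequence stays far below canonical scores.
DGDFFSYT still fails by default (its position-2 glycine is outside the
p2 class), consistent with its false-positive status; an optional
transposed-glycine mode (`allow_transposed_g`) matches it on request,
also as `relaxed` and penalized.

`best_degron` picks the highest score, breaking ties toward the
smaller spacer and then the earlier start — the shortest, most
N-terminal of equally good windows. For proteins with several listed
motifs the scan reports all of them and `best_degron` is a score
decision; adjacent overlapping consensus stretches (the CReP region
has a second, weaker downstream site) appear as separate overlapping
hits rather than one merged super-degron.

Positions are 1-based inclusive. Phospho-status is not modeled; S/T
are treated as potential phospho-acceptors on unmodified sequence.

### Ortholog comparison

Degron conservation is assessed alignment-free: the reference species'
best-degron window, extended by a 10-residue flank, is located in each
ortholog by best sliding (Hamming) match, and identity is reported
over the degron window proper, along with each species' own
best-degron string ("absent" when nothing scores). This is adequate
for the short, well-conserved windows it is meant for; it does not
handle indels inside the window.

## Decay kinetics

Chase densitometry is normalized by the loading-control band and then
to the t=0 value. The fit is least squares on ln(intensity) versus
time — deliberately log-linear, matching the "linear part of the
timecourse" convention, with the default 0–2 h window; nonlinear
exponential refinement is out of scope. The slope is clipped at zero:
k ≤ 10⁻⁶/h reports as stable with infinite half-life rather than a
negative rate. Points at or below an intensity floor (default 0.01 of
t=0) are excluded with a warning, because log of a near-zero band
quantitation is dominated by film/scanner noise.

Stabilization between a treated and a reference chase is the
half-life ratio, mapped onto the published vocabulary with thresholds
that are this package's defaults (the source assigned labels by
inspection): ratio ≥ 2.0 → "yes", ≥ 1.3 → "partial", else "no"; a
stable reference reports "stable" (nothing to slow down), a stable
treated fit over an unstable reference reports "yes". Both
thresholds are arguments.

No printed numeric half-life exists to anchor against, so this
module's guarantees are property-based: machine-precision recovery on
noiseless exponentials across k ∈ [0.05, 5]/h, and median relative
error of k within 3σ for multiplicative lognormal noise σ ≤ 0.1 (200
simulated chases per grid point in the tests).

## Synthetic data

The IP-MS simulator emulates the screen's design: 3 bait + 2 control
purifications; true substrates (default 5% of 500 proteins) draw
Poisson counts with mean λ_sub = 8 in bait runs and exactly 0 in
controls; a sticky background (default 20% of proteins) draws
Poisson(λ_bg = 3) in every run; the remainder is silent. Per-run
dropout (default 0.1) zeroes a substrate's count in a run, motivated
by real candidates detected in only two of three purifications.
Poisson rather than negative-binomial counts are the default for
transparency — no count-noise model is prescribed by the source — and
overdispersion can be emulated by raising dropout or lowering λ.

What this does *not* emulate: control-contaminating substrates (the
β-catenin situation), peptide-to-protein inference ambiguity,
run-to-run normalization drift, or correlated abundances. Perfect
precision of the calling rule on simulated data is therefore a
property of the simulation regime (substrates never hit controls by
construction), not a claim about real screens; recall under dropout is
the informative metric.

Sequence generation writes motifs verbatim into backgrounds whose
D/E/S/T (and G) frequencies are down-weighted (weight 0.1 relative to
other residues), keeping chance degron-class windows rare so planted
ground truth stays the top hit. Decay simulation is exp(−kt) with
multiplicative lognormal noise.

All generators are driven by `numpy.random.default_rng(seed)` and are
bit-reproducible.

## Validation tallies

A novel candidate is *confirmed* when polyubiquitinated forms of it
were precipitated by the trap, regardless of bulk-stability outcomes —
trap precipitation is the validation criterion, since a substrate can
be genuinely ubiquitinated yet show no bulk half-life change. The
confirmation rate divides known + confirmed by candidates actually
examined (the two technically untestable candidates leave the
denominator: 26 = 28 − 2). Percentages round half away from zero for
display; unrounded values are retained. The fixture stores the printed
table verbatim, including the footnoted MLN4924 "stable" entries, and
does not resolve locus IDs against any database (HIVEP1/2 stays one
row, as printed).

## Problem sizes in the checks

The acceptance script and test suite size their sweeps as 1000 random
tables (NSAF conservation), 1000 random ≤60-mers (scanner versus
brute-force enumeration), 100 seeded noisy chases (half-life
recovery) and 500-protein simulated screens — large enough for the
properties to be meaningful, small enough to run comfortably on a
laptop in seconds.

## Known limitations

* The calling rule is presence/absence; abundance information beyond
  the threshold is used only for ranking and scoring, not calling.
* The degron score is ordinal, not calibrated to binding affinity;
  it orders windows sensibly but its absolute values carry no units.
* Log-linear decay fitting is biased when the chase deviates from
  first-order kinetics inside the window (lags, biphasic pools);
  the window argument is the only remedy offered.
* The ortholog comparison assumes the degron neighborhood is
  alignable without gaps.
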