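# Methods

`repeatcal` builds and stress-tests annotation models for transposable
element (TE) families: it constructs seed alignments from per-copy
alignments to a family consensus, turns them into entropy-weighted
position-specific scoring models, simulates composition-faithful
benchmark genomes with planted repeats, calibrates per-family score
thresholds empirically, and quantifies false hits and overextension.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Seed alignment construction

Input is a set of pairwise alignments of genomic copies against a shared
family consensus (the form a RepeatMasker-style annotator emits). Each
record carries the gapped copy, the gapped consensus segment, the
genomic interval, a divergence (mismatches+indels over aligned columns)
and the fraction of the consensus covered.

Curation rules, applied in order:

1. **Duplicate-copy removal.** Copies whose flanking DNA (250 bp each
   side, truncated at contig ends) exceeds 90% global-alignment identity
   pairwise on *both* flanks are clustered by single linkage; one
   representative (lowest divergence, ties by id) is kept. Flank identity
   is `1 − editDistance/max(len)` from an edlib global alignment. The
   rationale: such pairs arise from tandem/segmental duplication of a
   region that already contained the insertion, and would count one
   transposition event twice.
2. **Sampling to the 2000-member cap.** If more copies survive than the
   cap, the most divergent quartile is dropped first (divergence is taken
   from the input records; no realignment), then members are drawn at
   random (seeded) with copies covering >75% of the consensus preferred
   over fragments.
3. **Depth top-up.** If any consensus position is covered by fewer than
   10 members, fragments covering the lowest-depth position are added
   greedily (lowest divergence first) from the unused pool and from
   optional supplementary-organism copies — but never past the member
   cap. Positions no available fragment covers are skipped.
4. **Exclusion masks.** Regions of the consensus shared with high-copy
   families can be supplied as explicit consensus ranges by the curator;
   members covering only masked regions are removed by the caller. This
   is deliberately not automated.

Joining to an MSA is pure column bookkeeping: match columns correspond
1:1 to consensus positions; copy residues opposite consensus gaps become
lowercase insert columns anchored after the preceding match column,
padded with `.` in other rows. Degapping any row reproduces the original
copy subsequence exactly (a tested invariant). Copies whose consensus
segment cannot be located in the full consensus are rejected with a
diagnostic, never silently dropped.

## Profiles and entropy weighting

A profile is a per-match-position emission distribution over A,C,G,T
with log-odds scores in bits against a background (uniform 0.25 by
default; trainable from genome composition). Column counts are mixed
with a symmetric Dirichlet prior α=(1,1,1,1): `p = (n+α)/Σ(n+α)`.
Insert columns are excluded from match states and from entropy
averaging; all-gap match columns are dropped with a warning.

The **relative entropy** of a position is D(p‖q) in bits — the expected
score of an aligned residue. Deep seeds give models whose average
relative entropy far exceeds what is wanted: over-sharp models lose
diverged copies, and low-RE *regions* of a model allow alignments to
wander into flanking sequence (overextension). Observed counts are
therefore down-weighted until the average RE over match positions hits a
target, 0.62 bits/position by default:

* **uniform weighting** multiplies every column's counts by one factor
  m ∈ (0,1];
* **exponential weighting** replaces each column total k by k^s with one
  exponent s ∈ [0,1], letter counts scaled proportionally (`n·k^(s−1)`);
  every scaled total stays in [1,k], so a column with a single
  observation is untouched at any s, while deep columns take almost all
  of the down-weighting. This is the right behavior for fragmented seeds
  (e.g. pervasive 5' truncation of LINE copies) where column depth spans
  an order of magnitude: uniform weighting would crush the shallow
  region toward the prior and invite overextension precisely there.

Average RE is continuous and monotone non-decreasing in the scale
parameter (asserted numerically on random alignments), so the fit is a
bisection. The bisection runs to an interval of 1e-12 on the scale —
far past the documented 1e-4-bit tolerance on achieved RE — so the
fitted scale itself is reproducible and grid-search-comparable. If the
unweighted model is already at or below the target the scale is 1; if
even full down-weighting leaves RE above target (prior-dominated
pathologies) the scale is 0 with a warning.

## Search scorer and E-values

The internal scorer is deliberately plumbing: position-specific local
alignment by dynamic programming over the emission log-odds with affine
gap costs (open 10 bits, extend 1 bit, configurable), both strands, no
position-specific transition training. Per sequence position it records
the best score of an alignment ending there in a match state plus that
alignment's start; candidate envelopes are then accepted greedily by
descending score with per-strand non-overlap. It is deterministic, and
on the model's own consensus it returns exactly the analytic
maximum-scoring path sum (a tested identity). Sequences under 10 bp
return no hits. `N` scores 0 bits (no information). This is not a full
profile HMM and is not intended to match an external search engine
hit-for-hit; externally produced hit tables can be supplied instead
wherever hits are consumed.

E-values come from a Gumbel right tail fitted to background search
scores: maximum likelihood on the top half of scores with the rest
entering as left-censored observations (scipy censored fit), then
`E(s) = P(S ≥ s) · search_space/null_space`. At least 100 null scores
are required; degenerate score distributions are an error. The empirical
tail at the 99th percentile matches the fit within two-fold in tests.

## Benchmark simulation

False-positive and overextension rates are measured on simulated
sequence that contains no real repeats but mimics genomic composition:

* **Background model**: windows (1 kb) are assigned to 6 GC bins by
  training-set quantiles (equal occupancy; the bounds are data-derived,
  not fixed); a Markov chain over bins is trained from consecutive
  windows; within a bin, letters are emitted conditioned on the previous
  3 letters from a per-bin context table with +1 smoothing. Windows that
  are mostly N are skipped and break the transition chain; N-containing
  contexts are skipped.
* **Simulation** draws the bin sequence from the chain (stationary
  start), then emits letters per window from the bin's context table.
  Deterministic given the seed.
* **Simple repeats** are tandem expansions of catalog motifs (geometric
  copy number), mutated to a configurable divergence, written in at
  per-bin Poisson rates (expected insertions per Mb per bin).
* **TE fragments** are windows of a family consensus — half 5'-truncated
  (keeping the 3' end, mimicking LINE decay), half random internal —
  mutated with substitutions (transition:transversion 2:1) at a
  per-fragment rate drawn from a configurable distribution (default
  uniform 0.05–0.25) plus indels at 10% of the substitution rate with
  geometric lengths of mean 2 bp. Placement draws a GC bin from the
  family's preference weights and a position within a window of that
  bin, avoiding existing truth intervals (20 bp of clearance); if the
  preference cannot be satisfied, placement falls back to uniform with a
  warning. Truth records carry exact genomic and model coordinates, the
  strand, and the realized divergence.

Two simplifications relative to a full genome simulator: repeats are
written *over* the background in place rather than inserted (so truth
coordinates never shift and the sequence length is exact), and planted
TE fragments never overlap each other or simple repeats. Real genomes
nest and fragment insertions; passing tests here says the pipeline's
bookkeeping and the entropy-weighting effect are correct, not that
absolute FDR values transfer to real genomes. The context length of 3
(one emission conditioned on three letters) is configurable.

## Threshold calibration

Hits on genomic (or planted-benchmark) sequence are compared with hits
on simulated background of the same size; the background count at a
threshold is taken as the false-hit count, so empirical FDR at t is
`100·|background ≥ t| / |genomic ≥ t|` (0 when no background hit
reaches t; undefined when no genomic hit does).

* **GA (gathering)**: the lowest observed genomic score with FDR ≤ 0.2%
  and every accepted hit at E ≤ 100. FDR is a step function changing
  only at observed scores, so scanning them is exact. For very
  high-count families the E-value cap, not the FDR bound, is binding.
  If nothing satisfies both, GA falls back to the lowest genomic score
  above every background hit. Hits are counted per hit, not per bp
  (bp-level FDR lives in the benchmark evaluator).
* **TC (trusted cutoff)**: max(score at E = 1e-4, best background score
  + 0.1 bits), then floored at GA. By construction zero background hits
  reach TC.

Per-taxon calibration is a re-run against that taxon's sequence and a
size-matched simulation, stored as separate threshold lines.

## Benchmark evaluation

Each hit is matched to the same-family truth interval of maximal
overlap (ties to the left-most). No overlap at all, or overlap only with
another family's truth, makes it a false hit — all of its bases count as
false annotation. Otherwise the bases outside the matched interval are
overextension. Every annotated base is exactly one of
true / false-hit / overextended (conservation is a tested invariant),
and the bp-level FDR splits accordingly into an FDR due to false hits
and an FDR due to overextension. Overextension is measured on alignment
envelopes, not per-column paths. The histogram of overextension lengths
and the bp share of long (>100 bp) events are reported because long
overextensions dominate the damage. The denominator for both FDR
percentages is total annotated bp.

## Redundant-hit adjudication

After applying GA or TC thresholds (inclusive ≥; a model without a
threshold is an error), overlapping hits on a target are adjudicated
greedily by descending score; ties break by lower E-value, then longer
hit, then model id — deterministic and input-order independent. A hit is
accepted iff its overlap with every accepted hit is within the
tolerance (default 0). Overlap between hit envelopes is measured as
`max(0, min(ends) − max(starts))` — the distance each encroaches past
the other's boundary — so abutting hits pass at tolerance 0 and a
10 bp-tolerance chain like [1,100]/[90,190]/[180,280] is fully accepted.
Greedy is not optimal; an exact maximum-weight-independent-set oracle in
the test suite shows it recovers ≥0.8× the optimal total score on random
instances. Nested-insertion excision (young TE inside old TE) is out of
scope; the overlap tolerance partially accommodates nesting.

## Problem sizes and numerical choices

Tests and the acceptance script run on synthetic inputs sized for a
single CPU: seed alignments of 300–400 columns and 100–150 members,
benchmark sequences of 0.15–4 Mb, 60–80 planted fragments per family.
The directional claim — overextension bp decreases when the RE target
rises from 0.45 to 0.62 — is asserted on such a benchmark; absolute
coverage and FDR values at genome scale are explicitly not reproduced
here. Statistical checks account for their own calibration: GC-bin
occupancy is compared by chi-square on sojourn-decorrelated windows
(consecutive windows are correlated through the bin chain), and the
sample-maximum E-value sanity band is set from the Exp(1) distribution
of a maximum's scaled tail probability.

Other numerics: relative entropy is clamped at 0 against −1e-16-scale
rounding residue; emission rows must sum to 1 within 1e-9; the member
cap, quartile rule, and all sampling use a seeded generator with
deterministic sort-based tie-breaks, so every pipeline stage is
byte-reproducible from its seed.
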