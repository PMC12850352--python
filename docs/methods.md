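# Methods notes

## Coordinate model

All positions live on the precursor protein: a chain of `L` residues has
bond positions `0..L`, with `0` and `L` virtual. A peptide `[s, e]`
(1-based, inclusive residues) exposes bond `s−1` at its N-terminus and
bond `e` at its C-terminus; its internal bonds are `{s, …, e−1}`. Peptide
location is exact substring matching after case normalization; I and L
are distinct by default (search engines report them distinctly; an
`equate_il` switch exists). Peptides matching more than one locus are
flagged ambiguous and excluded from scoring by default — double counting
would inflate every score they touch — with a count-in-all mode for
sensitivity analysis. Numbering follows the supplied sequence (UniProt
precursor numbering when a UniProt FASTA is used); mature-chain
renumbering is deliberately out of scope.

## Grouped scoring and the point taxonomy

Signed fold changes always compare the higher-intensity group to the
lower: +(hi/lo) when group 1 is higher, −(hi/lo) when lower, 0 on an
exact tie (such a feature can never be differential, so the convention
only affects bookkeeping). A zero mean on the low side is capped at a
configurable 2^10 and flagged rather than propagating infinities.

Each differential peptide's fold change is assigned to its internal bonds
`{s, …, e−1}` (the bonds *within* the peptide). This makes the per-bond
sum a step function whose discontinuities sit exactly at peptide terminal
residues, so slope analysis lands on changing points by construction. An
inclusive `{s−1, …, e}` mode exists because virtual bonds otherwise never
carry score.

A changing point at residue `p` is annotated with the signed step

    Δ_p = score_p − score_{p−1},

the jump its peptide termini introduce into the (cumulative) waterfall
curve: an N-terminal point of up-regulated products steps up, a
C-terminal point of the same products steps down. The step is computed on
the per-comparison track for per-comparison annotation and on the
cumulative track for waterfall display. By default a point must have a
non-zero step to count as a transition point for the important-position
call (a zero step means perfectly cancelling signal); a switch keeps
zero-step points since the definition can be read either way. Two
directions are recorded per point and kept distinct on purpose:
`direction` (sign of the members' fold changes — the biological
up/down of proteolysis at the site) and `step_sign` (the waterfall
geometry). Important positions require the same non-zero `step_sign` at
the same (protein, residue, orientation) in *every* pairwise comparison;
severity trends apply strict monotonicity (tolerance ε, default 0) to
per-comparison scores in the configured severity order and use the member
direction.

## Differential statistics

Tests run on log2-transformed observed abundances; Welch's t is the
default (group sizes in real cohorts are unequal; pooled t is available).
Zeros are offset by half the smallest observed positive value and
flagged. When both groups have zero variance the p-value is 1 for equal
means and 0 for a degenerate perfect separation, flagged either way.
Calling uses raw p-values (p < 0.05) with strict fold-change bounds
(ratio > 2 or < 0.5); Benjamini–Hochberg is computed as a column but not
used for calling unless requested. The presence rule (≥ 3 observed
samples per side, ≥ as stated; the missingness gate is strictly < 20 %)
is enforced before testing.

## Normalization

"Total amount then scale to 100": sample columns are equalized to the
median column total, then each feature row is rescaled so its mean over
observed cells is 100 (a max = 100 variant is configurable, since the
convention is a reporting choice). Missing cells stay missing; all
factors are returned. The output matrix is tagged `provenance="scaled"`
and re-normalizing a scaled matrix is the identity — the literal two-step
recipe is not an idempotent map, so idempotence is provided by
provenance, not by arithmetic.

## Individual scores

Cluster membership is every quantified peptide sharing the labelled
terminal residue; in discovery mode the member set is frozen from the
reference (members never observed in any reference replicate are dropped
for all samples) so each sample sums over a comparable denominator.
Reference intensity is the arithmetic mean over observed replicates
(geometric by flag). PRM mode applies the exclusion rule — any member
without its required measurement excludes the sample for that position —
because an absent heavy partner indicates the endogenous peptide went
undetected rather than absent. Discovery mode instead applies the union
rule, which yields the provable bound: a position's missing fraction
never exceeds the smallest member missing fraction. Member ratios are
plainly summed; response-weighted sums are a possible future option when
members differ greatly in response.

## ROC and selection

AUC is the Mann–Whitney statistic over observed values (ties counted
half), reported two-sided as `max(A, 1−A)` with the achieving direction,
so down-regulated fragments pass the same > 0.90 screen as up-regulated
ones; the directional value is also stored. Missing values are excluded,
never imputed — the < 20 % gate bounds their influence. Screening
peptides need the strict AUC bound in every disease-vs-control
comparison; candidate positions need it at the position level plus ≥ 2
independently-passing members. Embeddings and classifier ranking are left
to external tools; the module exports the eligible matrices.

## Synthetic degradome

The generator emulates the data-generating process the method exploits:
per protein, a few hotspot bonds (default 3, ≥ 40 residues from chain
ends and from each other) cut the chain into parent fragments; each
parent spawns two single-ended exopeptidase ladders (N-trims and C-trims,
default depth 4) whose species keep the hotspot-side terminus and decay
in abundance by a factor 0.5 per trimmed residue. Dropping double-trimmed
species is a deliberate simplification: they are rarer in real data and
their inclusion only adds low-abundance noise species. Abundances are
log-normal (baseline spread 1.0 natural-log units; within-group noise
σ = 0.5; per-sample loading factor σ = 0.1); a dysregulated site
multiplies every peptide it generates by 2^±1 per affected group —
protease activity changes, precursor abundance stays flat, so a fragment
between two sites carries the product of both site effects (opposite
neighbours can genuinely cancel). Dropout is logistic in log intensity
(midpoint at the 5th intensity percentile, steepness 1.5) plus a 2 %
MCAR floor. Reference replicates pool equal volumes (row mean) with 10 %
technical noise and the same dropout. Everything is deterministic under
the seed.

What the simulator does not emulate: modifications, chromatography/RT
structure, fragment-ion spectra, correlated biological covariates,
batch effects, and heavy-tailed contamination. Passing recovery tests
therefore demonstrates the machinery is correct under the generating
model, not that real cohorts will reach the same operating point.

**Recovery benchmark.** Predicted cleavage sites are
directionally-consistent *stable* transition points (≥ 2 differential
members — the taxonomy's own reliability notion, not a tuned threshold),
mapped to bonds (`p−1` for `_N`, `p` for `_C`), virtual bonds excluded.
Under the default conditions (20 proteins × 3 hotspots, 15/group, 2×
effects) precision is ~1.0 and recall 0.7–0.87 (F1 ≈ 0.87 on average
over seeds). Recall is structurally bounded by two features of the
conditions themselves: a true fold change of exactly 2 sits on the strict
> 2 calling boundary, and fragments between opposite-direction neighbour
sites carry a net effect of 1 and are invisible to any method.

## Problem sizes

The test suite and acceptance script use desk-scale runs chosen to keep
estimates stable: 100 random instances (≤ 50 peptides, L ≤ 500) for the
scoring oracle, 1000 null features at 10/group for type-I calibration,
the default 720-peptide × 30-sample degradome for recovery, and a
3-member PRM panel over 30 samples for route concordance. The full suite
runs in well under a minute.

## Known limitations

- Exact substring mapping cannot place peptides with sequence variants or
  cross-protein isoform collapse beyond the ambiguity policy.
- The fold-change cap (2^10) makes extreme one-sided features comparable
  but saturates their contribution to scores.
- Severity trends use strict monotonicity; noisy per-comparison scores
  near a tie need the ε tolerance.
- AUC confidence intervals are not computed; the selection criteria are
  point thresholds.
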