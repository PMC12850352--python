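# pepsite — single-position peptide clustering for peptidomics

Endogenous peptides in a biofluid are the products of in-vivo proteolysis.
Because exopeptidases progressively nibble the primary cleavage products,
a single dysregulated cleavage event shows up in a peptidomics report as a
ladder of dozens of nested, apparently redundant peptides — each one noisy,
often missing, and individually weak as a biomarker. `pepsite` collapses
this redundancy back onto the coordinate that generated it: the peptide
bond position on the precursor protein.

It is aimed at analysts of label-free or targeted (PRM) peptidomics data
who want cleavage-site-level summaries of degradation and
position-anchored peptide-cluster biomarkers rather than single-peptide
lists.

## The aa-score model

A protein of `L` residues carries bond positions `0..L` (`0` and `L` are
virtual bonds flanking the chain). A peptide occupying residues `[s, e]`
(1-based, inclusive) exposes its N-terminus at bond `s−1`, its C-terminus
at bond `e`, and contains bonds `{s, …, e−1}`.

**Grouped aa-score.** For a two-group comparison, each differential
peptide `k` (Welch t on log2 abundance, p < 0.05, and fold change > 2 or
< 0.5) carries a signed fold change `fc_k`: +(hi/lo) when the first group
is the higher one, −(hi/lo) otherwise. The score of bond `j` is

    score_j = Σ_{k spanning j} fc_k

summed over the `n_j` differential peptides whose internal bonds include
`j`; `(L−1)` normalizes per-protein means. The track is a step function
whose steps sit exactly at peptide termini. Terminal residues of
differential peptides are **changing points** — **stable** when ≥ 2
peptides share the residue and orientation (`_N`, `_C`, or `_B` for both),
**dynamic** when unique. The signed step `Δ_p = score_p − score_{p−1}`
marks **transition points**; positions whose step sign agrees in every
pairwise comparison are the disease-associated **important positions**.

**Individual aa-score.** Each sample gets its own position value by
summing member-peptide quantities over the cluster sharing that terminus:
back-calculated absolute amounts (heavy standards + calibration curve),
endogenous/heavy ratios, or sample/reference ratios (target-only or
all-member). In PRM mode a sample missing any required member is excluded
for that position; in reference-based discovery mode a union rule applies
— a position is missing only when *no* member is observed, which is what
shrinks missing-value rates relative to single-peptide analysis.

**Biomarker selection.** Two-sided ROC AUC (`max(A, 1−A)`, Mann–Whitney
with tie correction) under a strict < 20 % per-group missingness gate;
screening peptides need AUC > 0.90 in every disease-vs-control
comparison; candidate positions additionally need ≥ 2 member peptides
individually clearing the same bar.

A synthetic degradome generator (hotspot cleavage, geometric exopeptidase
ladders, log-normal abundances, intensity-dependent dropout, pooled
reference replicates, heavy spike-ins) provides ground truth for every
stage.

## Worked example

```python
from pepsite import SimulationConfig, simulate_proteome, simulate_degradome, inject_missingness
from pepsite.pipeline import run_grouped_analysis, recover_hotspots

cfg = SimulationConfig(seed=1)           # 20 proteins x 3 hotspots, 15/group, 2x effects
db = simulate_proteome(cfg)
matrix, truth, design = simulate_degradome(db, cfg)
observed = inject_missingness(matrix, cfg)

analysis = run_grouped_analysis(observed, design, db)
res = analysis.results["Case|Ctr"]
catalog = analysis.catalog()
report = recover_hotspots(analysis, truth, db)
```

This prints (via the obvious `print` calls):

```
peptides: 720 samples: 30
tested: 705 differential: 323
points: 380 stable: 84 transition: 380
recovery: precision=1.000 recall=0.767 f1=0.868
```

720 simulated ladder peptides over 30 samples yield 323 differential
peptides in the case-vs-control comparison; their termini define 380
changing points, of which 84 are stable. Treating directionally-consistent
stable transition points as predicted cleavage sites recovers the 60
planted dysregulated bonds with perfect precision and 77 % recall
(F1 = 0.87) — recall is bounded by the planted two-fold effect sitting
exactly on the strict fold-change calling threshold.

The same stages are available from the shell:

```
pepsite simulate --seed 1 --out-dir sim/
pepsite points --report sim/report.tsv --design sim/design.tsv \
               --fasta sim/proteins.fasta --out-dir out/
pepsite plot --report sim/report.tsv --design sim/design.tsv \
             --fasta sim/proteins.fasta --protein SIM001 --out SIM001.svg
```

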