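# Methods

This note documents the models, decision rules and numerical choices
behind each stage of the package, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Domain and motif annotation

Aux/IAA domain detection is ungapped pattern matching, not profile-HMM
search. Every analysis decision downstream of annotation depends only
on presence/absence, completeness and motif class — never on exact
alignment columns — so a pattern scanner with conserved flanking
anchors is sufficient and exactly testable. Each domain profile has
three layers, tried in order at each protein:

1. **full** — the intact domain (leftmost regex match wins; with
   leftmost-match semantics ties cannot occur);
2. **split** — two ordered sub-patterns within a bounded gap
   (default 15 residues), modelling a domain interrupted by a short
   insertion; counted as complete, mirroring the nine-residue
   insertion in one family member's domain IV;
3. **partial** — a truncated remnant, reported with
   `complete = False`.

The shipped default patterns correspond to the synthetic domain
templates of the generator; for real proteins they are meant to be
replaced via the YAML config. A protein is *canonical* iff all four
domains are present and complete. The degron is the literal GWPPV
pentapeptide, constrained to lie inside domain II when that span
exists; a protein without domain II is never called degron-positive.
The bipartite NLS requires a KR dipeptide strictly between domains I
and II *and* a basic hexamer (default `[KR]{6}`) inside domain II; the
second NLS is a basic stretch (default `[KR]{4}`) within the last 6
residues of domain IV. Both basic-residue patterns are configuration
placeholders — the literature does not specify the exact residue
composition, so they are config, not hard-coded truth. Family class
A/B is assigned from two non-overlapping domain-III consensus
signatures; zero or two matches give `unclassified`. Which class owns
the variant domain III is not fixed by the original study; the
package maps the variant signature to class B by default
(`variant_domain3_class` in the config).

## Promoter AuxRE profiling

Promoters are the `promoter_length` (default 3,000) bases immediately
5′ of the translation start on the coding strand; minus-strand genes
take the reverse complement of the 3′ genomic flank. Truncation at a
chromosome end is a warning, not an error. All occurrences of
TGTCTC/GAGACA (canonical) and TGTC/GACA (core) are counted, overlaps
included — no overlap-removal rule is defined in the original analyses,
and counting everything is the conservative, oracle-checkable choice.
A core hit inside a canonical hit is flagged `within_canonical` but
kept in core totals, since canonical elements and core "derivatives"
are tallied as separate summaries. Tandem clusters are maximal runs of
≥ 2 core hits with inter-start gaps ≤ `tandem_max_gap` (default
50 bp — no quantitative gap is stated in the original analyses, so the value is
config-exposed). Because the exact counting convention behind
published per-promoter tallies is not recoverable, both a per-motif
count table and a per-promoter presence flag are emitted.

## Phylogeny

Distances are uncorrected p-distances with pairwise deletion of
gapped columns (a pair with no comparable columns is an error naming
the pair). A Poisson-type correction switch is deliberately absent:
the family tree is interpreted only relatively, and the original tree
software's exact model is unstated, so the tree topology is not an
exact reproduction target. Neighbor joining follows Saitou–Nei with
three reproducibility rules:

- taxa are sorted lexicographically internally, making the result
  independent of input order;
- Q-matrix ties (within 1e-12 relative) break toward the
  lexicographically smallest label pair, each cluster keyed by its
  smallest member;
- negative branch estimates are clamped to zero with the deficit
  shifted to the sibling branch, preserving the joined pair's path
  length (standard practice; the original analysis software leaves this unstated).

On additive matrices the algorithm provably reproduces all
leaf-to-leaf path lengths; the test suite checks this to 1e-9 against
randomly generated additive trees and checks topology optimality
against an exhaustive least-squares enumeration for ≤ 6 taxa, plus an
independent NJ implementation (dendropy) on noisy matrices.

Bootstrap support resamples alignment columns with replacement from a
single seeded RNG stream; each internal edge of the full-data tree is
labeled with the percentage of replicates containing the same
bipartition (canonicalized against the lexicographically smallest
taxon). Paralog suggestion takes cherries — internal nodes with two
leaf children — whose support meets `min_pair_support` (default 50%).
On a family where only duplicate pairs are planted this recovers all
pairs exactly; on a full family with many singletons, chance cherries
among unrelated genes can add candidates beyond the planted pairs,
which is inherent to the sister-pair rule rather than a defect.

## qRT-PCR quantification

The amplification model is exponential: a transcript at relative
concentration `c` with per-cycle efficiency `E` crosses threshold at
`Ct = intercept − log_E(c)`. Primer efficiency is estimated by the
ordinary least-squares line of Ct on log10(dilution) over the
1 … 1/128 series, `E = 10^(−1/slope)`; at least three non-censored
points are required, and a non-negative slope flags the model invalid
rather than raising. Relative expression uses the two-efficiency
(Pfaffl-style, calibrator-free) ratio
`R = E_ref^Ct_ref / E_target^Ct_target` because the original study reports
tissue-level expression relative to *myosin*, not fold change against
a control condition; the exact normalization formula is unstated
in the original study, so a `assume_perfect_efficiency` switch provides the classical
ΔCt behaviour with E = 2, under which `R = 2^(Ct_ref − Ct_target)`
exactly. The ratio is computed in log space for numerical stability.

Technical replicates are averaged on the Ct scale (Ct noise is
approximately additive on cycles) within each biological replicate;
expression is computed once per biological replicate; group mean and
standard error are taken across biological replicates. Censoring: a
missing Ct or one above `max_ct` (default 35 cycles) is below
detection; a censored technical replicate is dropped from the
average, an all-censored biological replicate is censored, an
all-censored group carries no numeric mean, and a sample whose
housekeeping assay is censored is excluded with a warning. Transcript
shares divide a gene's group mean by the family-wide sum over
detected genes and sum to one by construction.

## Differential expression and hierarchy scoring

The pairwise test is the classical pooled-variance two-sided Student
t-test (matching the original study's naming; Welch is a config switch), on
per-biological-replicate expression values, reported in the tier
whose threshold the raw p-value meets (0.05 / 0.01 / 0.001 — the
red/yellow/green tiers of the original summary figure). No
multiple-testing adjustment is applied by default because the original study
reports raw tiers across all of its comparisons; a Benjamini–Hochberg
flag exists. Groups with fewer than two detected replicates are
skipped with a warning. Zero-variance degenerate samples are handled
explicitly: identical means give (t = 0, p = 1), distinct means an
unambiguous difference (p = 0).

The hierarchy score counts significant root-type contrasts that agree
with a fixed ranking (default crown > seminal > primary > lateral): a
call is consistent when the higher-ranked root type has the higher
mean. The published "55 patterns" tally mixes per-stage and
per-root-type comparisons in a way that cannot be reconstructed
unambiguously, so the package provides both counting modes: the
default collapses multi-stage comparisons to one pattern per (gene,
root-type pair) — consistent iff consistent at ≥ 1 stage and
contradicted at none — and `per_stage=True` counts every significant
call. With zero significant calls the fraction is undefined (`None`),
never 0/0.

Paralog correlation regresses one member's group means on the
other's across their shared detected sample groups (≥ 3 required;
zero variance in either profile is an undefined-correlation error).
R² and the zero-slope p-value come from ordinary least squares;
significance applies R² > 0.5 and p ≤ 0.01. The higher-expressed
member's subgenome is looked up from the metadata table.

## Induction kinetics

A time course holds replicate expression values at 0, 1, 2, 3 h
(t0 = untreated control; three biological replicates in the emulated
design). Comparisons are the same pooled t-test at
`induction_alpha = 0.05` per comparison (the original study states no level
for this step). The decision procedure:

1. all time points censored → **below_detection**;
2. t-tests of t1, t2, t3 vs t0 and of t2 vs t1, t3 vs t2;
3. **B** when t1 or t2 is significantly increased over t0 *and* a
   later consecutive comparison (t2 vs t1 or t3 vs t2) is
   significantly decreased;
4. otherwise **A** when some time point is significantly increased
   over t0 *and* t3 is still significantly above t0;
5. otherwise **not_inducible**.

When a course satisfies both definitions (rise, later significant
dip, t3 still elevated), B wins: the significant decrease is what
defines the transient class. This precedence is config-switchable.
The sustained-elevation requirement is implemented as the t3-vs-t0
test; whether intermediate time points must also remain elevated is
left unspecified in the original study and not enforced. A non-control time
point that is fully censored just loses its comparisons; a time point
with exactly one detected replicate is a classification error for
that gene.

One consequence worth stating: for any nonzero replicate noise, an A
course has roughly a 2×(α/2) ≈ α chance of a spurious significant dip
between consecutive equal-mean time points, independent of the noise
magnitude — so exact recovery of a planted A/B composition is only
guaranteed on noiseless courses, and recovery rates under noise
plateau near 1 − α per gene rather than at 1.

## Synthetic data

The generator emulates the study design, not maize biology:

- **Family sequences.** Proteins are assembled from fixed-layout
  synthetic domain templates (flank anchors with planted motif slots)
  joined by random linkers; the default 34-gene plan mirrors the
  published family composition — 29 canonical proteins; one member
  lacking domains I/II with incomplete III/IV; two lacking domain II;
  two lacking domain IV; one split domain IV; five LxLxPP variants;
  13 class-B domain IIIs; seven duplicate pairs (one of which pairs a
  split-IV member with an intact-IV member); 28 of 34 promoters with
  canonical AuxRE and all with a tandem core run. Duplicate pairs are
  made by copying a partner's row and substituting linker columns at
  rate 0.08, so pairs are mutually closest while domain content stays
  planted. All filler (protein linkers, promoter background) is
  rejection-sampled or repaired to contain no planted motif or
  pattern anchor, making planted counts exactly recoverable. The
  alignment is the fixed column layout itself ('-' for absent
  blocks), so no aligner is needed. Because the layout is fixed,
  synthetic families do not exercise indel-rich alignments, and the
  29/34 canonical recovery shows scanner correctness on planted
  truth, not SMART-equivalence on real proteins.
- **Ct tables.** `Ct = intercept − log_E(c) + N(0, σ_bio) + N(0,
  σ_tech)` with defaults intercept = 20 cycles at relative
  concentration 1, E = 2, censoring at Ct 35; five biological × three
  technical replicates per group (three biological for induction).
  Biological effects are drawn per (gene, group, replicate) — real
  biological covariance between genes within one RNA sample is not
  modelled, which makes the synthetic data slightly conservative for
  the correlation stage.
- **Induction courses.** Mean trajectories (1, e, e, e) for A,
  (1, e, 1, 1) for B, constant for flat; log-normal replicates with
  the requested coefficient of variation (mean-corrected). Default
  conditions for recovery experiments: 3-fold effect, 20% CV, n = 3.
- **Root-type hierarchy designs.** Per-gene baselines log-uniform
  over two decades; each step down the ranking divides the
  concentration by `fold_step` (default 2).
- The treatment metadata records both auxin concentrations stated in
  the original study protocol (5 mM in the methods text, 5 µM in the
  induction figure) without resolving the discrepancy.

Every generator is a pure function of (parameters, seed); truth
objects serialize to JSON beside the outputs.

## Problem sizes and numerical choices

The test and acceptance workloads use: 200 random additive trees
(4–12 taxa) plus exhaustive least-squares enumeration at 4–6 taxa;
1,000 noisy standard curves per planted efficiency; 10,000 null
t-tests; 500 planted courses per induction label; 200 hierarchy runs
of 30 genes; 1,000 random 3-kb promoters and 1,000 random proteins
for oracle agreement; 200 bootstrap replicates in the pipeline smoke
(the config default is 1,000). Tolerances: additive path lengths to
1e-9; efficiency MAE ≤ 0.05; type-I rate within 0.05 ± 0.01; label
recovery ≥ 95%; hierarchy fraction ≥ 0.9 under moderate noise.

## Known limitations

- Pattern-based annotation presumes the configured anchors; it is not
  a substitute for HMM/profile search on diverged real sequences.
- The NJ tree is a point estimate; no ME/ML/Bayesian alternatives.
- The paralog-suggestion rule (supported cherries) over-calls on
  families dominated by singletons.
- Expression statistics assume approximate normality of
  per-replicate expression ratios at n = 3–5; no mixed models or
  shrinkage.
- Genomic context is synthetic: no real B73 coordinates beyond the
  metadata fixture, no codon usage, no BLAST-based family discovery,
  no synteny computation.
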