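# Methods and design notes

This note documents the models and procedures implemented in `rapep`, the
parameters that matter, the numerical conventions, and the choices made
where the design was genuinely open.

## Problem setting

The toolkit classifies short peptides (9–20 residues, the HLA class II
binding range) as rheumatoid-arthritis (RA)-inducing or non-inducing. Two
signal families carry most of the information: global physicochemical
composition (RA-inducing peptides skew toward glycine, proline and
tyrosine; non-inducing peptides toward alanine, aspartate, glutamate and
leucine) and short degenerate sequence patterns shared by subsets of the
inducing class. The hybrid model combines both.

## Dataset handling

Cleaning applies, in order: collapse of duplicate sequences within each
class; removal of negative sequences identical to a positive sequence (the
positive copy is kept — an experimentally confirmed inducer outranks a
negative annotation); removal of sequences outside the 9–20 length window;
and optionally removal of positives whose occurrence count falls below a
threshold. The count filter interprets "low-frequency" positives as a
per-record count annotation (enable with `min_count=7` to drop records
seen ≤ 6 times); it is off by default because most inputs carry no counts.
Every removal is reported with its reason, and cleaning is idempotent.

Train/validation splitting is stratified per class with validation size
`floor(0.2·n)` (58/33 validation peptides for a 291/165 dataset); the
floor is computed on the exactly rounded fraction so binary floating-point
noise cannot shift a class by one peptide.

## Feature families

All features depend only on the sequence, never on the record id.

- **k-mer composition (AAC/DPC/TPC)**: `100 · count(m) / (L − k + 1)` over
  all `20^k` k-mers; each row sums to 100 by construction.
- **CTD**: seven 3-group partitions of the alphabet (hydrophobicity, van
  der Waals volume, polarity, polarizability, charge, secondary-structure
  propensity, solvent accessibility; the standard published partitions,
  shipped as `data/ctd_groups.tsv` and overridable). Per property:
  3 composition fractions, 3 transition rates (adjacent residue pairs in
  different groups ÷ (L−1)), and 15 distribution values. The distribution
  percentile for fraction q of a group with m occurrences is the sequence
  position (1-based, divided by L) of occurrence `min(floor(q·m)+1, m)` —
  the occurrence at which the fraction q is first exceeded — and 0 when
  the group is absent. Everything lands in [0, 1], matching the scale on
  which mean-difference feature rankings are reported.
- **Terminal binary profile**: the N-terminal and C-terminal 9-mers are
  concatenated into a fixed 18-mer (a 9-mer contributes itself twice) and
  one-hot encoded into 360 features summing to 18. The same 18-mer
  construction underlies positional enrichment analysis.
- **Bond composition (BTC)**: mean per-residue counts of total, hydrogen,
  single and double covalent bonds. No canonical table exists for these
  descriptors, so the shipped table (`data/bond_counts.tsv`) was derived
  once from the Kekulé structures of the 20 free amino acids with explicit
  hydrogens; it is a documented, overridable interpretation.
- **DDR**: per residue type, the sum of gaps between consecutive
  occurrences divided by L (0 with fewer than two occurrences) — a
  normalized dispersion statistic, documented as an interpretation since
  no published formula pins it down.
- **CTC**: conjoint-triad frequencies over the standard 7-class dipole/
  volume alphabet, normalized by (L−2).
- **PRI**: fractions of residues in documented physicochemical sets (NE =
  {D,E}, PO = {R,H,K}, etc.; see `tables.PRI_SETS`).
- **SER**: per residue type, `−f·log2 f` with `f = count/L`.
- **APAAC**: amphiphilic pseudo-amino-acid composition with standardized
  Tanford hydrophobicity and Hopp–Woods hydrophilicity scales; defaults
  λ = 8 (compatible with the minimum length 9) and w = 0.05. The full
  vector normalizes to exactly 1.

Feature names follow `FAMILY_subcode` (`CeTD_50_p_VW3`, `BTC_T`, `SER_Y`,
`PRI_NE`) so ranked feature lists are portable across runs. For the CTD
transition features the pair-of-groups naming (`CeTD_12_HB`) is this
package's own convention; published feature lists do not disambiguate
theirs.

## Profiling

Positional enrichment uses a two-sided Fisher exact test per (position,
residue) cell of the 18-mer representation, with α = 0.05 and no
multiple-testing correction — the analysis is descriptive, mirroring
two-sample-logo practice, not inferential. Univariate ranking min-max
normalizes each feature, drops constants, filters by two-sided t-test
p ≤ 0.05 and ranks by absolute mean difference (ties broken by name).
Single-feature AUC is the rank statistic (ties averaged), verified in
tests against brute-force pair counting.

## Exclusive motif discovery

A motif is a token string; each token is a literal residue or a residue
class. The Betts–Russell classes (polar, charged, negative, positive,
small, tiny, hydrophobic, aromatic, aliphatic) are shipped verbatim from
their published definition; the Koolman–Rohm classes are not printed in
any primary source at hand, so an atlas-style grouping (aliphatic, sulfur,
aromatic, neutral, acidic, basic, cyclic) ships as a documented config.
Support is **sequence-level**: a sequence counts once regardless of how
many sites match, which is what "coverage" counts in motif tables.

Discovery returns the top-k patterns with positive support ≥ fp and
negative support ≤ fn, ordered by support (descending), then length
(ascending), then token order. The search extends patterns token by token,
with candidate tokens generated from the residues actually following the
current matches (the literal plus every class containing it). Because
sequence-level support is anti-monotone under extension, a best-first
frontier ordered by support, pruned at the current k-th best qualifying
support, returns exactly the same list as full enumeration — an
equivalence the test suite checks against a brute-force oracle on random
literal-alphabet instances. Defaults mirror the deployed model: fp = 2,
fn = 0, g = 0 (contiguous matching), k = 20, maximum pattern length 5.
Gap budgets g > 0 are supported in matching and discovery (up to g total
skipped residues between tokens) but are not used by the default model;
the gap semantics are this package's documented interpretation.

The motif score is a capped indicator: +0.5 if any exclusive positive
motif matches, 0 otherwise. Matching three motifs earns the same bonus as
matching one.

## Similarity search

Full Smith–Waterman replaces seeded heuristics — reference sets here are
hundreds of short peptides, so exact DP is affordable and removes any
external aligner dependency. Scoring mirrors short-peptide search
conventions: PAM30, gap open 9 / extend 1 (a gap of length g costs
9 + g). E-values use `E = K·m·n·exp(−λS)` with λ solved for PAM30 under
ungapped Karlin–Altschul statistics with Robinson–Robinson background
frequencies, and K = 0.13 as a shipped constant. These e-values order and
threshold hits consistently; they are not calibrated to reproduce any
specific aligner build's output. Ties at the top score break by higher
alignment identity, then subject id.

## Classifier harness

Nine algorithms (decision tree, random forest, extra trees, logistic
regression, k-NN, Gaussian naive Bayes, RBF-kernel SVC, MLP, XGBoost-style
gradient boosting) sit behind one registry with small shipped default
grids — grids are configuration, chosen for coverage at desk scale, not
claims about any published tuning. Training runs stratified five-fold CV
per grid point, scored by AUC; normalization (min-max) lives inside the
pipeline, so it is re-fit on the training side of every fold and leakage
is structurally impossible (a test confirms that a 1-NN memorizer gains
nothing out-of-fold on noise). Aggregate metrics are computed on pooled
out-of-fold predictions of the best configuration — pooling keeps
threshold metrics well-defined on integer confusion counts — and the
final model is refit on all training data.

Metrics come from the standard confusion-matrix formulas (sensitivity,
specificity and accuracy as percentages; F1; MCC; Cohen's kappa) plus
rank-based AUC with tie averaging; all are verified against independent
brute-force implementations. Division-by-zero cases (empty margins)
return 0; single-class AUC is NaN while the count-based metrics are still
reported.

Feature selection: L1-penalized linear SVC (nonzero coefficients, on the
normalized matrix) and greedy mRMR in the MID form (mutual information
difference), with MI computed on 10 equal-width bins — deterministic and
documented; the bin count is a parameter.

## Hybrid model and deployment

The default deployed model is CTD features + gradient boosting + exclusive
Betts–Russell motifs, the strongest combination of the single-family
models. The combined score is the classifier's positive probability plus
the 0.5 motif bonus; the label compares the **uncapped** sum with the
threshold (default 0.5), while the reported score caps at 1.0 for
readability — with the default threshold the cap never changes a label,
and the cap-vs-decision distinction is documented because no published
convention exists. The similarity-first ensemble lets a reference top hit
decide the label outright and falls back to the pure ML score on no-hit.

Protein scanning slides a window (default 15, the midpoint of the trained
9–20 range) with step 1 and reports 1-based inclusive coordinates;
internally all coordinates are 0-based half-open. Analog design
enumerates all 19·L single-residue substitutions. Both paths are fully
deterministic given a fitted model.

## Synthetic benchmark generator

The generator emulates the structure of the real training data rather
than any specific measured dataset: lengths uniform on 9–20; positive
residues drawn with G/P/Y weighted 2× over a uniform background and
negatives with A/D/E/L weighted 2× (magnitudes chosen once so that
composition differences are detectable at n = 100, and documented as
arbitrary); and the degenerate pattern `tiny polar hydrophobic G
hydrophobic` planted — instantiated to concrete residues, biased by the
positive composition — into 60 % of positives at a random position, with
rejection sampling guaranteeing that no negative matches it and that all
sequences are unique. Default class sizes mirror a 291/165 positive/
negative dataset; benchmark scripts use 200/200 + 50/50 to keep runtimes
at desk scale.

What the generator does **not** emulate: assay metadata, HLA-allele
restriction, homology clusters between train and validation, position-
specific composition gradients, and real negatives' similarity to
positives. Passing benchmarks therefore demonstrates that the pipeline
recovers planted compositional and motif structure — not any particular
performance level on experimentally curated peptides.

## Known limitations

- The BTC, DDR and PRI definitions are documented interpretations with
  override hooks; no public formula fixes them uniquely.
- E-values are internally consistent but not calibrated against BLAST
  builds; decision rules, not e-value magnitudes, are the contract.
- Motif discovery cost grows with class overlap and fp ≈ 1; the shipped
  defaults (fp = 2, max length 5, top-20 pruning) keep datasets of a few
  hundred peptides in seconds, but very permissive settings on large
  datasets can be slow.
- The analog designer enumerates single substitutions only; multi-residue
  design is out of scope.
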