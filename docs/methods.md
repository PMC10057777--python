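# Methods

## Problem and scope

`aromapred` frames aromatase-related protein detection as binary sequence
classification: a positive family with a distinctive residue-composition
profile versus a background of unrelated proteins. The package covers the
whole workflow — dataset curation, four feature encodings, RBF-SVM
training and scoring, stratified five-fold cross-validation with
ACC/SN/SP/MCC, threshold sweeps and per-sequence score graphs — plus a
synthetic-data generator so every stage is testable end to end with no
external databases or profile searches.

## Dataset curation

Two steps, applied in this order:

1. **Annotation filter.** Records whose FASTA description contains any of
   the keywords `fragment`, `isoform`, `potential`, `similarity`,
   `probable` (case-insensitive substring, so plural forms also match) are
   dropped. Matching is restricted to the description line, where
   UniProt-style annotation words live.
2. **Redundancy reduction at 90% identity.** A deterministic greedy
   stand-in for CD-HIT: records are visited longest-first (ties by id);
   a record is kept iff its global pairwise identity to every already-kept
   record is ≤ the threshold. Identity is computed from a global alignment
   with match +1, mismatch 0, gap 0, as identical positions / alignment
   length. Because free gaps leave the alignment length ambiguous, the
   aligner applies an infinitesimal gap penalty (−10⁻⁶ per gap column) as
   a tie-break: among all match-maximising alignments the one with fewest
   gaps is used, which makes the identity value well defined and
   reproducible without ever sacrificing a match at realistic sequence
   lengths (total tie-break penalty ≪ 1). CD-HIT's word-based heuristic
   and its short-sequence identity convention are deliberately not
   reproduced; the exact-alignment definition is declared, deterministic
   and testable against a brute-force dynamic-programming oracle.

Non-standard residues (B, J, O, U, X, Z) and gap characters are removed at
ingestion with a logged warning, because the composition formulas are
defined only over the 20 standard amino acids; all length denominators use
the cleaned sequence.

## Feature encodings

| scheme | length | definition |
|---|---|---|
| AAC | 20 | residue counts / L |
| DPC | 400 | overlapping dipeptide counts / (L−1) |
| hybrid | 420 | AAC ‖ DPC |
| PSSM composition | 400 | per-(residue, column) mean of the normalized profile |

Residue order is alphabetical one-letter (A, C, D, …, Y) throughout;
dipeptides are indexed (first residue, second residue). Both composition
vectors are frequency distributions summing to 1 — the dipeptide
denominator is the number of overlapping dipeptides actually present
(L−1), not the constant 400, for consistency with the residue-level
definition.

PSSM profiles are read from the PSI-BLAST ASCII dialect (first 20-column
log-odds block only; the weighted-percentage block and footer statistics
are ignored; file column order, normally `ARNDCQEGHILKMFPSTWYV`, is kept
on parse and mapped to canonical order during composition). Normalization
is min-max over all L×20 cells of one profile — per-profile rather than
global constants, so each profile is self-contained; a constant matrix
maps to all zeros by convention. The composition divides the per-residue
column sums by L (not by per-residue counts), so residues that are rare in
the sequence cannot blow up their rows; components are therefore bounded
by the residue's frequency in the sequence.

## Classifier

`sklearn.svm.SVC` provides the quadratic-program solver; the contract is
the interface (deterministic training, continuous decision values,
prediction-time threshold), not solver internals. Defaults:

* kernel RBF; DPC: γ = 3, C = 375 (the published optimum for dipeptide
  composition); AAC/hybrid/PSSM: γ = 1, C = 100, overridable — optimized
  values for these schemes were never published.
* solver tolerance 10⁻⁸, tight enough that decision values are invariant
  (to ~10⁻⁸) under training-example reordering, and negating all labels
  negates all decision values.
* decision threshold 0 at prediction time; a score exactly at the
  threshold is called positive (a fixed convention for reproducibility).

Models persist via joblib with a format-version field and a stored scheme
tag; loading verifies both.

## Evaluation

Five-fold cross-validation is stratified by dealing each class —
shuffled by the seed, in id-sorted order so the result is independent of
input ordering — round-robin into k folds; per-class fold sizes differ by
at most 1, and every record is tested exactly once. The headline summary
is the unweighted mean of per-fold metrics; pooled-count metrics are kept
as a secondary output of `CVResult`.

MCC is the standard Matthews coefficient with the square root over the
denominator product, defined as 0 when any factor vanishes. (Without the
root the quantity is unbounded and cannot be the coefficient in [−1, 1]
that the metric names.)

Threshold sweeps default to 101 evenly spaced cutoffs between the minimum
and maximum observed decision value; sensitivity is non-increasing and
specificity non-decreasing along the grid by construction. Score graphs
report the per-sequence decision-value series split by true class, the
misclassification counts and FPR = FP/(FP+TN).

## Synthetic data generator

Positives are drawn residue-i.i.d. from a weight profile that mirrors the
aromatase family's composition qualitatively: L ×2.0, F/P/S/V ×1.5,
C/W ×0.3, everything else ×1.0 over a uniform background (negatives are
uniform). Defaults: 100 positives + 100 negatives, lengths uniform in
150–500 (the aromatase enzyme itself is ~503 residues and the family's
length profile sits in the few-hundred range), seed 42. Near-duplicate
records for redundancy-reduction tests substitute residues independently
at a mutation rate (default 0.02, keeping expected identity ≈ 98%).
Synthetic PSSM files give the observed residue's column a high score
(4–9) and others low (−4–2), so profile features carry the same
class-correlated signal as the sequences.

All randomness flows from one integer seed with a separate documented
stream per operation; outputs are byte-identical across runs.

What the generator does **not** emulate: positional structure, domains,
evolutionary relatedness between sequences, or realistic pseudo-count
PSSMs derived from alignments. Passing tests therefore demonstrate that
the pipeline recovers compositional class signal correctly and
deterministically — not that any particular accuracy carries over to real
UniProt-derived data, where the classes are less cleanly separable.

## Numerical and design choices

* Identity tie-break: see curation above (−10⁻⁶ gap penalty).
* SVM-light writer emits 6 significant digits and omits zero components;
  the paired reader accepts any float literal, so round-trips are stable
  at the printed precision.
* Constant-PSSM convention: normalize to all zeros.
* Fold means are unweighted; empty-class folds are prevented by
  stratification rather than patched after the fact.
* A tie at the decision threshold predicts positive.
* The `simulate`/`curate`/`featurize`/`train`/`cv`/`predict` subcommands
  are thin wrappers over the library and log a provenance header
  (version, subcommand, parameters) on every run.

## Problem sizes

Default test and demonstration runs use 100+100 sequences of length
150–500 for classification experiments and ≤20-sequence fixtures for
alignment-based redundancy checks; the exact-alignment identity is
quadratic in sequence length and in dataset size, so curation of much
larger collections is the slowest step and is best run once and cached via
`curate`'s FASTA output.

## Known limitations

* The CD-HIT stand-in is exact-alignment greedy clustering; cluster
  membership can differ from CD-HIT's heuristic on borderline pairs.
* PSSM profiles are treated as given inputs; the package neither runs
  PSI-BLAST nor builds profiles from alignments.
* Kernel parameters for AAC/hybrid/PSSM are defaults, not tuned optima.
* Single binary classification only; no probability calibration, no
  multi-class support, no ROC/AUC machinery beyond the threshold sweep.
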