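# Methods

## Data model

A phosphosite is identified by a substrate accession and a 1-based
position whose residue must be S, T or Y.  `seqio.centralize` cuts the
13-residue window at offsets −6…+6 around it; offsets that run past a
protein terminus are padded with the placeholder `J`, which by
construction can only occur as a contiguous prefix and/or suffix.  The
canonical amino-acid order `ACDEFGHIKLMNPQRSTVWY` indexes every matrix
column; `J` is never a column.  Duplicate (kinase, site) observations
in the input table are retained as separate counts: the counts reflect
the table as given.

Rows that cannot be resolved — accession missing from the FASTA,
position beyond the sequence, or a non-acceptor residue at the named
position — are skipped and tallied per reason rather than aborting the
build, since curated tables routinely contain isoform and
sequence-version mismatches.  The skip summary is part of the model's
diagnostics and is always logged by the CLI.

## Probability and information matrices

For each kinase the residue counts per position are converted to
probabilities

    p(i, j) = (c(i, j) + pc) / (n_eff(j) + 20 · pc)

where `n_eff(j)` is the peptide count minus the J placeholders at
position j, and the pseudocount `pc` defaults to 0 — profiles built
from as few as 30 peptides stay faithful to the observed counts, and
the logo convention 0·log2(0) = 0 handles empty cells.  A position
observed only as placeholders (`n_eff = 0`) is flagged unusable and
carries an all-zero column (information 0), not a uniform one, even
with a positive pseudocount.

Position information content is the uncorrected Shannon form
R(j) = log2(20) − H(j), in bits.  No small-sample correction term is
applied by default; with the minimum of 30 peptides per profile the
chi-square filter (below) is the guard against noise, and a correction
would change the scoring matrix scale for all kinases.

Letter heights h(i, j) = p(i, j) · R(j) form the dense information
matrix.  This unfiltered matrix — including the phosphoacceptor column,
whose one-hot row contributes the S/T/Y class information — is the
scoring matrix of the predictor.  Chi-square filtering affects only the
displayed logo model.

## Background distribution

The default background is the pooled residue frequency over every
kinase's peptides at all flank positions (offset 0 and J excluded),
floored at 1e−6 and renormalized so chi-square expectations are never
zero.  In vitro substrate pools share one proteome-level composition,
so a dataset-wide background is the natural reference; `uniform` and a
user-supplied 20-value table are available alternatives.

## Chi-square filtering and anti-logos

Each flank cell (position ≠ 0, residue i) is tested with a 1-df
dichotomous goodness-of-fit on {residue i, not residue i}:

    e = n_eff · b_i
    X² = (o − e)²/e + (o − e)²/(n_eff − e)

without continuity correction, p from the χ²₁ survival function.  A
single raw α (default 10⁻⁴) is applied per cell with no
multiple-testing correction — the filter is a display threshold, not an
inference procedure, and a deliberately non-stringent α avoids
discarding weakly informative positions.  Significant enriched cells
enter the logo with their height h(i, j); significant depleted cells
enter the anti-logo with depletion height

    d(i, j) = ((e − o) / n_eff) · R_dep(j)

where R_dep(j) is the Shannon information of the position's deficit
column (the positive parts of e − o, normalized).  Anti-logo letter
heights have no single established definition; this convention makes a
position whose depletion concentrates on few residues score higher than
one with diffuse deficits, is strictly positive and monotone in the
deficit, and downstream code asserts only membership and ordering of
anti-logo cells, never absolute heights.

## Kinase class and ranking

A kinase is classed "Y" when strictly more than half of its observed
center residues are tyrosine, otherwise "ST" (ties go to the majority
class of the kinome).  Ranking restricts by default to the class
matching the query's center residue; `restrict="all"` disables this.
Scores are raw summed bits — no normalization by query length or
profile size.  Ties are broken lexicographically by kinase name and
ranks are dense 1…K, so output is a deterministic total order.  The
scorer accumulates position by position in a fixed order, making it
bitwise identical to a plain double loop over the 13×20 cells.

## Synthetic data generator

`synthetic` emulates recombinant-kinase substrate pools.  Four preset
PWMs encode classical archetypes — basic residues (R/K) at −3/−2
(PKA-like), proline at +1 (CDK/MAPK-like), acidic residues at +1/+3
(CK2-like), and acidic flanks at −3…+3 around a tyrosine acceptor
(EGFR-like) — each planting `sharpness` probability mass (default 0.9,
split evenly over the signal residues) into an otherwise uniform
residue distribution; S/T-class centers split mass 50/50 between S and
T.  Peptides are drawn position-independently from the PWM columns.
`random_pwm` draws additional kinases with three random sharp flank
positions each.

`make_benchmark` splices each sampled peptide into its own random host
protein (i.i.d. uniform residues, length 50) at a random position,
writing the exact TSV/FASTA dialects `seqio` reads plus a JSON truth
map of the expected centralized (possibly J-truncated) peptides.  The
first two sites of every kinase are pinned near the N- and C-terminus
so the overhang-padding paths are always exercised regardless of seed.

What the generator does **not** emulate: position-dependent residue
correlations, mass-spectrometry detection biases, site-localization
uncertainty, shared substrates between kinases, or realistic proteome
composition.  Passing recovery tests therefore demonstrates the
correctness of the estimation and ranking machinery under the stated
sampling model, not predictive performance on biological data.

## Numerical choices

- Probability columns are validated to sum to 1 within 1e−6;
  closed-form information values are exact to 1e−9 in tests.
- Backgrounds are floored at 1e−6 before renormalization.
- p-values come from `scipy.stats.chi2.sf`; tests cross-check against
  the independent df=1 closed form erfc(√(X²/2)) at 1e−10 relative.
- The profile store serializes floats at full `repr` precision through
  JSON, so write → read round trips are bit-exact.
- Problem sizes in tests and the acceptance script (200 peptides per
  preset for motif recovery, 20 kinases × 100 peptides for self-ranking,
  6 kinases × 40 sites for the end-to-end round trip) are chosen so the
  planted signals are unambiguous under the sampling model while the
  whole suite runs in seconds.

## Design decisions

- The scoring matrix is the **unfiltered** heights matrix including the
  phosphoacceptor column.  Filtering is described in the source
  literature only for logo display; a dense "information content score
  for each position and amino acid" implies the unfiltered matrix.
  Both choices are exposed indirectly: a caller can zero out cells or
  drop the center column of `profile.information.heights` before
  scoring if desired.
- The package is organized around a statsmodels-style pair —
  `KinaseSpecificityModel` (data + configuration) and
  `KinaseSpecificityResults` (fitted profiles, diagnostics,
  `summary()`, `predict()`) — with the operation-level modules
  (`seqio`, `motif`, `predictor`, `synthetic`, `cli`) underneath for
  direct use.
- Isoform/version mismatch handling during the site → sequence join is
  a skip-and-report policy (no fuzzy matching); the alternative of
  aborting on first mismatch makes large curated tables unusable.
- The logo image renderer is a small matplotlib stacked-letter
  implementation with residues colored by side-chain class (basic blue,
  acidic red, hydrophobic green, aromatic black, polar/uncharged
  magenta, no-side-chain orange).

## Limitations

- Positions are modeled independently; cooperative or correlated
  positions (e.g. priming phosphorylation) are outside the model.
- Scores are comparable across kinases for one query but are not
  calibrated probabilities; closely related kinases produce very
  similar scores and cannot be distinguished by sequence alone.
- Profiles estimated near the minimum of 30 peptides have noisy
  low-information positions; users should weight results by `n`.
- The class restriction is binary (S/T vs Y); dual-specificity kinases
  are assigned to whichever class dominates their observed sites.
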