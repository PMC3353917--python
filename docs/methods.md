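# Methods

This note records the models implemented in `randnat`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical choices that affect results.

## Structural descriptors

**PDB parsing.** `parse_structure` reads PDB-format text through
Bio.PDB and reduces it to a single-chain, single-model atom table: only
the first MODEL is kept (the convention for NMR ensembles), HETATM
records are ignored, and alternate locations resolve to the
highest-occupancy conformer (ties prefer altLoc `A`, then blank).
Residue serials are 1-based in record order.  Non-standard residues map
to `X` in the sequence and make sequence-based descriptors fail loudly
rather than silently skipping positions.

**Net charge** counts +1 per Lys/Arg and −1 per Asp/Glu.  Histidine and
the termini are treated as neutral — the simplest pH ≈ 7 convention, and
the one consistent with a near-zero expected charge for uniform random
sequences (2/20 positive vs 2/20 negative residues).  No pKa model is
attempted.

**Volume** is the sum of mean per-residue volumes (Zamyatnin 1972,
packaged as `data/residue_volumes.csv`), deliberately structure
independent so that experimental structures and predicted models are
measured identically.  Any fixed published table shifts all values by a
method constant; comparisons between classes are unaffected.

**Solvent-accessible surface area** uses the Shrake–Rupley construction:
each heavy atom's van der Waals sphere is inflated by the probe radius
(default 1.4 Å) and sampled with a Fibonacci point set (default 960
points per atom, relative error well under 1% for isolated spheres); a
point survives if it lies outside every other inflated sphere.  Radii
are a Bondi-style heavy-atom set (C 1.70, N 1.55, O 1.52, S 1.80 Å,
default 1.70); hydrogens are ignored.  The implementation is tested
against the closed form for isolated spheres, a Monte-Carlo point oracle
on random clusters, and Bio.PDB's independent Shrake–Rupley on the same
radii.

**Secondary structure** is a simplified Kabsch–Sander assignment over
four states.  The amide hydrogen is placed 1 Å from N opposite the
preceding carbonyl; the electrostatic H-bond energy
`0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` defines a hydrogen bond
below −0.5 kcal/mol; prolines do not donate.  Two consecutive i→i+4
turns mark an alpha helix (`H`); Kabsch–Sander parallel/antiparallel
bridge patterns mark strand (`E`); residues inside isolated 3/4/5-turns
are "other" (`T`); the remainder is coil (`C`).  Because `T` exists,
alpha + beta + coil can be below the chain length — which is what the
packaged per-class count parameters imply (the mean counts sum to ~56 of
70 residues).  A missing carbonyl O is reconstructed in the carbonyl
plane when the next residue's N is present; chains with more than 20% of
residues lacking N/CA/C are rejected.  This is a deliberately simplified
assignment, not an 8-state DSSP clone; absolute helix/strand counts can
differ from DSSP by a small method offset.

**Surface hydrophobicity** is SASA of {A,V,L,I,M,F,W,C,P} residues over
total SASA, a fraction in [0,1].

## Random sequences

Positions are i.i.d. uniform over the 20 standard amino acids; integer
i maps to the i-th one-letter code in alphabetical order.  Default
length is 70 residues, the chain length both classes share.  The novelty
stage that rejects sequences resembling natural proteins is a pluggable
predicate: the default accepts everything (a uniform draw of a 70-mer is
astronomically unlikely to match a natural protein), and an offline
k-mer-overlap screen against a user-supplied FASTA is provided.  A BLAST
search against NR would slot into the same interface; running one is out
of scope.

## Synthetic feature tables

The generator stands in for the original raw data (hundreds of PDB
chains, tens of thousands of predicted models of random 70-mers), which
cannot ship with the package.  Its defaults *are* the study conditions:
per-class feature marginals with the packaged printed means and SDs, 762
records per class after balancing, Gaussian shape.  Three shapes are
available per variable — `gaussian` (default), `skewed` (shifted gamma,
shape 4, skewness 1, matched mean/SD), and `flat-wide` (uniform with
matched mean/SD), the last reflecting the qualitatively broad, flat
distributions seen in the natural class.  Draws are clipped to physical
bounds (percentages to [0,100], the hydrophobic fraction to [0,1],
counts and areas to ≥ 0) with clipping logged; clipping slightly biases
the moments of variables whose Gaussian puts mass outside the bounds, so
moment-recovery checks use unclipped draws.

What the generator does **not** emulate: cross-variable correlation
(variables are independent by default; the real descriptors are strongly
correlated — %alpha with alpha counts, volume with surface), the exact
empirical shapes of the real classes, and any relationship between a
record's descriptors and an underlying 3D structure.  Consequently,
passing tests demonstrate that the pipeline's statistics and the
evolutionary search behave correctly on data with the published
marginal structure — not that the published classifier accuracy would be
reproduced on the original structures.  On independent Gaussian
marginals the four historically selected variables support a
Bayes-optimal accuracy of roughly 0.86, which is what the final
classifier approaches; the published 94.36% lived on real, correlated
data and is not reachable from printed marginals alone.

The printed fold-similarity table ships verbatim
(`data/table2_fold_hits.csv`): 32 misclassified and 32 correctly
classified random proteins with best structural hit, RMSD and Z-score;
"no chain" rows carry missing RMSD/Z.  The summary lines printed with
the original table (`TABLE2_PRINTED_SUMMARY`) do not exactly equal the
means recomputed from the printed columns; both are kept, and
`summarize_fold_hits` always recomputes rather than forcing agreement.

## Preprocessing

Outlier cutoffs are per-variable empirical quantiles (numpy linear
interpolation between order statistics) estimated *within each class*,
at 0.005 and 0.995 by default; a record is flagged when any variable
falls strictly outside its band (union semantics), so with 11
independent continuous variables the expected flagged fraction is about
1 − 0.99¹¹ ≈ 10.4%.  Per-class estimation is used because the recorded
flagged counts are reported per dataset.  A constant variable flags
nothing; a class too small to resolve the requested tail (< 1/0.005
records) warns and is left unfiltered.  Balancing subsamples the
majority class without replacement to the minority size with a seeded
generator, preserving record order.  Filtering always precedes
balancing.

## Statistical battery

All tests are two-sided with scipy backends: Shapiro–Wilk per class,
Wilcoxon rank-sum (Mann–Whitney U; exact for small tie-free samples,
midrank normal approximation with tie correction otherwise) for
location, Fligner–Killeen for dispersion.  The working significance
level in summaries is 0.01 and no multiple-testing correction is applied
(eleven variables, descriptive intent).  The rank-sum test is a test of
location shift; under a shift model that speaks to means, which is how
its p-value is read in the class summary.  Exact p-value variants differ
across software environments, so the test suite asserts calibration
properties (type-I error near nominal, exact-enumeration agreement for
n₁+n₂ ≤ 10) rather than any particular historical p-value.

## Evolutionary neural network

**Network.** Two hidden sigmoid layers, one sigmoid output; inputs are
z-scored with statistics from the training split only.  Hidden sizes
default to ⌈(d+2)/2⌉ for d selected inputs, the convention of the
Weka-style environment the original analysis used.  Training minimizes
binary cross-entropy with mini-batch SGD (batch 32, seeded shuffles) at
learning rate 0.3 and momentum 0.2 — rate and momentum follow that
environment; cross-entropy was chosen over squared error because with a
sigmoid output it removes the output-derivative factor and conditions
the plateau away, and the choice is not dictated by the design being
reproduced.  150 epochs are the default: on tables of ~1500 records the
CV misclassification at 150 epochs is indistinguishable from 500 (0.152
vs 0.151 on the standard synthetic table), and the lower default keeps a
full evolutionary run on one CPU inside minutes.  Deterministic given
the config seed.  Single-class training data yields a constant predictor
with a warning.  An output of exactly 0.5 classifies as "random"
(arbitrary, documented).

**Fitness.** 10-fold stratified CV misclassification, folds from a
seeded shuffle of a content-sorted copy of the table, so fitness is
invariant to record order.  Folds with equal training size are trained
simultaneously as stacked tensors — numerically identical in
distribution, ~10× faster in wall time.  Fitness is deterministic given
(mask, table, seed), so mask evaluations are cached within a run.

**Genetic algorithm.** Population 30, 10 generations, roulette-wheel
selection, single-point crossover, bitwise mutation at 0.01, elitism 1
(so the best-so-far fitness trace is monotone).  A misclassification
rate is a cost, so selection weights are 1 − rate; the literal
cost-proportional weighting (which would favour the worst networks) is
available as `GAConfig(literal_fitness_weights=True)` for fidelity
experiments.  All-zero chromosomes are redrawn at initialization and
assigned fitness 1.0 if created by mutation.  If every fitness is equal,
selection is uniform.  All randomness flows from one master seed through
`numpy.random.SeedSequence` spawns (initial population, GA steps, CV
folds, weight init).

**Outputs.** The final population's per-variable occurrence
probabilities identify robust variables (threshold 0.9 for "close
to 1"); the final classifier reports both a stratified-holdout accuracy
(the honest estimate) and the resubstitution accuracy of a refit on the
whole table, because "rate of correct classification on the whole data"
admits both readings.

## Pipeline and problem sizes

`run_pipeline` chains simulate/load → outlier filter → balance →
statistics → ENNA → final classifier → fold-hit summary, with every
stage seed derived from one master seed and logged in the report;
synthetic-mode defaults are the study's pre-filter sizes (902 natural,
20494 random).  The test suite exercises the full 762+762, 30×10,
10-fold configuration once (about four minutes on one CPU) and uses
smaller tables elsewhere; the acceptance script recomputes the headline
quantities at the study's printed sizes (18465 and 10000 draws for the
moment-recovery checks) in under a minute.

## Known limitations

- The secondary-structure assignment is 4-state and simplified; it is
  validated on ideal geometry and against its own H-bond definitions,
  not against DSSP output.
- Descriptor values carry method offsets (volume table, radii set,
  SS assignment), so absolute feature values should not be compared
  across packages — only within-analysis class contrasts are meaningful.
- The synthetic generator's independence assumption understates the
  separability real correlated descriptors would provide.
- The GA searches 2¹¹−1 masks with 30×11 evaluations at most; on such a
  small space it approaches exhaustive search (and is tested against it
  on 4-variable problems), but occurrence probabilities retain sampling
  noise across seeds.
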