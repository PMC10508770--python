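# Methods

`kinleak` is an audit harness for a familiar claim in computational drug
discovery: that a neural network reading a kinase's pocket sequence and an
inhibitor's SMILES string can predict binding affinity for compounds it has
never seen. The package implements the full audit — data standardization,
three splitting schemes, a sequence/SMILES CNN regressor, a junk-token
control, ten SMILES similarity measures with a 1-nearest-neighbor
label-transfer baseline — and a synthetic screen generator whose latent
structure makes the leakage mechanisms measurable and reproducible.

## Label standardization

All bioactivity labels are placed on a single "pActivity" scale, the
−log10 of a molar potency:

* `pKd = −log10(Kd)` for dissociation constants (records with Kd ≤ 0 are
  unphysical and dropped);
* pIC50 for single-dose percent-inhibition screens. Percent inhibition is
  first clipped to [2, 98] (so the log transform stays finite at the assay's
  resolution limits), then converted under single-site competitive binding
  with Hill slope 1 at screening dose D:

      f = p / 100,   IC50 = D · (1 − f) / f,   pIC50 = −log10(IC50 [M])

  with D = 0.5 µM by default. This form is strictly increasing in p, as
  pharmacology requires; an anti-monotone variant sometimes seen in print
  (IC50 = D·f/(1−f)) is kept behind `formula="literal"` strictly for
  comparison, never as a default. Sources reporting percent *activity* are
  bridged as inhibition = 100 − activity before conversion (conversion
  happens first, clipping inside it).
* Records with SMILES longer than 90 characters are excluded (strict
  inequality: 90 is kept, 91 dropped); pocket sequences must be exactly 85
  residues, with `-` marking missing residues.

Duplicate (kinase, inhibitor) measurements are rejected by the default
reader; an explicit `duplicates="mean"` mode aggregates replicates.

## Splitting schemes

* **standard** — each measurement independently assigned to
  train/validation/test (0.8/0.1/0.1 by default).
* **by_inhibitor** — 10% of the distinct compounds go to test, a disjoint
  10% to validation; every measurement follows its compound, so test
  compounds are unseen at training time.
* **by_group** — the generic grouped split: any record→group map (kinase,
  chemical scaffold, cluster) is kept intact within one fold. `by_inhibitor`
  is the special case group = inhibitor; a scaffold split is group =
  scaffold.

Grouped schemes fill folds by *count of groups* (the natural reading of
"10% of the ligands"); a record-count-greedy mode is deliberately not the
default. Fold sizes use largest-remainder rounding with ties broken in fold
order, which makes 80/10/10 exact whenever n divides and the assignment a
pure function of (scheme, seed, table order). Every split call owns a
dedicated `numpy` Generator seeded from its arguments, so draws elsewhere in
a program cannot shift assignments.

## The CNN regressor

Twin branches, DeepDTA-style: integer-encoded SMILES (length 90) and pocket
sequence (length 85) each pass through an embedding (default dim 128), three
consecutive valid 1D convolutions with filter counts (n, 2n, 3n) (default
n = 32; kernel width 4 on the SMILES branch, 8 on the pocket branch), ReLU,
and a global max pool; the concatenated branch outputs feed a dense stack
(1024, 1024, 512, 1) with ReLU and dropout 0.1. Training minimizes MSE with
Adam (lr 0.001, batch 256) and the reported model is the checkpoint with the
lowest validation loss — loss histories are recorded but never assumed
monotone.

The network is implemented directly in NumPy (forward, backward, Adam written
out; convolutions via stride-tricks windows and `tensordot`). That choice
keeps the package dependency-light and makes every run bit-reproducible from
its seed on a fixed platform; gradients are verified against central
differences in the test suite (checked away from ReLU kinks, where the
subgradient convention makes finite differences disagree by construction).
Dropout is applied after each hidden dense layer and on the pooled branch
outputs (`conv_dropout` toggles the latter).

Two profiles exist: the full-scale defaults above (300 epochs), and a
`desk()` profile (embed 32, base filters 8, dense 256/256/128, 30 epochs)
used by the experiments and tests so that a full audit runs in minutes on
one CPU. The desk CNN is deliberately small and briefly trained; the audit's
conclusions compare it against controls trained under *identical*
conditions, so its absolute concordance is not the quantity of interest.

## Junk-SMILES control

Each inhibitor's SMILES is replaced by one constant random string of the
same length over the SMILES character set, unique per inhibitor (collisions
redrawn). The string carries identity but no chemistry. The control CNN is
trained on the identical split assignment as the real-SMILES CNN; any gap
between the two measures how much chemistry the model actually reads.

## Similarity measures and label transfer

Ten symmetric, [0,1]-valued inhibitor similarities: MACCS-key Dice and
MCS-Tanimoto (over atoms+bonds, via RDKit behind a pluggable backend), plus
eight string kernels on raw SMILES text — normalized edit similarity
(1 − d/max len), the three-component CLCS (squared-normalized LCS, longest
common prefix, longest common substring, equally weighted), LINGO q = 3/4/5,
all-substring cosine, 4-gram cosine (TF), and tf-idf-weighted 4-gram cosine
with smoothed idf `ln((1+N)/(1+df)) + 1` fitted on training-fold SMILES only
(fitting idf on the full table would itself be leakage). Where the
literature leaves a normalization open, the cosine/Tanimoto choices above
were fixed once; each lives in its own function so an alternative is a local
change. LINGO operates on raw characters without ring-digit renumbering.

The label-transfer baseline predicts a query (inhibitor, kinase) by copying
the training label of the most similar training inhibitor *measured on that
kinase* — no interpolation, ties to the lexicographically smallest id. If a
kinase has no training measurements (impossible on near-complete matrices,
possible on sparse ones), the global training mean is returned and flagged.

## The synthetic screen

The generator reproduces the two redundancy structures the audit needs, with
defaults chosen to resemble a mid-sized selectivity panel:

* 8 kinase families × 5 members; each family's 85-residue pocket ancestor is
  uniform-random, members mutate each position at rate 0.05 (≈95% identity
  within a family, background ≈5% between families).
* 20 chemical scaffolds × 6 analogs. Each scaffold is a fixed, chemically
  valid core template with two substitution slots filled from a 16-substituent
  pool; every emitted SMILES parses in RDKit and stays ≤ 90 characters.
  Cores are deliberately string-distinct so that analogs of one scaffold
  share long core substrings that other scaffolds do not — string kernels
  must be able to recognize an analog series for the audit's premise
  (nearest training neighbor = close analog) to hold, as it does in real
  libraries built around hinge-binding cores.
* Labels on the pActivity scale: `clip(μ + a[scaffold, family] + b[i] + c[k]
  + ε, 4, 10)` with μ = 6 and independent zero-mean normal effects —
  scaffold-by-family σ = 1.0 (dominant: an analog series shares its
  selectivity profile across a kinase family), per-inhibitor σ = 0.2,
  per-kinase σ = 0.3, noise σ = 0.15. The clip range [4, 10] mimics real
  pActivity ranges and is rarely active at these scales.

What this emulates: complete measurement matrices, analog series, kinase
phylogeny, shared series-level selectivity. What it does not: mechanistic
structure–activity relationships, activity cliffs, assay-to-assay systematic
shifts, missing data (a masking option exists but defaults off), mutant
kinases. Passing the audit here therefore demonstrates the *logic* of the
leakage phenomena — that the measurement pipeline detects them when present
and that the controls behave as designed — not model performance on any real
screen.

## Experiment orchestration and determinism

A plan seed deterministically derives per-stage substream seeds (split, junk
map, generator, model init) via `SeedSequence`, so any stage reruns
identically in isolation. Within a plan, each (scheme, seed) split is
computed once and shared by every model — the junk control and the 1NN
baselines are only meaningful on the very same folds. 1NN cells rerun
bit-exactly; CNN cells also rerun exactly on the same platform because the
backend is NumPy, but cross-platform BLAS differences are tolerated by
comparing concordance at band rather than bit level.

## Problem sizes

The shipped experiments run on the default 4,800-record matrix: label
transfer over 5 split seeds (seconds per cell), the CNN comparisons over 3
seeds with the desk profile (≈45 s per training on one CPU, nine trainings
across the two CNN experiments). These sizes were chosen so the entire audit
— generation, splits, ten baselines, nine CNN trainings, metrics —
completes in roughly a quarter hour on a laptop core while leaving every
qualitative contrast far larger than its seed-to-seed spread.

## Known limitations

* The audit's CNN conclusions are calibrated for contrasts (real vs junk,
  CNN vs 1NN), not absolute benchmark numbers; the desk profile underfits
  relative to a 300-epoch GPU run by design.
* The MCS measure depends on RDKit's FMCS search; a timeout (default 10 s)
  guards pathological pairs, returning the best substructure found so far.
* String kernels treat SMILES as raw text; two different writings of the
  same molecule are different strings. The generator emits each analog in
  one canonical writing, so this does not affect the shipped experiments.
* `read_bioactivity_csv` trusts its schema config for units; it cannot
  detect a mislabeled unit column.
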