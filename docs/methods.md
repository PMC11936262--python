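# Methods

## Residue taxonomy

For one protein with several structure entries mapped to the same full-length
sequence, each position is classified from the entries' Cα presence masks:
present in all → *modeled*; absent in all → *hard missing*; otherwise *soft
missing*. The rule is a pure function of the presence matrix, implemented as a
vectorised kernel over (entries × positions) so corpora classify in bulk.

Two boundary situations are resolved deliberately:

* a position never covered by any entry's construct is indistinguishable,
  under the Cα rule, from one that was in the construct but unresolved; it is
  labelled hard missing (a warning notes the convention);
* with a single entry, soft missing is undetectable; classification proceeds
  with a warning and emits only modeled/hard labels.

Maximal runs of hard-missing positions form regions tagged *short* (≤ 30
residues) or *long* (> 30). Region sets are derived from the realised label
vector, so tags always reflect actual run lengths, and segmentation is
idempotent.

Solved/unsolved labelling for coverage-annotated proteins marks every position
inside any annotated range as solved (overlaps merged, 1-based inclusive
bounds); a protein with no ranges is entirely unsolved.

## Score tracks and thresholds

pLDDT is read from the temperature-factor column of predicted-model files
(gemmi handles PDB and mmCIF); all atoms of a residue must agree to 1e-6, the
file must cover residues 1..L exactly, and files whose values all lie in
[0, 1] are rejected rather than rescaled (the package works on the 0–100
scale). B-factor columns carry two decimals, so parsed values are rounded to
two decimals; this makes simulated-fixture round-trips exact.

IUPred long-mode tables (`# POS RES IUPRED`, three whitespace-separated
columns) are validated position by position against the sequence. Sequences
shorter than 16 residues cannot be scored by IUPred and receive an all-zero
track, treating very short peptides as having negligible disorder content.

Thresholds are pLDDT 70 and IUPred 0.5 throughout. A residue at exactly 70 is
high-confidence and one at exactly 0.5 is disordered; the same conventions
drive the quadrant assignment (Q1: ≥ 70 & < 0.5; Q2: ≥ 70 & ≥ 0.5; Q3: < 70 &
< 0.5; Q4: < 70 & ≥ 0.5) and the IUPred baseline, keeping the boundary
behaviour consistent across every module.

## Correlation and composition analyses

Correlations are computed **across proteins on raw counts**: per protein, the
number of residues in each class versus the number with pLDDT ≥ 70 (and < 70),
IUPred < 0.5 (and ≥ 0.5), per amino-acid letter, and optionally per
secondary-structure element type from an annotation track. Counts are not
normalised by protein length; since every count scales with length, the
reported r values partly reflect shared length variation, which is the level
at which these relationships are usually displayed. Zero-variance inputs make
r undefined; it is reported as NaN with a warning, never coerced to 0.

Composition profiles are per-class letter frequencies over the 21-letter
alphabet (20 standard residues + X); enrichment divides a class's frequencies
by the modeled class's.

## The classifiers

*Baselines.* pLDDT < 70 → hard missing, else modeled; IUPred ≥ 0.5 → hard
missing, else modeled. Both are pointwise and never predict soft missing, so
soft-missing residues count as negatives for both targets when baselines are
scored.

*Recurrent labeler.* Each position is encoded as 23 features: a one-active
token over 20 amino acids plus an unknown token (any non-standard letter),
pLDDT/100 (both score dimensions then share the [0, 1] scale), and IUPred.
Sequences are zero-padded to a standardized length with an off-mask, or
truncated to it with a warning (the tail is then excluded from evaluation).
The network is a single-direction LSTM layer (a bidirectional switch exists
but is off by default) into a dense softmax over the three classes, trained
with Adam on categorical cross-entropy averaged over real positions only.
Proteins with fewer than five hard-missing residues are discarded before
training to counter the modeled-class imbalance; no class weighting is
applied.

The LSTM is implemented directly in numpy (combined input+recurrent weight
matrix, forget-gate bias 1, full backpropagation through time, float32);
gradients were verified against central differences to ~1e-4, the float32
noise floor. Batches are truncated to their longest real sequence, so padding
costs nothing. Training is deterministic given the seed (initialisation and
batch shuffling share one generator).

Presets follow the published configurations: X-ray — standardized length
1,500, 256 hidden units; SPA — 2,500 and 300. Default schedule: 30 epochs,
batch 32, learning rate 1e-3, validation fraction 0.1 — all overridable in
`TrainConfig`. For the reduced-scale runs used in the test suite and the
acceptance script (200 proteins, standardized length 800, 64 hidden units)
the schedule is batch 8 at learning rate 2e-3 for 30 epochs: with only ~160
training proteins, batch 32 yields five optimizer steps per epoch and the
network is still far from converged after 30 epochs, so smaller batches are
used to reach convergence at this corpus size.

## Evaluation

Per-class metrics are one-vs-rest per-residue confusion counts with
precision = TP/(TP+FP), recall = TP/(TP+FN), and F1 their harmonic mean. A
metric with a zero denominator is reported missing (None/NaN), never 0 — a
model that makes no positive predictions has undefined precision, not perfect
or zero precision.

Region-stratified metrics segment hard-missing runs **independently in the
prediction and in the truth** and score per-residue membership in short (or
long) regions. A long truth region fragmented by one mispredicted residue
becomes two short predicted runs: its positions are long-target false
negatives and short-target false positives. This reading makes region-level
scores strictly harder than class-level ones, matching the observed drop via
increased false positives.

The prioritisation screen selects sequences with high-confidence pLDDT ratio
≥ 0.8 **and** predicted-modeled ratio ≥ 0.8 **and** length strictly greater
than 200. Both ratio comparisons are inclusive; the length comparison is
strict ("over 200 residues").

## Synthetic corpus generator

The generator emulates the statistical structure the analyses rely on, not
protein physics:

* **Truth architecture.** Sequences (default 100 proteins of 300–800
  residues) are laid out as alternating segments whose class is drawn from
  `class_weights` (default 0.70/0.20/0.10 for modeled/hard/soft region
  budget). Hard segments draw their length from the short/long mix (default
  0.7 short, uniform 1–30, else uniform 31–90); modeled segments are uniform
  10–60 and soft segments 2–20. A one-residue modeled spacer is forced between
  adjacent non-modeled segments so run segmentation is unambiguous.
* **Observations.** Default 2–6 entries per protein. Modeled positions are
  present everywhere, hard-missing nowhere; soft-missing positions appear per
  entry with probability `soft_visibility` (default 0.5) and each soft column
  is re-sampled until it is neither all-present nor all-absent, making the
  planted truth exactly recoverable (a `require_recoverable=False` switch
  disables this for robustness work; real data contain unrecoverable soft
  residues).
* **Scores.** Per-position normal draws at class-conditional locations —
  pLDDT 97.1/84.4/55.5 and IUPred 0.2/0.29/0.38 for modeled/soft/hard, scales
  (3, 8, 12) and (0.08, 0.12, 0.15) — are moving-average smoothed over a
  5-residue window to mimic along-sequence autocorrelation (the window is a
  modelling choice; the smoothing blurs class boundaries realistically), then
  clipped to the legal ranges. Clipping after smoothing keeps the class
  medians at the target locations, which a truncated draw would bias. Scores
  are quantised to file precision (2 decimals pLDDT, 4 IUPred) so fixture
  round-trips are bit-exact.
* **Composition.** Hard-missing stretches draw letters with K/E/S/P weighted
  3× and W/Y/F/L/I/V 0.35× against a uniform background; soft-missing
  stretches use intermediate weights (1.8× / 0.65×) — the polar/charged
  enrichment and hydrophobic depletion characteristic of disordered regions.
  An `unknown_rate` (default 0) injects 'X' to exercise the unknown token.

What the generator does **not** emulate: realistic 3D coordinates (only Cα
presence matters), B-factor physics, experiment-group resolution differences,
inter-protein homology, and real pLDDT/IUPred error structure (their errors
here are independent given the class, which makes the synthetic task easier
than real disorder prediction). Passing tests therefore demonstrate that the
machinery is correct and self-consistent, not that the trained labeler would
reach the same scores on real corpora.

## Numerical and degenerate-input conventions

1-based inclusive coordinates everywhere. Structure inputs must be numbered on
the full-length sequence; insertion codes and negative residue numbers are
rejected, out-of-range numbers are ignored with a warning, and a structure
file with no atoms at all is a legal all-absent observation. Fixture PDB files
are CA-only ATOM records on a straight line with 3.8 Å spacing. Training
aborts on non-finite loss. Identical seeds give byte-identical fixture sets.

## Problem sizes

The test suite and acceptance script use a 100-protein corpus for descriptive
statistics and a 200-protein corpus (160 train / 40 held out) at the reduced
preset (standardized length 800, 64 hidden units) for the learner checks;
these sizes give stable statistics while keeping a full run to a couple of
minutes on one CPU.

## Known limitations

Renumbering author-numbered PDB chains onto the full-length sequence is out of
scope (inputs are required to be pre-numbered). Corpus-scale retrieval from
PDB/AlphaFoldDB/UniProt, IUPred's energy model, and AlphaFold inference are
consumed as inputs, never reimplemented. The labeler trains on CPU in float32;
very long standardized lengths (the SPA preset) are supported but slow in this
implementation.
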