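# Methods

This note documents the models and procedures `ptmstar` implements, the
parameters that matter, the design choices made where the literature leaves
the procedure under-specified, and what the synthetic benchmark does and
does not establish.

## Data model

One *PTM type* (e.g. phosphorylation by a particular kinase group) is
treated as an independent binary classification problem over 9-residue
sequence windows.  The window width of 9 reflects the short-range substrate
specificity of most modifying enzymes; the centre residue is the candidate
site.  Positions within four residues of a terminus are padded with `X`
rather than discarded, so annotated sites near protein ends are kept; `X`
is encoded as the mean value of each index over the 20 amino acids, i.e. an
uninformative residue.

Negative windows are drawn only from centres whose residue type occurs
among the positives (e.g. S/T for a serine/threonine kinase) and that carry
no annotation of *any* PTM type — otherwise the classifier would partly
learn to distinguish serine from glycine rather than substrate from
non-substrate.  Redundancy is removed by exact 9-mer identity (first
occurrence kept); a 9-mer observed as a positive is also excluded from the
negative pool.  Exact identity is the only fully reproducible
redundancy-removal rule at this window length; no homology reduction is
attempted.

The split protocol: `round(0.67 · n_pos)` positives (round half up, so 861
positives give 577) go to training and the rest to test; negatives are then
sampled uniformly without replacement, five per positive *per split*, so
the 1:5 class balance is exact in both halves by construction rather than
in expectation.

## Index sets (HQI tiers)

Amino-acid indices are 20-value physico-chemical scales (AAindex1 format).
Given a clustering of a collection into groups of similar scales, the high
quality index tiers per cluster are:

* tier 1 — the medoid (the member minimising summed distance to its
  co-members): the cluster's most representative property;
* tier 3 — medoid plus the two members *farthest* from it, adding diversity;
* tier 5 — tier 3 plus the two non-medoid members *nearest* the medoid,
  reinforcing the medoid property.

Over eight clusters these give nested sets of 8, 24 and 40 indices.  The
farthest/nearest geometry needs a metric that the source literature never
names; this package uses **Euclidean distance between z-scored 20-value
vectors** (each index standardised over its own 20 values), so scales with
large raw magnitudes do not dominate.  A constant index z-scores to the
zero vector.  Exact distance ties are broken by accession lexicographic
order and logged.  The clustering itself is an input (a TSV of accession,
cluster id, medoid flag), not computed here; the packaged
`data/hqi_sets.yaml` records the eight published medoid accessions, while
the 24- and 40-member tiers are reproduced by running `select_hqi` on a
clustered collection.

Windows are encoded position-major (for each of the 9 positions, the d
index values of its residue).  Each index is min-max scaled to [0, 1] over
its 20 canonical values by default: sigmoid networks need bounded inputs,
and per-index scaling keeps every feature on the same footing.  A constant
index maps to 0.5.

## Networks and objective-specific checkpoint selection

Each classifier is a single-hidden-layer feed-forward network with sigmoid
units throughout, trained by **online** (per-sample) back-propagation on
squared error with momentum.  Defaults: learning rate 0.1, momentum 0.9,
1000 epochs, checkpoint every 50 epochs, initial weights uniform in
[−0.5, 0.5].  All are free hyperparameters exposed in `TrainConfig`; the
test suite trains for 40–60 epochs with checkpoints every 20, which already
separates the synthetic classes cleanly, and the library defaults remain
the conservative classical settings.  Sample order is reshuffled every
epoch from the run seed; training is bit-reproducible.

Over-fitting control is by *checkpoint selection*, not early stopping: deep
copies of the network saved during training are compared afterwards on an
evaluation split, and the checkpoint maximising AUC (objective A), recall
(R) or precision (P) at threshold 0.5 is kept — one training run therefore
yields three selected models, and a checkpoint from an early epoch can
legitimately win.  Ties are broken by higher AUC, then by the later
checkpoint.  Precision of a checkpoint that predicts nothing positive is
defined as 0.  Hidden sizes run over {2, 4, …, 20}, so a *family* for one
feature set holds 30 networks, 10 per objective.

Following the original evaluation protocol, the evaluation split used for
checkpoint selection defaults to the test split.  This means selected
per-network test metrics are optimistically biased (selection and reporting
share data); callers wanting an unbiased estimate should pass a held-out
third split as the evaluation data — the API takes evaluation data
explicitly everywhere, so this is a one-line change.

## Metrics

AUC is the Mann–Whitney statistic with ties counted as 0.5, computed from
midranks.  The tie rule is load-bearing: consensus vote sums take at most
N+1 distinct values, so tied score pairs dominate, and a tie-ignorant AUC
would be badly miscalibrated.  Recall and precision are standard, at a
fixed 0.5 decision threshold.

## Consensus schemes and star quality

Each member network casts a binary vote (score ≥ its threshold; a score
exactly at threshold votes positive).  For an N-member ensemble the vote
sum S_p ∈ {0..N} grades the prediction: *n-star quality* means n ≤ S_p, so
positives at level n are a superset of positives at n+1 (monotonicity), and
a prediction with S_p = m is negative at every level above m.  The reported
confidence S_p/N is a vote share, not a calibrated probability.

The six schemes: C10 = the A family of one feature set; C20 = A+R; C30 =
A+R+P (so S_p^30 decomposes exactly into the three family sums); C3 = the
best A, best R and best P network, each chosen by maximum evaluation AUC
("MAT" selection; ties to the smaller hidden size, then objective order
A < R < P); C9 = the MAT triples of the three HQI tiers; C12 = C9 plus the
triple of a fourth feature set (a legacy 10-index descriptor, configured as
an explicit accession list).  The meta-consensus picks the scheme with the
highest consensus AUC on the evaluation split, with deterministic
tie-breaking (C12 > C30 > C20 > C10 > C9 > C3).

**Two consensus AUCs.**  How a vote count becomes a ROC curve is a genuine
choice.  `evaluate_scheme` reports as `auc` the AUC of the graded score
S_p/N — the score the star semantics are defined on — and additionally
`mean_score_auc`, the AUC of the mean of the members' continuous outputs.
Binarising each member at a single threshold discards within-member ranking
information, so near the performance ceiling the vote-count AUC can sit a
point or two *below* the average single-network AUC even when the ensemble
is behaving well; the averaged continuous score does not suffer this
discretisation and, in every regime we measured, is at least as good as the
mean of its members.  The vote-count AUC remains the headline number
because it is the quantity the n-star decision rule actually realises.

## Synthetic benchmark

`generate_proteome` emulates a curated PTM database: i.i.d. background
sequences (uniform residue composition by default — this makes the
null-model check sharp; a vertebrate-like composition is available), with
`n_sites` 9-mers re-drawn from a position-specific motif and annotated at
their centres.  The default motif is basophilic-kinase-like (R/K at −3/−2,
S/T centre, P/G/A at +1, hydrophobic at +3).  The `strength` parameter
mixes motif and background per position; the centre is always drawn from
the motif's centre distribution so annotated residues stay modifiable even
at strength 0.  Implants are non-overlapping and ≥ 4 residues from termini,
keeping labels unambiguous.  The study conditions used throughout the tests
are 100 proteins of mean length 300 with 500 implanted sites — large enough
for stable AUC estimates (165 test positives, 825 test negatives), small
enough that the full 30-network family trains in well under a minute.

`generate_index_collection` draws well-separated cluster centres (sd 3) in
20-dimensional value space with isotropic member noise (`spread`, default
0.5) and computes medoids by brute force, exercising the full HQI selection
path; at `spread` 0 all members coincide and the medoid falls to the
lexicographically first accession.

What passing the synthetic benchmark shows: the pipeline recovers a strong
implanted signal (strength-0.9 motif → C30 consensus test AUC ≥ 0.9) and
does not hallucinate one (strength-0 → every network's test AUC in
[0.4, 0.6]).  What it does not show: performance on real proteomes, whose
sequences are not i.i.d., whose motifs are weaker and family-structured,
and whose annotations are incomplete (unlabelled true sites contaminate the
negative pool).  Reported numbers on synthetic data should not be read as
expected real-data accuracy.

## Numerical and degenerate-input choices

* Round-half-up for the 67% training fraction (0.67 × 861 = 576.87 → 577).
* AAindex `NA` values are rejected by default; an `impute` flag replaces
  them with the index's mean over defined values.
* Unknown/ambiguous residues are mapped to `X` on input with a logged count.
* A vote score exactly at the network threshold counts as positive.
* Single-class training or evaluation data raises immediately rather than
  returning degenerate metrics.
* All randomness (proteome, splits, weight initialisation, epoch shuffling)
  flows from explicit integer seeds; every artifact the CLI writes is
  byte-identical across reruns with the same config.

## Known limitations

* Squared-error online BP is faithful to the classical design but slower
  and less well-conditioned than modern batch cross-entropy training; it is
  a reference implementation, not a performance-oriented one.
* The recall/precision objectives act only through checkpoint selection at
  a fixed 0.5 threshold; no threshold tuning or class weighting is done.
* Exact-duplicate removal does not remove near-duplicates from homologous
  proteins; on real data the test split can therefore be optimistic.
* The consensus confidence is uncalibrated; star levels order predictions
  but S_p/N is not a posterior probability.
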