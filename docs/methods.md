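# Methods

This note documents the models, conventions and numerical choices behind
dockjury, in the spirit of a package's own methods section: what is
computed, under which assumptions, and what the synthetic tests do and
do not demonstrate.

## Structures and residue identity

A structure is a list of chains, each an ordered list of residues, each
an ordered map of heavy atoms.  Residue identity is author numbering —
`(chain_id, res_seq, ins_code)` — throughout; nothing is ever
renumbered, because assembly models keep the target numbering of the
exercise they come from and local scores must be attributable to those
exact residues.  Reading (gemmi-backed) keeps heavy atoms of standard
amino acids from the first MODEL, drops HETATM records, hydrogens, and
alternate locations other than blank/'A', and tolerates CASP TS headers.
Writing is fixed-column PDB with occupancy 1.00; local score tracks are
written into the B-factor column as `score × 100` (two decimals), the
plDDT convention, with 0.00 for unscored residues.  QMODE2 records carry
the global score to three decimals and per-residue values to two, "X"
for unscored, wrapped twenty per line; these precisions follow common
QA-submission practice since the exchange format itself does not fix
them.

## Chain grouping and mapping

Chains are partitioned into sequence groups by global pairwise alignment
(Biopython PairwiseAligner, end gaps free so modelling truncations are
not penalized); identity is identical positions over the shorter length,
threshold 0.95.  The threshold tolerates modelling gaps while separating
paralogs; chains shorter than 3 residues group by exact match only.

Model chains are assigned to reference chains within each group to
maximize the number of *shared inter-chain residue contacts* (5 Å
heavy-atom), the quantity every downstream interface score depends on.
When the product of per-group permutation counts is ≤ 720 the search is
exhaustive (exact up to six copies of one subunit); beyond that, a
greedy assignment seeded by a rigid superposition on the largest chain
pair is refined by pairwise swaps.  Ties resolve to the
lexicographically smallest assignment, so mapping is deterministic.
Per-chain-pair residue correspondences come from the same alignments.

## Global metrics

**Kabsch superposition** is the standard SVD solution with the
reflection correction; degenerate (collinear) point sets are rejected.

**GDT_TS** is the mean over cutoffs {1, 2, 4, 8} Å of the maximal
fraction of mapped CA atoms superposable within the cutoff.  **TM-score**
uses a single superposition and a single normalization: all chains
concatenated, `L` = total mapped residues, `d0 = 1.24(L−15)^⅓ − 1.8`
clamped below at 0.5 Å.  Both run on one deterministic fragment-seeded
search: fits seeded from contiguous fragments of lengths
{3, L/4, L/2, L} (strided starts), refined by k-nearest inclusion growth
(after each fit, the k closest residue pairs are refit over a ladder of
k), with every visited fit scored against all GDT cutoffs and the TM
sum.  Problems of ≤ 8 residues are searched exhaustively over every
residue subset, making the search provably optimal at test scale.  The
search is heuristic above that; determinism comes from the fixed seed
schedule and first-found tie-breaks.  Official multimeric TM values come
from external aligners with different searches, so agreement with
published numbers is expected only within a small tolerance.

**lDDT** is superposition-free and heavy-atom only, without the
stereochemistry penalty: all reference atom pairs within 15 Å whose
atoms lie in distinct residues (intra- and inter-chain alike) are tested
for preservation of their distance within {0.5, 1, 2, 4} Å; atoms absent
from the model count as unpreserved.  The pair list always comes from
the reference; local values are re-keyed to model residues through the
chain mapping so they can be written directly into B-factors and QMODE2
records.

## Interface metrics

Generic contacts are 5 Å minimal heavy-atom distance between residues of
distinct chains.  **fnat** is the fraction of reference contacts
reproduced by the model.  **DockQ** per chain pair combines fnat with
scaled interface and ligand RMSDs,
`DockQ = (fnat + 1/(1+(iRMSD/1.5)²) + 1/(1+(LRMSD/8.5)²))/3`,
with interface residues defined by a 10 Å backbone-atom criterion and
LRMSD measured on the smaller chain after superposing the larger; these
constants are the published DockQ definition.  **DockQ-wave** aggregates
per-interface DockQ values weighted by reference contact counts.
**QS-score** weights CB–CB (CA for glycine) residue pairs by
`w(d) = 1` for `d ≤ 5`, `exp(−(d−5)²/(2·4.28²))` to 12 Å, 0 beyond;
QS-global is Σmin/Σmax of weights over all pairs, QS-best the same
restricted to chain pairs interfacing in both structures (hence
QS-best ≥ QS-global always).  **ICS** is the F1 of the two contact sets.

**CAD** here is an analytic overlap proxy, not a Voronoi tessellation:
the contact area between two residues is approximated as
`Σ max(0, r_i + r_j + 1.4 − d)` over their heavy-atom pairs with
Bondi-style van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å) and a
1.4 Å probe, and `CAD = 1 − min(1, Σ|A_ref − A_model| / Σ A_ref)` over
residue pairs with positive reference area.  The proxy is monotone in
the same sense as tessellated contact areas and dependency-free; exact
parity with Voronoi-based implementations is out of scope, and output
metadata flags the flavor as `cad-proxy`.

**Patch scores** give per-residue interface accuracy.  Interface
residues are those of the *model* in any 5 Å inter-chain contact; the
patch around a residue is itself plus its 19 nearest residues by CB
distance in the model (any chain; `patch_size` configurable).  PatchQS
is the QS ratio restricted to residue pairs inside the patch.
PatchDockQ applies the DockQ functional form to the patch: fnat over
reference contacts inside the patch, the patch backbone RMSD after
superposing the patch as the iRMSD term, and the minor-chain patch RMSD
after superposing the majority chain's patch residues as the LRMSD
term.  The patch construction is this package's design — the scores it
mirrors are named in assessment practice without a published patch
definition — and is therefore exposed as configuration.

## The jury

The pairwise matrix entry `(i, j)` evaluates model `i` against model `j`
as pseudo-reference, with the chain mapping recomputed per pair; the
jury score of a model is the mean (default) or top-k mean of its row's
defined entries.  Unscored comparisons are excluded from means, never
imputed as zero: missing is not bad.  Global assembly quality combines
the {lDDT, TM, GDT, CAD} juries and global interface quality the
{QS-best, DockQ-wave, PatchQS, PatchDockQ} juries — equal weights by
default, configurable, since fitted combination weights are a
server-side artifact.  `D2R` replaces the weighted mean with the mean
reciprocal rank of the model across the metric group (competition
ranking for ties), which is already in (0, 1].  Ranking is by global
interface score, ties by assembly score then label.  The single-model
mode (`D2S`) runs the same machinery on the row of one query against an
external reference pool, and computes the combined local track directly
as the unweighted mean of the four local jury tracks (the deployed
server predicts this same target quantity with a trained network; the
direct mean is the regression target itself, not an approximation of
the network).

## Assessor evaluation

Pearson and Spearman correlations are scipy's, with average-rank ties.
ROC AUC is computed by explicit pair counting,
`P(pred_pos > pred_neg) + ½ P(tie)`, after binarizing observed scores at
0.5 (configurable; per-metric assessment thresholds vary between
exercises).  Selection loss is `max(observed) − observed[argmax(pred)]`
with predicted ties resolved to the first index.  The composite totals
sum `0.5·Pearson + 0.5·Spearman + AUC` per local metric
(PatchDockQ, PatchQS, CAD, lDDT; maximum 8) and add `(1 − Loss)` per
global metric for the QSCORE total (DockQ-wave, QS; maximum 6) and the
SCORE total (GDT_TS, TM; maximum 6).  An undefined term (zero-variance
correlation, single-class AUC) contributes zero to its total.

## Synthetic data generator

The generator builds idealized helical toy assemblies: poly-amino-acid
chains with backbone N, CA, C, O plus CB on an α-helical trace (rise
1.5 Å, 100°/residue, CA radius 2.3 Å), arranged with C_n symmetry for
homomers of three or more copies and as a staggered collinear row for
dimers and heteromers.  Inter-axis spacing is searched deterministically
so the closest heavy-atom approach between adjacent chains lands in
3.2–4.2 Å, giving a dense 5 Å interface; the 2.7 Å z-stagger of the row
layout breaks exact swap symmetry so chain mapping is unambiguous, as in
real (asymmetric) interfaces.  Heteromer groups use distinct residue
types (ALA, GLY, SER, …) so sequence grouping separates them cleanly.

Decoy pools consist of the reference copy plus one decoy per ladder
rung; each rung applies a rigid rotation/translation to one chain about
its centroid followed by i.i.d. Gaussian coordinate noise on that
chain's atoms.  Two design choices matter:

* **Rigid modes follow a fixed schedule of mutually orthogonal or
  antiparallel axes and directions** (rotation axes x, y, z, −x, …;
  translation directions y, z, −y, −z, …), with only the noise drawn
  from the per-rung seeded RNG.  Models built by independent methods err
  in nearly orthogonal directions of a very high-dimensional
  conformation space; a single chain's rigid-body space has only six
  dimensions, so isotropically random rung directions would be strongly
  mutually correlated — the relative orientation of two rungs' errors
  would be a coin flip, and no consensus scheme could then order the
  ladder reliably.  The fixed schedule restores, at toy scale, exactly
  the decorrelation property that makes consensus scoring work on real
  pools.
* **Default ladder** `(5°, 0.5 Å, 0.05 Å) → (10°, 1 Å, 0.15 Å) →
  (25°, 3 Å, 0.4 Å) → (60°, 8 Å, 1.0 Å)`: rung magnitudes are well
  separated so the quality levels are distinguishable by every metric,
  spanning near-native to wrong-interface without fully destroying
  chain mapping.

What the toys emulate: chain interfaces, graded and decorrelated model
errors, stoichiometry variety, missing-residue and relabelling edge
cases.  What they do not: side-chain packing, realistic contact-density
distributions, clash relief, sequence diversity within a chain, domain
motion.  Passing tests therefore demonstrate the correctness of the
formulas, mappings, aggregation and formats, and the qualitative
behavior of consensus ranking — not parity with official scoring stacks
on experimental structures, which differ at the level of search
heuristics and tessellated contact areas.

## Problem sizes and determinism

The test suite and the acceptance script run on pools of five models
with chains of 10–16 residues (2–3 chains per assembly), sizes at which
the superposition search is exact or near-exact and a full jury run
takes seconds.  All randomness flows through explicit integer seeds
(numpy `default_rng`); identical inputs and seeds produce byte-identical
PDB, QMODE2 and TSV outputs.

## Known limitations

* The CAD proxy is not voronota-parity; treat absolute CAD values as
  internally consistent rather than comparable to tessellation-based
  numbers.
* The GDT/TM search is heuristic for assemblies larger than 8 mapped
  residues; scores are reproducible but can differ from other
  implementations' searches by small amounts.
* DockQ-style recall metrics reward models that over-predict contacts;
  in small pools this can slightly favor contact-inflated decoys in the
  jury.  The symmetric metrics (QS, lDDT, CAD, PatchQS) do not share
  this bias, and the combined interface score dilutes it.
* Nucleic acids, ligands, mmCIF input and multi-model ensembles are out
  of scope.
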