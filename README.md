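# dockjury

Consensus ("jury") quality assessment for predicted protein quaternary
structures: score, rank and annotate multimeric models from any source,
with or without a native reference structure.

## The problem

Structure predictors emit many alternative models of a protein complex,
and the native structure is unknown at prediction time.  Estimation of
model accuracy (EMA/QA) asks: which model is best, and which interface
residues can be trusted?  A robust answer, used throughout blind
assessment exercises, is *consensus scoring*: a model's quality is
estimated as its average structural similarity to the other models of
the same target — each pool member takes a turn as a pseudo-reference.

For a pool of models `m_1 … m_n` and an assembly similarity metric `S`,
the jury score of model `i` is

    jury_S(i) = mean_{j != i} S(m_i, m_j)

computed for eight metrics: QS-best, DockQ-wave, TM-score, oligomeric
GDT_TS, lDDT, a contact-area-difference (CAD) proxy, and the local
PatchQS / PatchDockQ interface tracks.  Global assembly quality is the
mean of the {lDDT, TM, GDT, CAD} juries; global interface quality the
mean of the {QS-best, DockQ-wave, PatchQS, PatchDockQ} juries; the
per-residue interface score is the mean of the four local jury tracks.
Three variants are provided: a linear combination (`D2`), a mean
reciprocal-rank combination optimized for ranking (`D2R`), and a
single-model mode that scores one query against an external reference
pool (`D2S`).

The package also implements the surrounding machinery as first-class,
tested components:

* PDB reading/writing (via gemmi), CASP QA **QMODE1/QMODE2** exchange
  files, and B-factor annotation of models with local scores (`score*100`,
  the plDDT convention);
* stoichiometry strings (`"A3"`, `"A1B1C1"`), modal stoichiometry voting
  over template hit tables, sequence-based chain grouping, and
  contact-overlap-optimal model-to-reference chain mapping;
* the reference-based metrics themselves (lDDT, TM, GDT_TS, fnat, DockQ,
  DockQ-wave, QS-global/QS-best, ICS, CAD proxy, patch scores);
* a CASP-assessor evaluation layer (Pearson/Spearman, ROC AUC by pair
  counting, top-1 selection loss, and the LOCAL/QSCORE/SCORE composite
  totals);
* a seeded generator of synthetic reference complexes and graded decoy
  pools, so the full stack is testable without any downloads.

## Worked example

Generate a synthetic homodimer target with a four-rung decoy ladder and
rank the pool with the consensus engine:

```sh
dockjury make-decoys --stoichiometry A2 --length 12 --seed 1 --out-dir decoys
dockjury qa decoys --target T1 --out-dir qa_out
head -6 qa_out/ranking.tsv
```

```
rank  model   assembly_score  interface_score  jury_CAD  jury_DockQwave  ...
1     rung00  0.8090          0.7177           0.8421    0.6997
2     rung01  0.8048          0.6923           0.8414    0.6615
3     rung02  0.7667          0.6880           0.8112    0.6747
4     rung03  0.7030          0.5457           0.7340    0.5244
5     rung04  0.6522          0.4762           0.7184    0.3664
```

`rung00` is the unperturbed reference copy and `rung01`–`rung04` are
decoys of decreasing quality; the jury ranks them in the true order
without ever seeing the reference labelled as such.  `qa_out/` also
contains a QMODE2 file (global interface score plus one local score per
residue for every model), per-model PDBs with the combined local score
×100 written into the B-factor column, and a `manifest.json` echoing the
full configuration.

Scoring a single model against a known reference prints the whole metric
table:

```sh
dockjury score decoys/rung01.pdb decoys/rung00.pdb
```

```
metric      value
lDDT        0.9965
TM          0.9036
GDT_TS      1.0000
CAD         0.9795
fnat        0.8333
DockQ-wave  0.9307
QSglobal    0.9429
QSbest      0.9429
ICS         0.9091
...
```

Here the mild decoy preserves nearly all interatomic distances (lDDT
0.996) and five of the six native contacts (fnat 0.83); the assembly
TM-score of 0.90 reflects the small rigid displacement of one chain.  The assessor layer
is reachable via `dockjury eval <predictions.qmode2> <observed.tsv>`,
which prints the composite totals with a per-term breakdown.

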