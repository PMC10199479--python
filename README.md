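# depp — phage depolymerase prediction from protein sequence

Bacteriophage depolymerases (DPs) are phage-encoded lyases and hydrolases
that degrade the polysaccharide layers — capsules (CPS), exopolysaccharides
(EPS), and lipopolysaccharide (LPS) — that shield bacteria inside biofilms.
They are promising anti-biofilm and anti-virulence agents, but they are hard
to spot by homology: DP domains are often among the *least* conserved parts
of a phage genome, frequently buried inside receptor-binding tail spikes.
`depp` is a sequence-only machine-learning classifier for this problem: given
the translated gene products of a phage genome, it scores each protein with
a depolymerase probability and ranks the proteome so an experimentalist
knows which handful of genes to test first.

It is aimed at phage biologists and bioinformaticians who have annotated
phage proteomes (FASTA of translated ORFs) and want a ranked candidate list,
and at method developers who want a transparent, fully reproducible
featurization/training/evaluation pipeline to retrain on their own curated
sets.

## Model

Each protein sequence `s` of length `L` is mapped to a fixed 424-descriptor
vector **x**(s):

* **11 global physicochemical parameters** (Biopython `ProteinAnalysis`):
  molecular weight; aromaticity `f_F + f_W + f_Y`; Guruprasad instability
  index `II = (10/L) Σ DIWV(s_i, s_i+1)`; isoelectric point (bisection on the
  Bjellqvist charge model); GRAVY (mean Kyte–Doolittle hydropathy);
  helix/turn/sheet residue fractions; molar extinction coefficients
  `ε_red = 5500·n_W + 1490·n_Y`, `ε_ox = ε_red + 125·⌊n_C/2⌋`; mean Vihinen
  window-9 flexibility.
* **20 residue frequencies** and the **sequence length**.
* **49 + 343 grouped k-mer frequencies**: the 20 amino acids are partitioned
  into 7 physicochemical classes (hydrocarbon-R {G,A,V,L,I}; aromatic
  {F,W,Y}; sulphur {C,M}; positive {K,R,H}; negative {D,E}; polar uncharged
  {S,T,N,Q}; proline {P}); every di- and tripeptide window is reduced to its
  class string (e.g. AE → "15", LD → "15") and counted, normalized by the
  window count `L − k + 1`.

The classifier is a pipeline: degree-2 polynomial feature expansion →
min/max scaling to [0, 1] → a 1500-tree random forest (entropy criterion,
max depth 30, ≥3 samples per leaf, √p features per split). The reported
probability is the forest's positive-vote fraction. Model selection between
SVM (linear/RBF) and random forest uses nested cross-validation: 20
independent trials, the trial index seeding the shuffle and the learner,
with stratified 4-fold outer loops for generalization and 4-fold inner
grid searches (accuracy criterion) for hyperparameters, so selection never
sees the rows it is scored on. Reported accuracy `(TP+TN)/(TP+FP+TN+FN)`
and recall `TP/(TP+FN)` are means over all outer folds of all trials.

Training uses a 1:1 balanced table of positives and negatives whose lengths
are sampled across the positive set's 150–1267 aa range, so sequence length
carries no class signal. Because curated depolymerase sequences cannot be
redistributed with this package, a seeded synthetic generator provides
stand-in study conditions (composition-biased "depolymerase-like" positives
vs. background negatives); see `docs/methods.md` for exactly what it does
and does not emulate.

## Worked example

Simulate a balanced synthetic training set, train the final model, and rank
a 21-protein synthetic "proteome" containing one planted depolymerase-like
sequence:

```console
$ depp -q simulate --n 25 --kind positive-like --seed 11 --out pos.faa
$ depp -q simulate --n 25 --kind negative --composition background \
      --variability 60 --seed 12 --out neg.faa
$ depp build-table --pos pos.faa --neg neg.faa --out train.tsv
INFO depp: training table: 50 rows x 424 features
$ depp train --table train.tsv --out model.bin
INFO depp: training rf on 50 rows (seed=0)
INFO depp: model saved to model.bin (training hash a58e12043650)
$ depp rank --model model.bin --proteome proteome.faa --out ranks.tsv
INFO depp: ranked 21 proteins (0 skipped)
$ head -4 ranks.tsv
rank    protein_id      probability
1       synthpos_1      0.5282724867724863
2       synthneg_19     0.46625952380952407
3       synthneg_17     0.3626134920634921
```

The planted depolymerase-like protein (`synthpos_1`, a held-out draw from
the positive generator, not a training sequence) ranks 1st of 21 with a
vote fraction of 0.53 — above every background protein. In a real genome
scan you would send the top handful of ranked gene products to activity
assays; `depp recovery` then summarizes, across a panel of genomes, how
often the annotated depolymerase lands in the top k.

Other subcommands: `depp featurize` (emit the 424-column table for any
FASTA), `depp evaluate` (nested-CV comparison of `svm`/`rf` with bundled
`full`/`reduced` grids), `depp predict` (probabilities without ranking).
All stochastic commands take explicit seeds and are bit-reproducible.

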