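# metseg

Sequence-only identification of metal-ion binding residues in proteins.

The method slides a fixed-length window over each chain (terminal positions
are padded with the dummy residue `X`), labels each window by whether its
center residue binds the ion, and classifies windows by two complementary
routes:

1. **PWSM** — a pair of conservation-weighted position weight scoring
   matrices (one per class). Each matrix scores a window in [0, 1] using
   log-odds weights against a background composition, with every position
   weighted by its conservation index (100 minus the normalized Shannon
   entropy, scaled to [0, 100]). A window is called positive when the
   positive-matrix score exceeds the negative-matrix score. This route
   works well on ions whose binding sites are strongly position-conserved
   (e.g. the transition metals, whose preferred residues are C/H/D/E).
2. **SVM fusion** — a C-SVC with RBF kernel (libsvm defaults: cost 1,
   gamma = 1/n_features) over a staged multi-channel feature vector:

   | channel   | dim | content                                              |
   |-----------|-----|------------------------------------------------------|
   | `id_aa`   | 2   | increment of diversity of the window's 21-letter composition vs. the positive/negative training sources |
   | `s_p`     | 2   | PWSM pair scores on the residue window               |
   | `ss_freq` | 3   | H/E/C secondary-structure frequencies                |
   | `s_ss`    | 2   | PWSM pair scores on the 3-state SS window            |
   | `s_h`     | 2   | PWSM pair scores on the 6-class hydropathy recoding  |
   | `s_c`     | 2   | PWSM pair scores on the 3-class charge recoding      |
   | `s_sa`    | 2   | PWSM pair scores on the 4-letter binned-RSA recoding |

   Features are min-max scaled to [-1, 1] with ranges fitted on training
   data only.

Evaluation uses a balanced-subsampling repeated cross-validation protocol:
negatives are randomly subsampled to the positive count (10 repetitions by
default), each balanced set is split into 5 folds, every model component is
refitted inside each training split, and metrics (Sn, Sp, Acc in percent,
MCC) are averaged per fold; pooled-count metrics are reported alongside.
All randomness flows from one master seed.

## File formats

* **FASTA** — standard multi-record FASTA; non-standard residues (B, Z, U,
  O, J, ...) are normalized to `X`.
* **Sites TSV** — `chain_id<TAB>ligand<TAB>positions`, where positions is a
  comma-separated list of 1-based residue indices. Rows for the same chain
  are unioned; an optional ligand filter selects one ion's rows.
* **Annotations TSV** — `chain_id<TAB>ss_string<TAB>rsa_csv`; `ss_string`
  is over `{H,E,C}`, `rsa_csv` a comma-separated list of relative solvent
  accessibilities in [0, 1]; either field may be `-`.
* **Segment TSV** — `chain_id  center  label  residues  [channels...]`, for
  debugging and fixtures.

## CLI

```sh
# generate a planted-signal synthetic dataset
metseg simulate --n-chains 50 --chain-length 100 --theta 0.9 --seed 0 -o data/

# cross-validate (PWSM-only route)
metseg cv --fasta data/chains.fasta --sites data/sites.tsv \
    --window 7 --pwsm-only --channels s_p --seed 42 -o cv.tsv

# train the full SVM model and predict
metseg train --fasta data/chains.fasta --sites data/sites.tsv \
    --annotations data/annotations.tsv --window 7 --seed 42 -o model/
metseg predict --model model/ --fasta data/chains.fasta \
    --annotations data/annotations.tsv -o calls.tsv
```

`--ion` selects a per-ion default window (zn 7, cu 13, fe2 9, fe3 9, co 11,
mn 7, ca 9, mg 9, k 11, na 9) and filters the sites file by ligand id.
Prediction output columns: `chain_id position residue call s_pos s_neg
svm_decision`.

## Layout

```
src/metseg/
  segio.py      sequences, annotations, windows, recodings, file dialects
  pwsm.py       position weight scoring matrices + conservation index
  diversity.py  increment-of-diversity measure and ID features
  features.py   staged multi-channel feature assembly
  model.py      metrics, balanced-subsampling CV, SVM, model bundles
  synthetic.py  planted-signal dataset generator and recovery harness
  cli.py        metseg simulate / train / predict / cv
```
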