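# ppisite

Residue-level prediction of protein–protein interaction sites from sequence
features, using a Gaussian naive Bayes classifier (NBC) with a tunable
decision threshold.

## The problem and the model

Proteins interact through a minority of *interface residues* — surface
residues that bury more than 1.0 Å² of absolute solvent accessibility when
the complex forms.  Identifying them from sequence alone avoids expensive
structure determination.  `ppisite` frames this as per-residue binary
classification:

* **Features.**  Each residue *i* is encoded by the 20-column PSSM rows
  (PSI-BLAST log-odds, evolutionary conservation) of a window of *w*
  consecutive residues centred on *i*, concatenated N→C, plus the centre
  residue's relative solvent accessibility (RSA, 0–100%).  At the default
  *w* = 9 the vector is 20·9 + 1 = **181-dimensional**.  Windows overhanging
  a terminus are zero-padded, so a chain of length *L* yields exactly *L*
  vectors.
* **Classifier.**  With class *C* ∈ {0, 1} (1 = interface) and naive
  conditional independence, each feature follows a per-class univariate
  Gaussian.  The decision statistic is the natural-log posterior ratio

  ```
  s(x) = ln p(C=1)/p(C=0) + Σᵢ [ ln pᵢ(xᵢ|C=1) − ln pᵢ(xᵢ|C=0) ]
  ```

  and residue *x* is called interface iff `s(x) > θ`.  Because interface
  residues are rare (~12% of residues), θ is not 0 but is chosen by
  leave-one-chain-out cross-validation (LOOCV) to maximise the Matthews
  correlation coefficient (MCC); the default operating point is *w* = 9,
  θ = −0.88.
* **Evaluation.**  Sensitivity, precision, specificity, accuracy, MCC and
  F-measure from pooled (micro-averaged) LOOCV confusion counts, where each
  fold holds out one whole chain.
* **Supporting machinery.**  Surface/interface definitions from solvent
  accessibility, sequence-clustering statistics of interface residues
  (neighbour profiles and per-window composition tables), a seven-rule
  curation engine for building nonredundant heterodimer benchmarks from
  complex-level metadata, and a synthetic-data generator so the whole
  pipeline is testable without downloads.

Running PSI-BLAST, RSA predictors or any database retrieval is out of scope:
their outputs are consumed as plain-text files (FASTA, ASCII PSSM, RSA and
label TSVs).

## Worked example

Everything below runs offline on synthetic chains (12 chains, ~12% interface
prevalence, clustered labels, weak per-feature class separation):

```sh
ppisite simulate --out demo/chains --seed 7 --n-chains 12 \
    --length-min 60 --length-max 120 --separation 0.15 --metadata-rows 40
ppisite train --data demo/chains --window 9 --theta -0.88 --out demo/model.json
ppisite cv    --data demo/chains --window 9 --theta -0.88
```

prints the pooled LOOCV confusion counts and the six measures:

```
tp      tn      fp      fn
15      979     25      56
sensitivity     precision       specificity     accuracy        mcc     f_measure
0.2113  0.3750  0.9751  0.9247  0.2445  0.2703
```

Note the signature of an imbalanced problem: accuracy is high (92%) mostly
because the negative class dominates, which is why model selection uses MCC.
A grid search over window sizes and thresholds,

```sh
ppisite sweep --data demo/chains --windows 3,5,7,9 \
    --theta-min -1 --theta-max 1 --theta-step 0.1 --out demo/sweep.tsv
```

writes the full sweep TSV and reports the MCC-optimal operating point:

```
selected        window=3        theta=-0.90     mcc=0.2846      f_measure=0.3256
```

Per-residue scoring emits one row per residue with the log posterior ratio
and the thresholded call:

```
$ ppisite predict --model demo/model.json --data demo/chains | head -4
chain   position        residue log_ratio       class
syn0001 1       P       -8.090033       0
syn0001 2       T       -5.196551       0
syn0001 3       K       -4.076468       0
```

`ppisite stats` exports the interface-clustering tables (neighbour profile
and per-window composition) and `ppisite curate` applies the seven curation
rules to a metadata TSV with a per-rule audit trail.  Any flag can also be
supplied from a YAML file via `ppisite --config file.yaml <command>`.

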