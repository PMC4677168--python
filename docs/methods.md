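# Methods

## Classification model

A residue is described by `x = (x_1, …, x_n)` and a class `C ∈ {0, 1}`
(1 = interface).  Under the naive Bayes assumption the posterior factorises
as `p(C|x) ∝ p(C) · Π_i p_i(x_i|C)`; the shared normaliser cancels in the
posterior ratio, and the decision statistic is the natural-log ratio

    s(x) = ln p(C=1) − ln p(C=0) + Σ_i [ ln p_i(x_i|1) − ln p_i(x_i|0) ].

A residue is called interface iff `s(x) > θ` (strict; ties go to the
majority, noninterface, class).  Natural log is used throughout — the log
base only rescales θ, which is a free parameter anyway.

**Conditional density family.**  Each `p_i(·|c)` is a univariate Gaussian
with the per-class sample mean and population variance (ddof = 0).  The
features — PSSM log-odds scores and an RSA percentage — are real-valued,
which makes the Gaussian family the natural choice, and it admits an
independent external oracle (a reference Gaussian-NB implementation is used
in the tests to check the joint-log-likelihood difference to 1e-8).
Variances are floored at `1e-6` so that constant features (e.g. all-zero
terminal pad columns in a fold with no terminal windows of one class)
cannot produce infinite log densities.  All computation is done as sums of
log densities; raw density products would underflow at 181 features.

**Priors.**  Empirical class frequencies without smoothing.  Both classes
must be present at fit time — with a single class the posterior ratio is
undefined, so this is an error rather than a degenerate fit.

## Feature encoding

The vector for residue *i* is the PSSM rows of the length-*w* window
centred on *i* (odd *w*, default 9), flattened N-terminal→C-terminal, plus
the centre residue's RSA: `20·w + 1` values (181 at *w* = 9).  Decisions
taken where the encoding was underdetermined:

* **Terminal windows are zero-padded**, never dropped, so every chain of
  length *L* yields exactly *L* vectors and dataset residue totals equal
  chain-length totals.
* **One RSA slot**: the dimension count `20·w + 1` forces a single RSA
  value; it is the centre residue's.
* **PSSM scores are used raw** (the 20 integer log-odds columns, not the
  percentage block), with the column order fixed to the PSI-BLAST output
  alphabet and asserted at parse time.  No sigmoid or min-max rescaling is
  applied; the Gaussian class-conditionals absorb affine location/scale.

## Surface and interface definitions

From solvent accessibility: a residue is *surface* when its monomer RSA
reaches 5% (the comparison direction is exposed as a flag because the
convention is sometimes quoted in the buried direction; the default is
RSA ≥ 5% ⇒ exposed — the opposite reading would leave almost every residue
"buried" and interfaces empty).  A surface residue is *interface* when it
loses strictly more than 1.0 Å² of absolute accessibility between monomer
and complex.  Accessibility that *grows* upon binding is physically
suspicious and logged as a warning, not an error.  By construction
interface ⊆ surface, and raising the Å² threshold can only shrink the
interface set; both properties are tested.

## Evaluation protocol

Cross-validation is leave-one-chain-out: chains, not residues, are the
exchangeable units (residues within a chain are strongly dependent).  Each
fold refits on all other chains and scores the held-out chain; confusion
counts are pooled over folds before metrics are computed (micro-averaging —
a single metric set per operating point).  Macro-averaging is deliberately
not offered.

The fold models are obtained by subtracting the held-out chain's per-class
count/sum/sum-of-squares from dataset totals, which is algebraically
identical to refitting (a test verifies the equivalence against literal
refits) and makes a full grid sweep linear in the data size.  Within a
sweep, per-fold log ratios are computed once per window size and merely
re-thresholded for each θ, which also guarantees the sensitivity/specificity
monotonicity in θ exactly.

Metrics: sensitivity TP/(TP+FN), precision TP/(TP+FP), specificity
TN/(TN+FP), accuracy, MCC with the standard square-root denominator, and
F-measure (harmonic mean of precision and sensitivity).  Any metric whose
denominator is zero is defined as 0 with a logged warning.  Model selection
returns the grid row with maximal MCC; ties break to the smaller window,
then the smaller θ (prefer the simpler, more conservative model).  The
default θ grid is −1.00…1.00 in steps of 0.02.

## Clustering statistics

Interface residues cluster along the sequence; two summaries quantify this.
The neighbour profile counts, for every interface residue, interface
residues at each signed offset up to ±m.  The window composition table
gives, for windows centred on interface residues, the percentage containing
exactly k interface residues (k ≥ 1 since the centre counts).  Windows and
offsets never cross chain boundaries, and windows overhanging a terminus
are **truncated** rather than padded — padding would inject fictitious
noninterface residues and inflate the small-k bins.

## Curation rules

Seven ordered filters on complex-level metadata for dimeric structures:
(1) X-ray resolution strictly above 3.0 Å or any chain shorter than 50
residues; (2) homodimers (identical UniProt accessions); (3) missing-residue
ratio ≥ 0.30; (4) transmembrane complexes; (5) interface area outside the
inclusive 500–2500 Å² band; (6) sub-assemblies of larger complexes;
(7) sequence redundancy — within each precomputed >25%-identity cluster only
the first complex in input order is kept.  Boundary semantics are the
literal readings: resolution exactly 3.0 Å and length exactly 50 are
retained, missing ratio exactly 0.30 is rejected, the area bounds are
inclusive.  A rejected complex is attributed to the *first* rule it
violates; rules 1–6 are order-independent for membership, and only rule 7
depends on input order (a complex claims its clusters only after surviving
rules 1–6, so an earlier rejected complex never shadows a later clean one).
Annotation lookups (clustering runs, transmembrane registries, interface
areas) are consumed as metadata columns, never performed.

## Synthetic data generator

The generator emulates the statistical structure the method exploits, at
the scale of the curated training corpus it was developed for:

| parameter | default | why |
| --- | --- | --- |
| `n_chains` | 186 | training-corpus chain count |
| chain length | uniform 50–340 | mean ≈ 195, matching corpus residues/chains; minimum 50 mirrors the curation length rule |
| `interface_prevalence` | 0.12 | observed interface fraction (~11.7%) |
| `label_persistence` | 0.8 | P(next = interface \| interface); gives strongly clustered labels with mean run length 5 |
| `class_separation` | 0.5 sd | weakly informative features — real PSSM/RSA signals are weak (realistic MCC well below 1) |
| `pssm_sd` | 2.0 | spread of integer log-odds scores within a class |
| `rsa_class_means` | (25, 40) | interface residues are the more exposed class |
| `rsa_sd` | 15 | broad overlap between classes |

Labels follow a stationary two-state Markov chain: the interface
self-transition is `label_persistence`, and the noninterface→interface rate
is solved from stationarity so the long-run interface fraction equals
`interface_prevalence`.  PSSM scores are class-conditional Gaussians rounded
to integers (matching the printed PSI-BLAST format); RSA is class-conditional
normal clipped to [0, 100] and rounded to two decimals so file round-trips
are exact.  Amino-acid letters are uniform — composition modelling is out of
scope.  The generator writes the same FASTA/PSSM/RSA/label files the parsers
read, so it doubles as a format round-trip test.

What passing tests on this data do **not** show: real PSSM columns are
correlated (profiles evolve along the sequence), real feature–class
relationships are nonlinear and heteroscedastic, and real interface labels
depend on 3-D geometry, none of which the generator reproduces.  Results on
synthetic data bound what the implementation can do, not what the method
achieves on real complexes.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 30–200 chains
(≈3,000–40,000 residues), chosen to make the statistical assertions stable:
parameter recovery runs at 10⁴ residues (priors within 2/√n, means within 5
standard errors), the separated/null LOOCV contrast uses class separations
of 10 sd and 0, and the threshold sweep covers a 101-point θ grid.  Model
files are versioned JSON; an unrecognised format or version is an error,
not a best-effort load.

## Known limitations

* Only Gaussian class-conditionals are provided; a histogram/binned variant
  is out of scope.
* Only leave-one-chain-out CV is offered, and only micro-averaged metrics.
* The curation engine trusts its metadata table; it does not validate
  annotations against external databases.
* No posterior calibration: the log-ratio scale is comparable within one
  model but not across models.
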