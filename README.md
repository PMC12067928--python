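# decaysense

Differential-sensing diagnostics from chemiluminescence decay kinetics.

A molecular-rotor chemiluminescence probe added to serum emits a signal
whose decay speed depends on the biomolecular environment it binds: a
transient interaction (albumin-like) decays in minutes, a tight one
(IgG-like) persists for over an hour. Doping the serum with each compound
of a small-molecule library perturbs that decay differently for different
sera, so the array of per-compound decay half-lives forms a physicochemical
signature of the sample — a differential-sensing readout usable for disease
classification (e.g. Alzheimer's disease versus healthy controls) without
any single molecular biomarker.

`decaysense` implements the full analysis path from plate-level time series
to cross-validated diagnosis:

1. **Decay kinetics** — fit the one-phase decay model
   *I(t) = A·exp(−k·t) + c* to each well by nonlinear least squares and
   extract the half-lifetime *T*₁/₂ = ln 2 / *k* (minutes), the sole
   downstream feature.
2. **Flag screening** — normalize each compound's half-life by the same
   sample's no-compound (vehicle) baseline; call "flag" molecules whose
   normalized ratio deviates from the library mean by more than 3 × sample
   SD; score compounds by the AD/HC mean-ratio and rank a top-*n* panel by
   |log score|.
3. **Batch correction** — under the additive model
   *x*ᵢⱼ = *μ*ᵢ + Δ_g + *ε*ᵢⱼ with Δ_HC + Δ_AD = 0, estimate each batch
   baseline as *μ̂*ᵢ = ½(mean over HC + mean over AD) per compound and
   correct *z*ᵢⱼ = *x*ᵢⱼ − *μ̂*ᵢ.
4. **Diagnostic models** — standardize, reduce with PCA, and compare seven
   classifier families (logistic regression, LDA, QDA, SVM, KNN, decision
   tree, random forest) under stratified 3-fold cross-validation with
   accuracy, precision, recall, F1 and AUC; 2-D discriminant projections
   and unpaired *t* tests serve the small multi-disease cohorts.
5. **Synthetic data** — a seeded generator emits complete experiments
   (plates of decay traces, metadata, ground truth) with planted group
   effects, flag compounds and batch offsets, so every stage is testable
   end to end.

## Worked example

`examples/01_fit_decay_curves.py` fits noiseless traces generated from four
reference half-lifetimes spanning the serum-protein range and one noisy
trace:

```
noiseless traces (amplitude 1000, plateau 0):
  albumin      true T1/2 =   9.08 min   fitted =   9.0800 min
  IgG          true T1/2 =  72.70 min   fitted =  72.7000 min
  albumin+IgG  true T1/2 =   8.57 min   fitted =   8.5700 min
  serum        true T1/2 =  13.15 min   fitted =  13.1500 min

noisy trace, true T1/2 = 30 min: fitted = 29.70 min (plateau 50.8, rss 726, converged=True)
```

The fitter recovers noiseless parameters to machine precision and stays
within a few percent of truth at 2 % detector noise. The other examples
walk the remaining stages; `examples/02_flag_screen.py` plants six
compounds with a 2-fold AD-specific effect in a 96-compound library and
recovers all six in the top-6 panel:

```
fitted 582 wells; 582 converged
3xSD flag calls: ['C04', 'C18', 'C45', 'C62', 'C89']
top-6 panel (compound, AD/HC score):
  C89   2.15  planted
  C62   1.93  planted
  ...
```

Scores near 2 are the planted 2-fold effects; a compound missing from the
3×SD list (C31 here) can still rank in the panel, because flag calling
thresholds against the library spread while the panel ranks relative
effect sizes.

Each stage is also exposed as a thin CLI
(`decaysense simulate | fit | screen | correct | classify`); run any
subcommand with `--help`.

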