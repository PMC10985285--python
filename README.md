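# degenmhc

Pan-specific prediction of MHC class I peptide presentation and binding
affinity from a structure-derived *degenerate encoding* of peptide–MHC
pairs, with an attention-augmented ConvNeXt-style network.

MHC-I molecules display short peptides (8–11 residues) to T cells;
predicting which peptides a given allele binds is a central problem in
epitope discovery and vaccine design. Pan-specific predictors cover many
alleles with one model by conditioning on the allele's *pseudo sequence*
— the MHC α-chain residues found within 4.0 Å (any atom pair) of bound
peptides in crystal structures. `degenmhc` goes one step further and
encodes the *pairwise* residue interactions explicitly: each
peptide–allele pair becomes a 20 × 9 × 21 image-like array (ILA) whose
first channel marks, for every (amino-acid type *h*, core position *j*),
whether the allele has a contacting residue of type *h* at *j*, and
whose remaining 20 channels one-hot the peptide (0.90 hit / 0.05 miss)
along the 9 core positions. Affinities train on the bounded scale
`log50k(IC50) = 1 − log(IC50)/log(50000)`; the binder convention is
IC50 < 500 nM.

The package provides, end to end and without any external downloads:

- pseudo-sequence derivation from PDB structures (4.0 Å any-atom
  contacts, 9-mer complexes, mature-chain renumbering) plus the
  published 34- and 37-residue preset position lists;
- the degenerate encoder and flat baseline encoders (one-hot, BLOSUM62);
- an attention + ConvNeXt-style network (numpy, manual backprop) with
  presentation (AP) and affinity (BA) heads and AP→BA transfer learning;
- label transforms, random decoy generation, model-filtered decoy
  labelling, MS→affinity pseudo-labelling, train/test overlap removal;
- a synthetic contact-driven data generator for parameter-recovery
  testing, including toy PDB fixture writing;
- stratified cross-validation, accuracy/F1/MCC and Pearson/MSE metrics,
  length-stratified reporting, and an encoding-ablation harness with
  Shapiro and t-test columns;
- a `degenmhc` command-line interface over all of the above.

See `docs/methods.md` for the model, its assumptions and the design
choices.

## Worked example

Simulate a small pan-specific world, fit the presentation model, and
evaluate held-out records by peptide length:

```python
from degenmhc import PresentationModel, ModelConfig, make_world, simulate_presentation
from degenmhc.evaluate import length_stratified_report

world = make_world(seed=7)
train = simulate_presentation(world, 2000, positive_fraction=0.3, seed=8)
test = simulate_presentation(world, 500, positive_fraction=0.3, seed=9)

model = PresentationModel(train, world.contact_matrices(),
                          config=ModelConfig(head="ap", seed=0, epochs=10))
results = model.fit(seed=0)
print(results.summary())

report = length_stratified_report(results.predict(test), test,
                                  labels=[r.label for r in test])
print(f"held-out accuracy {report.accuracy:.3f}, F1 {report.f1:.3f}, MCC {report.mcc:.3f}")
```

which prints:

```
==========================================================
degenmhc Presentation (AP) model fit
----------------------------------------------------------
No. observations:                 2000
No. parameters:                  14657
Epochs run:                         10
Seed:                                0
Data hash:                    5f0131e6c0236cdd
State hash:                   445d60babf2472d8
Final train loss:               0.2776
Best val loss:                  0.3914
----------------------------------------------------------
val accuracy:                   0.8000
val f1:                         0.6386
val mcc:                        0.5012
==========================================================
held-out accuracy 0.798, F1 0.689, MCC 0.544
```

The summary carries everything needed to regenerate the fit (seed, data
hash, config); `results.predict_ic50(allele, peptides)` converts BA
outputs to nanomolar IC50s, and `results.plot_history()` draws the
training curves. On this 2,000-record example the model reaches ~0.80
accuracy against a quantile-labelled ground truth whose Bayes-optimal
accuracy is itself well below 1 because of the simulation noise; per-length
blocks (8/9/10/11-mers) are reported alongside the pooled numbers.

The same workflow is available from the shell:

```
degenmhc simulate --kind ms --n 2000 --seed 7 --out train.csv --write-matrices mats.npz
degenmhc train-ap --data train.csv --matrices mats.npz --seed 0 --out ap_model
degenmhc predict --model ap_model --peptides peps.txt --allele SYN-01 \
    --matrices mats.npz --out preds.csv
degenmhc ablation --n 2000 --k 5 --seed 1 --out ablation.csv
```

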