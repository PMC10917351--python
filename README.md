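# catrace

Prediction of T cell antigen specificity from single-cell intracellular
calcium dynamics.

Antigen-specific T cells flux calcium within seconds of T cell receptor
(TCR) engagement, long before surface activation markers appear. `catrace`
implements an end-to-end pipeline that exploits this: two-channel
ratiometric (Indo-1) time-lapse movies of T cell–dendritic cell cocultures
are segmented and tracked, per-cell 405/447 nm ratio traces are extracted
and normalized, and each cell is classified as antigen-specific or not —
either by a transparent dual-threshold rule or by a small 1D convolutional
network — with evaluation metrics tailored to the TCR-discovery use case.
It is aimed at imaging labs prototyping calcium-based antigen-specific
T cell identification, and ships a seeded synthetic-coculture generator so
the whole pipeline is testable without microscope data.

## The model

For each cell the readout is the background-subtracted emission ratio
R(t) = (I405 − bg405)/(I447 − bg447), a monotone proxy of [Ca²⁺]ᵢ, sampled
every 30 s for 2 h. Per field of view (FOV), a two-component Gaussian
mixture fitted to the pooled ratio values gives the resting ([Ca²⁺]ˡᵒ) and
elevated ([Ca²⁺]ʰⁱ) state means; traces are divided by the resting mean
(fold change) to remove inter-experiment scale drift.

Two classifiers operate on the normalized traces:

* **Dual threshold** — a calcium threshold θ_Ca and a dwell-time threshold
  θ_t: a cell is called antigen-specific iff it spends strictly more than
  θ_t seconds above θ_Ca. Both are fitted by exhaustive grid search.
* **1D CNN** — two convolution blocks, global average pooling, and a dense
  softmax head over the trace (optionally plus |ΔR| and instantaneous
  speed channels), emitting P_antigen-spe per cell, binarized at a
  selectable cutoff (default 0.47).

Per FOV, with predictions compared to the genotype and to human
majority-vote reactivity labels:

* model efficiency = reactive-labelled specific cells called / reactive-labelled specific cells
* overall efficiency = specific cells called / specific cells
* FDR = nonspecific cells called / positive calls

and classifiers are ranked by the weighted performance metric over the
strong (OVA-like) and weak (gp33-like) agonist conditions:

```
pM = 1 / sqrt( w_eff (1−eff_OVA)² + w_eff (1−eff_gp33)²
               + w_FDR FDR_OVA²   + w_FDR FDR_gp33² ),    w_eff = 1, w_FDR = 5
```

## Worked example

```python
import numpy as np
import catrace as ct
from catrace import preprocess as pp, classify as cc, evaluate as ev

cfg = ct.SimulationConfig(n_fov=10, cells_per_fov=100, seed=0)
ds = ct.simulate_dataset(cfg, n_days=2, conditions=("OVA_like", "gp33_like"))
pp.normalize_dataset(ds)                      # per-FOV fold-change normalization

rng = np.random.default_rng(0)
train, evaluation = ct.build_training_set(ds, "manual", ("ratio",),
                                          ct.SplitSpec(), rng, balance_eval=False)
hp = ct.CNNHyperparams(epochs=8, seed=0)
clf = cc.cnn_train(cc.cnn_build(hp, 1, cfg.n_frames), train, hp)

preds = cc.cnn_predict(clf, evaluation.trace_matrix, cell_ids=evaluation.cell_ids)
truth = ev.truth_arrays(ds, evaluation.cell_ids)
_, report = ev.per_fov_summary(cc.calls(preds), truth["reactive"],
                               truth["genotype"], truth["fov_ids"],
                               truth["conditions"])
print({k: round(v, 3) for k, v in report.condition_efficiency.items()})
print({k: round(v, 3) for k, v in report.condition_fdr.items()})
print(round(report.pm, 2))
```

prints

```
{'OVA_like': 0.972, 'gp33_like': 0.464}
{'OVA_like': 0.0, 'gp33_like': 0.0}
1.86
```

i.e. on this small simulation the plain CNN recovers 97% of the
reactive-labelled strong-agonist cells with no false discoveries, but
only 46% of the weak-agonist cells it never saw in training — the
amplitude-generalization gap that the full benchmark closes with
amplitude-scaling augmentation (`preprocess.augment_training_set`,
`pipeline.run_study` reaches ≈95% weak-agonist efficiency). The weighted
performance metric pM summarizes each operating point.

The same stages are available from the shell:

```bash
catrace simulate --out data --seed 0
catrace train --data data --out run --classifier cnn --mode manual
catrace predict --model run/model --data data --out pred.csv
catrace evaluate --pred pred.csv --data data --weights 1,5 --out metrics
catrace run --config run.yaml --out full_run --seed 0   # all stages + manifest
```

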