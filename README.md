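# distnet

Protein inter-residue **distance map prediction**, end to end: ground-truth
label construction from structures, alignment-derived input feature volumes,
a fully convolutional residual network with three interchangeable output
heads, the reciprocal log-cosh regression loss, long-range evaluation
metrics, and conversion of predicted distances into bounded restraints for
3D model building.  A synthetic-data generator makes the whole pipeline
runnable and testable offline, with no structure downloads or external
feature predictors.

It is aimed at structural-bioinformatics researchers who want a small,
transparent, CPU-friendly framework for experimenting with losses,
architectures and features on the distance-prediction problem, rather than a
production predictor.

## The problem and the model

For a protein of length *L* the target is the symmetric *L* × *L* matrix of
Cβ–Cβ Euclidean distances computed from the solved structure (Cα for
glycine).  The input is an *L* × *L* × *C* feature volume built from seven
features: sequence profile, three-state secondary-structure and solvent
accessibility predictions (tiled row- and column-wise from 1D to 2D),
CCMpred- and FreeContact-style coevolution matrices, an MSA
contact-potential matrix, and per-column Shannon entropy — 55 channels in
total.

A residual network (each block: batch norm → ReLU → 3×3 conv → dropout 0.3 →
ReLU → 3×3 conv, with an identity skip) maps the volume to one of three
outputs:

* **contact** — sigmoid, binary cross-entropy against the <8 Å contact map;
* **binned** — softmax over variable-width distance bins (0.2 Å wide below
  8 Å, widths growing by 0.2 Å per bin up to 26 Å, then an open 26+ bin);
* **distance** — ReLU output trained with the reciprocal log-cosh loss

      Loss = log(cosh(K/(P + e) − K/(T + e))),   K = 100,

  implemented in label space: the true distance matrix *T* is reciprocated
  (diagonal first replaced by its neighbour mean) and a plain log-cosh is
  applied — the same minimiser, but better conditioned.  Reciprocation makes
  errors at short distances far more expensive, so the model optimises the
  structurally informative short distances first.

Training runs on random 128 × 128 crops (after zero-padding width 5);
prediction is full-width because the network is fully convolutional.
Evaluation reports MAE₈/MAE₁₂ (mean absolute error over long-range pairs
with true distance < 8/12 Å) and P_L/P_NC (precision of the top *L* / top
*NC* long-range contacts, ranked through the score P_ij = 4/D_ij for
D_ij ≥ 4, else 1).  Predicted distances convert to bounded restraints with
error range δ = 0.03·d², lower bound d − δ/2 and upper bound d + δ/2.

## Worked example

Train a small real-valued distance model on synthetic chains with a
perfectly informative coevolution channel, then evaluate held-out targets:

```python
import numpy as np
from distnet import (SyntheticSpec, make_dataset, ModelConfig, build_model,
                     train, predict, evaluate_dataset, select_restraints)

conditions = SyntheticSpec(length=80, signal_strength=1.0, noise_sd=0.1)
train_set = make_dataset(12, conditions, seed=0)
held_out = make_dataset(3, conditions, seed=100)

model = build_model(ModelConfig(input_channels=55, num_blocks=2, filters=16,
                                head="distance"), seed=0)
model, history = train(model, train_set, epochs=6, crop=64, pad=5, seed=0)
print(f"training loss: {history['loss'][0]:.3f} -> {history['loss'][-1]:.3f}")

preds = {f"t{k}": predict(model, vol) for k, (vol, _) in enumerate(held_out)}
truths = {f"t{k}": dmap for k, (_, dmap) in enumerate(held_out)}
report = evaluate_dataset({k: p.values for k, p in preds.items()}, truths,
                          mode="distance")
print(report.per_target[["id", "L", "NC", "mae8", "p_l", "p_nc"]])

r = select_restraints(preds["t0"], max_distance=12.0)[0]
print(f"tightest restraint: residues {r.i}-{r.j}, d={r.d:.2f} A, "
      f"bounds [{r.lower:.2f}, {r.upper:.2f}]")
```

Output (a minute or two on one CPU):

```
training loss: 4.361 -> 1.629
id  L  NC     mae8    p_l      p_nc
t0 80 142 2.924283  98.75 85.915493
t1 80 184 2.422179 100.00 86.413043
t2 80 124 2.788147  93.75 81.451613
tightest restraint: residues 32-49, d=5.25 A, bounds [4.84, 5.67]
```

The training loss falls as the network learns to read the planted contact
channel; MAE₈ ≈ 2.4–2.9 Å is the mean error over truly-close long-range
pairs; P_L ≥ 94% means nearly all of the top-80 ranked long-range pairs are
genuine contacts; the restraint bounds bracket the predicted 5.25 Å distance
with the quadratic error range 0.03·d² ≈ 0.83 Å.

The same pipeline is scriptable from a shell:

```sh
distnet synth --out data --n-targets 4 --length 64
distnet featurize --dir data
distnet train --dir data --head distance --epochs 5 --out model.npz
distnet predict --model model.npz --volume data/synth0000.volume.npz --out pred.npz
distnet restraints --pred pred.npz --out restraints.tsv --rosetta restraints.cst
```

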