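# rvt — recurrent convolutional vision models with anytime decisions

`rvt` is a toolkit for studying how *lateral recurrence* lets a convolutional
image classifier trade speed for accuracy. It targets computational
neuroscientists and machine-learning researchers who want to exercise, at desk
scale and in pure numpy, the full pipeline around a family of recurrent and
feedforward control architectures: building and unrolling the networks,
accounting for their parameters and floating-point costs, stopping their
computation at a confidence threshold, tracing speed–accuracy trade-off
curves, fitting network reaction times to subject reaction-time data, and
decomposing learned lateral weights into principal components.

## The model family

The baseline network **B** is a seven-block feedforward CNN (feature maps
96…2048, kernels 7…1, 2×2 max pooling between blocks, global average pooling
and a dense softmax readout). Three feedforward controls match the parameter
count of the recurrent model by enlarging kernels (**B-K**), doubling feature
maps (**B-F**), or doubling depth (**B-D**). The recurrent network **BL**
adds, to every block, a *lateral* convolution from the block's own activations
one time step earlier:

    H_{t,n} = φ( W_n^b ∗ η(H_{t,n−1}) + W_n^l ∗ H_{t−1,n} + b_n )

where η is optional max pooling and φ is batch normalisation (independent
gain/shift per time step) followed by rectification. The network is unrolled
for T time steps with a readout per step; the lateral state at t = 0 is zero,
so the first step is exactly the feedforward sweep. **B-U** is BL's unrolled
graph with unique weights per convolution (no sharing across time).

Decisions are made anytime-style: the *cumulative readout* at step t is the
mean of the per-step softmax distributions, and computation stops at the first
step whose readout entropy falls to or below a threshold θ (in nats). Varying
θ traces a speed–accuracy trade-off: the mean floating-point cost at decision
against top-1 accuracy. For reaction-time analysis, binary (super-category)
sigmoid readouts `y_t = σ(α y_{t−1} + w·p_t + b)` are trained on
PCA-projected activations at eight cost-spaced sites, and the entropy
threshold that best aligns network and subject reaction times is fitted by
double leave-one-out cross-validation (hold out one subject and one image per
fold), scored by per-subject Pearson correlation against a
leave-one-subject-out noise-ceiling lower bound.

Because no deep-learning framework is assumed, the networks (including
backpropagation through time and Adam) are implemented in numpy and run at
configurable reduced scale; a synthetic recognition task with graded per-image
difficulty and synthetic subject reaction times with a planted threshold
make every stage testable end to end.

## Worked example

```python
import numpy as np
from rvt import (make_spec, count_parameters, ReducedScale, TrainConfig,
                 train, run_model, sat_curve, generate_images,
                 SyntheticTaskConfig)

# full-scale accounting: the recurrent model and its unrolled control
print(count_parameters(make_spec("BL", "full")).total_millions)   # 28.9
from rvt import build_bu
print(count_parameters(build_bu(make_spec("BL", "full"))).total_millions)  # 212.7

# desk-scale: train a tiny BL on the synthetic task and trace its SAT curve
ds = generate_images(SyntheticTaskConfig(seed=0))
Xtr, ytr, _, _ = ds.subset("train")
Xva, yva, _, _ = ds.subset("val")
spec = make_spec("BL", ReducedScale(timesteps=4, n_classes=10))
model, log = train(spec, (2*Xtr-1, ytr, 2*Xva-1, yva),
                   TrainConfig(epochs=30, batch_size=50, seed=0,
                               augment=False, preprocessed=True))
print(np.round(log[-1]["val_accuracy_per_step"], 2))  # [0.54 0.65 0.7 0.72]
curve = sat_curve(run_model(spec, model, 2*Xva-1), yva)
```

The per-step numbers are the validation accuracy of the cumulative readout at
time steps 1…4: accuracy rises as the recurrent computation proceeds, which
is the signature behaviour the decision mechanism exploits — an entropy
threshold spends extra steps only on the images that need them, and the SAT
curve's accuracy rises with mean cost until it saturates.

A command-line interface mirrors the library:

```bash
rvt count-params --family BL --scale full --timesteps 8   # JSON breakdown
rvt synth --out data/ && rvt train --family BL --out run/
rvt sat --checkpoint run/checkpoint.h5 --out sat/
rvt lateral --checkpoint run/checkpoint.h5 --layer 1 --k 5 --out comps/
```

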