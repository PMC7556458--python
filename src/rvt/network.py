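"""Numpy implementation of the architecture family.

A network is executed by unrolling in "engineering" time: at step t, layer n
receives bottom-up input from layer n-1 at step t (max-pooled where the block
is followed by pooling) and, if the layer is recurrent, lateral input from its
own activations at step t-1.  The two convolution outputs are summed, batch
normalised (with independent gain/shift per time step) and rectified.  The
lateral state at t=0 is the all-zero stack, so the first step is exactly the
feedforward sweep.  A readout (global average pooling + dense softmax) is
taken from the final block at every step.

The implementation keeps parameters in a flat dict of numpy arrays so a
hand-written backward-through-time pass and Adam can operate on them; there
is no automatic differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .counting import count_flops
from .decision import DecisionPolicy, ReadoutSequence, decide
from .specs import ArchitectureSpec, BlockSpec, ReducedScale, make_spec


# ------------------------------------------------------------------ layers

@dataclass(frozen=True)
class LayerDef:
    """One convolutional layer of the flattened block structure."""

    in_maps: int
    out_maps: int
    kernel: int
    lateral: bool
    pool_after: bool
    block: int
    conv_index: int


def layer_defs(spec: ArchitectureSpec) -> list[LayerDef]:
    layers = []
    f_in = spec.input_size[2]
    for bi, b in enumerate(spec.blocks):
        for ci in range(b.convs_per_block):
            last = ci == b.convs_per_block - 1
            layers.append(
                LayerDef(
                    in_maps=f_in if ci == 0 else b.feature_maps,
                    out_maps=b.feature_maps,
                    kernel=b.kernel_size,
                    lateral=b.has_lateral and ci == 0,
                    pool_after=b.followed_by_pool and last,
                    block=bi,
                    conv_index=ci,
                )
            )
        f_in = b.feature_maps
    return layers


class ModelParams:
    """Trainable arrays plus batch-norm running statistics for one spec."""

    def __init__(self, params: dict[str, np.ndarray], state: dict[str, np.ndarray]):
        self.params = params
        self.state = state

    def copy(self) -> "ModelParams":
        return ModelParams(
            {k: v.copy() for k, v in self.params.items()},
            {k: v.copy() for k, v in self.state.items()},
        )


def _wb_key(spec: ArchitectureSpec, li: int, t: int) -> str:
    return f"layer{li}/Wb" if spec.weight_sharing_across_time else f"layer{li}/Wb/t{t}"


def _wl_key(spec: ArchitectureSpec, li: int, t: int) -> str:
    return f"layer{li}/Wl" if spec.weight_sharing_across_time else f"layer{li}/Wl/t{t}"


def _ro_key(spec: ArchitectureSpec, name: str, t: int) -> str:
    return f"readout/{name}" if spec.weight_sharing_across_time else f"readout/{name}/t{t}"


def init_params(spec: ArchitectureSpec, rng: np.random.Generator) -> ModelParams:
    """Variance-scaling (fan-in) initialisation for convolutions, zeros for
    the readout bias, unit gain / zero shift for batch-norm."""
    params: dict[str, np.ndarray] = {}
    state: dict[str, np.ndarray] = {}
    layers = layer_defs(spec)
    T = spec.n_timesteps
    bu_times = [0] if spec.weight_sharing_across_time else list(range(T))
    for li, L in enumerate(layers):
        for t in bu_times:
            fan_in = L.kernel * L.kernel * L.in_maps
            params[_wb_key(spec, li, t)] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (L.kernel, L.kernel, L.in_maps, L.out_maps)
            )
        if L.lateral:
            lat_times = [0] if spec.weight_sharing_across_time else list(range(1, T))
            for t in lat_times:
                fan_in = L.kernel * L.kernel * L.out_maps
                params[_wl_key(spec, li, t)] = rng.normal(
                    0.0, np.sqrt(2.0 / fan_in), (L.kernel, L.kernel, L.out_maps, L.out_maps)
                )
        for t in range(T):
            params[f"layer{li}/bn{t}/gamma"] = np.ones(L.out_maps)
            params[f"layer{li}/bn{t}/beta"] = np.zeros(L.out_maps)
            state[f"layer{li}/bn{t}/mean"] = np.zeros(L.out_maps)
            state[f"layer{li}/bn{t}/var"] = np.ones(L.out_maps)
    f_last = spec.blocks[-1].feature_maps
    for t in bu_times:
        limit = np.sqrt(6.0 / (f_last + spec.n_classes))
        params[_ro_key(spec, "W", t)] = rng.uniform(-limit, limit, (f_last, spec.n_classes))
        params[_ro_key(spec, "b", t)] = np.zeros(spec.n_classes)
    return ModelParams(params, state)


def _batchnorm(model: ModelParams, key_base: str, z: np.ndarray, *, training: bool):
    bn = nn.BatchNormState.__new__(nn.BatchNormState)
    bn.gamma = model.params[f"{key_base}/gamma"]
    bn.beta = model.params[f"{key_base}/beta"]
    bn.running_mean = model.state[f"{key_base}/mean"]
    bn.running_var = model.state[f"{key_base}/var"]
    out, cache = nn.batchnorm_forward(z, bn, training=training)
    if training:  # write back updated running statistics
        model.state[f"{key_base}/mean"] = bn.running_mean
        model.state[f"{key_base}/var"] = bn.running_var
    return out, cache


def forward(
    spec: ArchitectureSpec,
    model: ModelParams,
    x: np.ndarray,
    *,
    training: bool = False,
    return_caches: bool = False,
):
    """Run a batch through the unrolled network.

    Returns per-step class probabilities of shape (N, T, n_classes), and the
    caches needed for the backward pass when ``return_caches`` is set.
    """
    layers = layer_defs(spec)
    T = spec.n_timesteps
    n = x.shape[0]
    probs = np.empty((n, T, spec.n_classes))
    h_prev: list[np.ndarray | None] = [None] * len(layers)
    all_caches, ro_caches = [], []
    for t in range(T):
        cur = x
        new_h: list[np.ndarray] = []
        t_caches = []
        for li, L in enumerate(layers):
            cache: dict = {}
            z, c_bu = nn.conv2d_forward(cur, model.params[_wb_key(spec, li, t)])
            cache["bu"] = c_bu
            if L.lateral and t > 0:
                zl, c_lat = nn.conv2d_forward(h_prev[li], model.params[_wl_key(spec, li, t)])
                z = z + zl
                cache["lat"] = c_lat
            z, c_bn = _batchnorm(model, f"layer{li}/bn{t}", z, training=training)
            cache["bn"] = c_bn
            h, mask = nn.relu_forward(z)
            cache["relu"] = mask
            new_h.append(h)
            if L.pool_after:
                cur, c_pool = nn.maxpool_forward(h)
                cache["pool"] = c_pool
            else:
                cur = h
            t_caches.append(cache)
        h_prev = new_h
        g = nn.global_avg_pool(cur)
        logits = g @ model.params[_ro_key(spec, "W", t)] + model.params[_ro_key(spec, "b", t)]
        probs[:, t] = nn.softmax(logits)
        ro_caches.append((g, cur.shape))
        all_caches.append(t_caches)
    if return_caches:
        return probs, (all_caches, ro_caches)
    return probs


def loss_and_grads(
    spec: ArchitectureSpec,
    model: ModelParams,
    x: np.ndarray,
    y: np.ndarray,
    *,
    l2: float = 0.0,
    training: bool = True,
):
    """Multi-readout cross-entropy loss and gradients via BPTT.

    The loss is the mean over readouts of the batch-mean cross-entropy, plus
    l2 times the squared norm of all convolution and readout weights.
    """
    layers = layer_defs(spec)
    T = spec.n_timesteps
    n = x.shape[0]
    probs, (caches, ro_caches) = forward(spec, model, x, training=training, return_caches=True)

    eps = 1e-12
    picked = probs[np.arange(n)[:, None], np.arange(T)[None, :], y[:, None]]
    loss = float(-np.log(picked + eps).mean())

    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    onehot = np.zeros((n, spec.n_classes))
    onehot[np.arange(n), y] = 1.0

    dh_lat_next: list[np.ndarray | None] = [None] * len(layers)
    for t in reversed(range(T)):
        dlog = (probs[:, t] - onehot) / (n * T)
        g, cur_shape = ro_caches[t]
        grads[_ro_key(spec, "W", t)] += g.T @ dlog
        grads[_ro_key(spec, "b", t)] += dlog.sum(axis=0)
        dg = dlog @ model.params[_ro_key(spec, "W", t)].T
        _, hh, ww, cc = cur_shape
        dcur = np.broadcast_to(
            dg[:, None, None, :] / (hh * ww), (n, hh, ww, cc)
        ).astype(float)
        for li in reversed(range(len(layers))):
            L = layers[li]
            cache = caches[t][li]
            if L.pool_after:
                dh = nn.maxpool_backward(dcur, cache["pool"])
            else:
                dh = dcur
            if dh_lat_next[li] is not None:
                dh = dh + dh_lat_next[li]
            dz = dh * cache["relu"]
            dz, dgamma, dbeta = nn.batchnorm_backward(dz, cache["bn"])
            grads[f"layer{li}/bn{t}/gamma"] += dgamma
            grads[f"layer{li}/bn{t}/beta"] += dbeta
            if "lat" in cache:
                dlat, dwl = nn.conv2d_backward(dz, model.params[_wl_key(spec, li, t)], cache["lat"])
                grads[_wl_key(spec, li, t)] += dwl
                dh_lat_next[li] = dlat
            else:
                dh_lat_next[li] = None
            dcur, dwb = nn.conv2d_backward(dz, model.params[_wb_key(spec, li, t)], cache["bu"])
            grads[_wb_key(spec, li, t)] += dwb
        # dcur is now the gradient wrt the input image; not needed

    if l2 > 0:
        for k, v in model.params.items():
            if "/Wb" in k or "/Wl" in k or k.startswith("readout/W"):
                loss += l2 * float(np.sum(v * v))
                grads[k] += 2.0 * l2 * v
    return loss, grads, probs


def run_model(
    spec: ArchitectureSpec,
    model: ModelParams,
    images: np.ndarray,
    *,
    batch_size: int = 128,
) -> ReadoutSequence:
    """Evaluate a batch of images into a ReadoutSequence with FLOP costs."""
    h, w, c = spec.input_size
    if images.shape[1:] != (h, w, c):
        raise ValueError(f"images must be (N, {h}, {w}, {c}), got {images.shape}")
    chunks = [
        forward(spec, model, images[i:i + batch_size], training=False)
        for i in range(0, images.shape[0], batch_size)
    ]
    probs = np.concatenate(chunks, axis=0)
    costs = np.asarray(count_flops(spec).cumulative_flops, dtype=float)
    return ReadoutSequence(probs=probs, site_costs=costs)


# ---------------------------------------------------------------- estimator

class RecurrentConvClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style image classifier over the architecture family.

    Parameters mirror the training recipe of the full-scale study (Adam with
    learning rate 0.005 and epsilon 0.1, L2 1e-6, batch 100, multi-readout
    cross-entropy averaged over time steps) but default to desk-scale sizes.

    ``fit`` expects images as an (N, H, W, C) float array in [-1, 1] (see
    :func:`rvt.training.preprocess`) and integer class labels.
    """

    def __init__(
        self,
        family: str = "BL",
        blocks: tuple = ((8, 3), (16, 3)),
        n_timesteps: int = 4,
        input_size: tuple = (32, 32, 3),
        epochs: int = 10,
        batch_size: int = 50,
        learning_rate: float = 0.005,
        adam_epsilon: float = 0.1,
        l2: float = 1e-6,
        random_state: int = 0,
    ):
        self.family = family
        self.blocks = blocks
        self.n_timesteps = n_timesteps
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.adam_epsilon = adam_epsilon
        self.l2 = l2
        self.random_state = random_state

    def _make_spec(self, n_classes: int) -> ArchitectureSpec:
        feats = tuple(f for f, _ in self.blocks)
        kerns = tuple(k for _, k in self.blocks)
        scale = ReducedScale(
            base_features=feats,
            base_kernels=kerns,
            input_size=tuple(self.input_size),
            n_classes=n_classes,
            timesteps=self.n_timesteps,
        )
        return make_spec(self.family, scale)

    def fit(self, X, y):
        from .training import TrainConfig, train  # local import avoids cycle

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.spec_ = self._make_spec(len(self.classes_))
        config = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            adam_epsilon=self.adam_epsilon,
            l2_coefficient=self.l2,
            seed=self.random_state,
            augment=False,
            preprocessed=True,
        )
        self.model_, self.history_ = train(self.spec_, (X, y_enc, None, None), config)
        return self

    def readout_sequence(self, X) -> ReadoutSequence:
        check_is_fitted(self, "model_")
        return run_model(self.spec_, self.model_, np.asarray(X, dtype=float))

    def predict_proba(self, X):
        """Cumulative readout at the final time step."""
        seq = self.readout_sequence(X)
        return seq.probs.mean(axis=1)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def decide(self, X, policy: DecisionPolicy):
        return decide(self.readout_sequence(X), policy)
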