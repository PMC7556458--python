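"""Trainable-parameter and floating-point-operation accounting.

Counting conventions
--------------------
* Parameters: convolution weights, per-time-step batch-norm gain and shift
  (2 per feature map per time step), and the dense readout's weights and bias
  are trainable.  Convolution layers carry no separate additive bias: the
  batch-norm shift plays that role (``conv_bias=True`` restores an explicit
  per-layer bias for sensitivity analyses).  Batch-norm running statistics are
  not trainable and are never counted.
* FLOPs: one multiply-add counts as 2 floating-point operations.  By default
  only convolution and dense multiply-adds are counted; pooling comparisons,
  batch-norm and rectifier element-wise operations can be included with flags.
  All outputs carry the convention tag so comparative analyses (ratios,
  orderings) remain convention-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .specs import ArchitectureSpec, spatial_sizes

FLOP_CONVENTION = "multiply-add = 2 flops; conv and dense only unless flagged"


@dataclass(frozen=True)
class ParameterCount:
    bottom_up: int
    lateral: int
    biases: int
    batchnorm: int
    readout: int

    @property
    def total(self) -> int:
        return self.bottom_up + self.lateral + self.biases + self.batchnorm + self.readout

    @property
    def total_millions(self) -> float:
        """Total rounded to 0.1 million, the precision used in print."""
        return round(self.total / 1e6, 1)

    def as_dict(self) -> dict:
        return {
            "bottom_up": self.bottom_up,
            "lateral": self.lateral,
            "biases": self.biases,
            "batchnorm": self.batchnorm,
            "readout": self.readout,
            "total": self.total,
            "total_millions": self.total_millions,
        }


@dataclass(frozen=True)
class CostProfile:
    flops_per_timestep: tuple[int, ...]
    convention: str = FLOP_CONVENTION

    @property
    def cumulative_flops(self) -> tuple[int, ...]:
        out, acc = [], 0
        for f in self.flops_per_timestep:
            acc += f
            out.append(acc)
        return tuple(out)

    @property
    def total(self) -> int:
        return sum(self.flops_per_timestep)


def count_parameters(spec: ArchitectureSpec, *, conv_bias: bool = False) -> ParameterCount:
    """Count trainable parameters with a per-component breakdown.

    For weight-shared recurrent specs (BL) convolution weights are counted
    once and batch-norm gain/shift once per time step.  For B-U every
    convolution instance in the unrolled graph has unique weights: T bottom-up
    instances per layer, T-1 lateral instances (the lateral input at the first
    step is the zero state and has no incoming convolution), and one readout
    per former time step.
    """
    T = spec.n_timesteps
    shared = spec.weight_sharing_across_time

    bottom_up = lateral = biases = batchnorm = 0
    f_in = spec.input_size[2]
    for b in spec.blocks:
        f, k = b.feature_maps, b.kernel_size
        w_bu = k * k * f_in * f
        w_second = k * k * f * f  # second conv (B-D) or lateral conv (BL/B-U)
        n_conv_layers = b.convs_per_block

        if b.has_lateral:
            if shared:
                bottom_up += w_bu
                lateral += w_second
            else:
                bottom_up += T * w_bu
                lateral += (T - 1) * w_second
        else:
            bottom_up += w_bu + (w_second if n_conv_layers == 2 else 0)

        # one batch-norm (and optional bias) per conv layer per time step;
        # lateral and bottom-up inputs are summed before a single batch-norm
        bn_sites = n_conv_layers * T
        batchnorm += bn_sites * 2 * f
        if conv_bias:
            biases += (n_conv_layers if shared or not b.has_lateral else T) * f
        f_in = f

    readout_each = (spec.blocks[-1].feature_maps * spec.n_classes) + spec.n_classes
    readout = readout_each if shared else T * readout_each

    return ParameterCount(
        bottom_up=bottom_up,
        lateral=lateral,
        biases=biases,
        batchnorm=batchnorm,
        readout=readout,
    )


def count_flops(
    spec: ArchitectureSpec,
    *,
    include_pooling: bool = False,
    include_batchnorm: bool = False,
    include_elementwise: bool = False,
    skip_zero_lateral: bool = False,
) -> CostProfile:
    """Per-time-step and cumulative floating-point operations for one image.

    ``skip_zero_lateral`` omits the lateral products at the first time step
    (the lateral state is all-zero there); by default they are counted, so the
    per-time-step cost is constant across t.
    """
    sizes = spatial_sizes(spec)
    per_t = []
    for t in range(spec.n_timesteps):
        flops = 0
        f_in = spec.input_size[2]
        for b, (h, w) in zip(spec.blocks, sizes):
            f, k = b.feature_maps, b.kernel_size
            flops += 2 * k * k * f_in * f * h * w
            if b.convs_per_block == 2:
                flops += 2 * k * k * f * f * h * w
            if b.has_lateral and not (skip_zero_lateral and t == 0):
                flops += 2 * k * k * f * f * h * w
            n_conv = b.convs_per_block
            if include_batchnorm:
                flops += n_conv * 2 * h * w * f
            if include_elementwise:
                flops += n_conv * h * w * f  # rectifier
            if b.followed_by_pool and include_pooling:
                flops += 3 * (h // 2) * (w // 2) * f  # 3 comparisons per window
            f_in = f
        # readout: global average pool (optional) + dense
        f_last = spec.blocks[-1].feature_maps
        if include_elementwise:
            h, w = sizes[-1]
            flops += h * w * f_last
        flops += 2 * f_last * spec.n_classes
        per_t.append(flops)
    return CostProfile(flops_per_timestep=tuple(per_t))
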