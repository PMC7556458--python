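"""Declarative specifications of the recurrent/feedforward architecture family.

The family consists of a bottom-up baseline ``B`` (a plain feedforward
convolutional network), three parameter-matched feedforward controls built by
enlarging kernels (``B-K``), doubling feature maps (``B-F``) or doubling depth
(``B-D``), a laterally recurrent network ``BL`` (every block gains a
within-layer recurrent convolution and the whole network is unrolled for T
time steps with a readout per step), and ``B-U``, the feedforward network
obtained by unrolling BL without weight sharing across time.

Specs are plain data: nothing here allocates weights or runs images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

FAMILIES = ("B", "B-K", "B-F", "B-D", "BL", "B-U")

#: Table of (feature_maps, kernel_size) per block for the full-scale
#: bottom-up skeleton, and the per-block kernel enlargement used by B-K.
_FULL_F = (96, 128, 192, 256, 512, 1024, 2048)
_FULL_K = (7, 5, 3, 3, 3, 3, 1)
_FULL_K_ENLARGED = (11, 7, 5, 5, 5, 5, 3)
#: B-K's kernel increment pattern relative to B: +4 in block 1, +2 elsewhere.
_BK_INCREMENTS = tuple(ke - k for ke, k in zip(_FULL_K_ENLARGED, _FULL_K))

FULL_INPUT_SIZE = (128, 128, 3)
FULL_TIMESTEPS = 8


@dataclass(frozen=True)
class BlockSpec:
    """One convolutional block.

    ``convs_per_block`` is 2 only for the deeper control family (B-D), where
    the block's convolution is applied twice in sequence.  ``has_lateral``
    marks the within-layer recurrent convolution of BL/B-U, which always has
    the same feature-map count and kernel size as the bottom-up convolution.
    """

    feature_maps: int
    kernel_size: int
    convs_per_block: int = 1
    has_lateral: bool = False
    followed_by_pool: bool = True

    def __post_init__(self) -> None:
        if self.feature_maps < 1:
            raise ValueError(f"feature_maps must be >= 1, got {self.feature_maps}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(
                f"kernel_size must be a positive odd integer, got {self.kernel_size}"
            )
        if self.convs_per_block not in (1, 2):
            raise ValueError("convs_per_block must be 1 or 2")


@dataclass(frozen=True)
class ArchitectureSpec:
    """A complete network of the family.

    The readout is always global average pooling over the final block's
    activations followed by a dense softmax layer with bias.  Feedforward
    families have ``n_timesteps == 1``; BL unrolls for ``n_timesteps`` steps
    with shared weights, B-U uses the identical unrolled graph but unique
    weights per time step (``weight_sharing_across_time=False``).
    """

    family_name: str
    blocks: tuple[BlockSpec, ...]
    n_classes: int
    input_size: tuple[int, int, int]
    n_timesteps: int = 1
    weight_sharing_across_time: bool = True

    def __post_init__(self) -> None:
        if self.family_name not in FAMILIES:
            raise ValueError(f"unknown family {self.family_name!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_timesteps < 1:
            raise ValueError("n_timesteps must be >= 1")
        if not self.blocks:
            raise ValueError("spec needs at least one block")
        recurrent = any(b.has_lateral for b in self.blocks)
        if not recurrent and self.n_timesteps != 1 and self.weight_sharing_across_time:
            raise ValueError("feedforward families must have n_timesteps == 1")

    @property
    def is_recurrent(self) -> bool:
        return any(b.has_lateral for b in self.blocks)

    @property
    def n_readouts(self) -> int:
        return self.n_timesteps

    def to_yaml(self) -> str:
        d = asdict(self)
        d["blocks"] = [asdict(b) for b in self.blocks]
        d["input_size"] = list(self.input_size)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        d = yaml.safe_load(text)
        blocks = tuple(BlockSpec(**b) for b in d.pop("blocks"))
        d["input_size"] = tuple(d["input_size"])
        return cls(blocks=blocks, **d)


@dataclass(frozen=True)
class ReducedScale:
    """Desk-scale descriptor preserving the family's structural deltas.

    ``base_features``/``base_kernels`` describe the bottom-up skeleton at
    reduced scale; B-K adds the same per-block kernel increments pattern as at
    full scale (+4 in block 1, +2 in later blocks), B-F doubles the feature
    maps, B-D duplicates each block's convolution, BL adds lateral recurrence
    with ``timesteps`` steps.
    """

    base_features: tuple[int, ...] = (8, 16)
    base_kernels: tuple[int, ...] = (3, 3)
    input_size: tuple[int, int, int] = (32, 32, 3)
    n_classes: int = 10
    timesteps: int = 4
    pool_last: bool = False

    def __post_init__(self) -> None:
        if len(self.base_features) != len(self.base_kernels):
            raise ValueError("base_features and base_kernels lengths differ")


def _bk_kernels(kernels: Sequence[int]) -> tuple[int, ...]:
    incs = [_BK_INCREMENTS[0]] + [2] * (len(kernels) - 1)
    return tuple(k + i for k, i in zip(kernels, incs))


def make_spec(
    family_name: str,
    scale: str | ReducedScale = "full",
    *,
    n_classes: int | None = None,
    n_timesteps: int | None = None,
) -> ArchitectureSpec:
    """Build an ArchitectureSpec for one family at full or reduced scale.

    Parameters
    ----------
    family_name : one of B, B-K, B-F, B-D, BL, B-U
    scale : "full" for the printed full-scale family (1000 classes,
        128x128x3 input, 8 time steps for the recurrent members), or a
        :class:`ReducedScale` descriptor.
    n_classes, n_timesteps : overrides (e.g. 565 classes for the
        ecologically sampled task's label set).
    """
    if family_name not in FAMILIES:
        raise ValueError(f"unknown family {family_name!r}; choose from {FAMILIES}")

    if scale == "full":
        feats, kerns = _FULL_F, _FULL_K
        input_size = FULL_INPUT_SIZE
        classes = 1000 if n_classes is None else n_classes
        T = FULL_TIMESTEPS if n_timesteps is None else n_timesteps
        pool_flags = [True] * 6 + [False]
    elif isinstance(scale, ReducedScale):
        feats, kerns = scale.base_features, scale.base_kernels
        input_size = scale.input_size
        classes = scale.n_classes if n_classes is None else n_classes
        T = scale.timesteps if n_timesteps is None else n_timesteps
        pool_flags = [True] * (len(feats) - 1) + [scale.pool_last]
    else:
        raise ValueError(f"scale must be 'full' or a ReducedScale, got {scale!r}")

    if family_name == "B-K":
        kerns = _bk_kernels(kerns)
    elif family_name == "B-F":
        feats = tuple(2 * f for f in feats)

    lateral = family_name in ("BL", "B-U")
    convs = 2 if family_name == "B-D" else 1
    blocks = tuple(
        BlockSpec(
            feature_maps=f,
            kernel_size=k,
            convs_per_block=convs,
            has_lateral=lateral,
            followed_by_pool=p,
        )
        for f, k, p in zip(feats, kerns, pool_flags)
    )
    timesteps = T if lateral else 1
    return ArchitectureSpec(
        family_name=family_name,
        blocks=blocks,
        n_classes=classes,
        input_size=input_size,
        n_timesteps=timesteps,
        weight_sharing_across_time=(family_name != "B-U"),
    )


def build_bu(bl_spec: ArchitectureSpec) -> ArchitectureSpec:
    """Unroll a BL spec into its feedforward control B-U.

    Same computational graph, but unique parameters for every convolution
    (no weight sharing across time) and one readout per former time step.
    """
    if not bl_spec.is_recurrent:
        raise ValueError("build_bu requires a recurrent (BL) spec")
    return ArchitectureSpec(
        family_name="B-U",
        blocks=bl_spec.blocks,
        n_classes=bl_spec.n_classes,
        input_size=bl_spec.input_size,
        n_timesteps=bl_spec.n_timesteps,
        weight_sharing_across_time=False,
    )


def spatial_sizes(spec: ArchitectureSpec) -> list[tuple[int, int]]:
    """Spatial size of each block's output; pooling halves (ceil) each axis."""
    h, w, _ = spec.input_size
    sizes = []
    for b in spec.blocks:
        sizes.append((h, w))
        if b.followed_by_pool:
            h = -(-h // 2)
            w = -(-w // 2)
    return sizes
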