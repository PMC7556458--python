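"""Checkpoint and manifest serialisation.

Checkpoints are HDF5 files holding every trainable array under ``params/``
and batch-norm running statistics under ``state/``, with the architecture
spec embedded as YAML and a manifest naming every parameter.  Images passed
to the networks are channels-last float arrays scaled to [-1, 1] (see the
preprocessing step); this convention is recorded in the manifest.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import h5py
import numpy as np

from .network import ModelParams
from .specs import ArchitectureSpec

FORMAT_VERSION = 1
IMAGE_CONVENTION = "channels-last (N,H,W,C), float, scaled to [-1, 1]"


def save_checkpoint(path, spec: ArchitectureSpec, model: ModelParams) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["spec_yaml"] = spec.to_yaml()
        f.attrs["image_convention"] = IMAGE_CONVENTION
        gp = f.create_group("params")
        for k, v in model.params.items():
            gp.create_dataset(k, data=v)
        gs = f.create_group("state")
        for k, v in model.state.items():
            gs.create_dataset(k, data=v)
        f.attrs["manifest"] = json.dumps(sorted(model.params) + sorted(model.state))


def load_checkpoint(path) -> tuple[ArchitectureSpec, ModelParams]:
    with h5py.File(path, "r") as f:
        spec = ArchitectureSpec.from_yaml(f.attrs["spec_yaml"])
        params = {k: np.asarray(v) for k, v in _walk(f["params"])}
        state = {k: np.asarray(v) for k, v in _walk(f["state"])}
    return spec, ModelParams(params, state)


def _walk(group, prefix=""):
    for key, item in group.items():
        name = f"{prefix}{key}"
        if isinstance(item, h5py.Group):
            yield from _walk(item, prefix=f"{name}/")
        else:
            yield name, item[()]


def write_manifest(out_dir, config: dict, seed: int | None = None) -> Path:
    """Write a run manifest (config echo + library versions + seed)."""
    import click
    import pandas
    import scipy
    import sklearn
    import yaml as _yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seed": seed,
        "format_version": FORMAT_VERSION,
        "image_convention": IMAGE_CONVENTION,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__,
            "pyyaml": _yaml.__version__,
            "click": click.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
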