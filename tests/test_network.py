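"""Forward/backward correctness of the unrolled networks."""

import numpy as np
import pytest

from rvt import io, network
from rvt.specs import ArchitectureSpec, ReducedScale, make_spec

rng = np.random.default_rng(7)


def _tiny_batch(spec, n=4):
    h, w, c = spec.input_size
    return rng.normal(0, 1, (n, h, w, c))


def test_forward_outputs_are_distributions(tiny_bl_spec, tiny_bl_model):
    x = _tiny_batch(tiny_bl_spec)
    probs = network.forward(tiny_bl_spec, tiny_bl_model, x)
    assert probs.shape == (4, tiny_bl_spec.n_timesteps, tiny_bl_spec.n_classes)
    np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_bl_first_step_equals_pure_feedforward_sweep(tiny_bl_spec, tiny_bl_model):
    """At t=1 the lateral state is zero, so step 1 is the bottom-up sweep."""
    x = _tiny_batch(tiny_bl_spec)
    probs = network.forward(tiny_bl_spec, tiny_bl_model, x)
    ff_spec = ArchitectureSpec(
        family_name="B", blocks=tuple(
            type(b)(b.feature_maps, b.kernel_size, 1, False, b.followed_by_pool)
            for b in tiny_bl_spec.blocks),
        n_classes=tiny_bl_spec.n_classes, input_size=tiny_bl_spec.input_size,
    )
    ff_model = network.init_params(ff_spec, np.random.default_rng(99))
    for li in range(len(tiny_bl_spec.blocks)):
        ff_model.params[f"layer{li}/Wb"] = tiny_bl_model.params[f"layer{li}/Wb"].copy()
        for part in ("gamma", "beta"):
            ff_model.params[f"layer{li}/bn0/{part}"] = tiny_bl_model.params[f"layer{li}/bn0/{part}"].copy()
        for part in ("mean", "var"):
            ff_model.state[f"layer{li}/bn0/{part}"] = tiny_bl_model.state[f"layer{li}/bn0/{part}"].copy()
    ff_model.params["readout/W"] = tiny_bl_model.params["readout/W"].copy()
    ff_model.params["readout/b"] = tiny_bl_model.params["readout/b"].copy()
    ff_probs = network.forward(ff_spec, ff_model, x)
    np.testing.assert_allclose(probs[:, 0], ff_probs[:, 0], atol=1e-12)


def test_zero_lateral_shared_norm_is_time_constant(tiny_bl_spec, tiny_bl_model):
    model = tiny_bl_model.copy()
    for k in model.params:
        if "/Wl" in k:
            model.params[k][:] = 0.0
    for li in range(len(tiny_bl_spec.blocks)):
        for t in range(1, tiny_bl_spec.n_timesteps):
            for part in ("gamma", "beta"):
                model.params[f"layer{li}/bn{t}/{part}"] = model.params[f"layer{li}/bn0/{part}"].copy()
            for part in ("mean", "var"):
                model.state[f"layer{li}/bn{t}/{part}"] = model.state[f"layer{li}/bn0/{part}"].copy()
    probs = network.forward(tiny_bl_spec, model, _tiny_batch(tiny_bl_spec))
    assert np.abs(probs - probs[:, :1]).max() < 1e-6


@pytest.mark.parametrize("family,timesteps", [("BL", 3), ("B-D", 1), ("B-U", 2)])
def test_gradients_match_finite_differences(family, timesteps):
    rs = ReducedScale(base_features=(2, 3), base_kernels=(3, 3), input_size=(6, 6, 2),
                      n_classes=3, timesteps=timesteps)
    spec = make_spec(family, rs)
    model = network.init_params(spec, np.random.default_rng(1))
    x = _tiny_batch(spec, n=3)
    y = rng.integers(0, 3, 3)
    _, grads, _ = network.loss_and_grads(spec, model, x, y, l2=1e-4)
    eps = 1e-6
    check_rng = np.random.default_rng(5)
    keys = [k for k in model.params if grads[k].size > 0]
    for key in check_rng.choice(len(keys), size=min(8, len(keys)), replace=False):
        key = keys[key]
        arr = model.params[key]
        idx = tuple(check_rng.integers(0, s) for s in arr.shape)
        orig = arr[idx]
        arr[idx] = orig + eps
        lp, _, _ = network.loss_and_grads(spec, model, x, y, l2=1e-4)
        arr[idx] = orig - eps
        lm, _, _ = network.loss_and_grads(spec, model, x, y, l2=1e-4)
        arr[idx] = orig
        num = (lp - lm) / (2 * eps)
        assert abs(num - grads[key][idx]) < 1e-5 * max(1.0, abs(num)), key


def test_bu_has_unique_parameters_per_timestep():
    rs = ReducedScale(base_features=(2,), base_kernels=(3,), input_size=(4, 4, 1),
                      n_classes=2, timesteps=3)
    spec = make_spec("B-U", rs)
    model = network.init_params(spec, np.random.default_rng(0))
    assert "layer0/Wb/t0" in model.params and "layer0/Wb/t2" in model.params
    assert "layer0/Wl/t0" not in model.params  # zero state needs no weights
    assert "layer0/Wl/t1" in model.params
    assert "readout/W/t2" in model.params


def test_run_model_attaches_increasing_costs(tiny_bl_spec, tiny_bl_model):
    seq = network.run_model(tiny_bl_spec, tiny_bl_model, _tiny_batch(tiny_bl_spec))
    assert np.all(np.diff(seq.site_costs) > 0)
    with pytest.raises(ValueError, match="images must be"):
        network.run_model(tiny_bl_spec, tiny_bl_model, rng.normal(0, 1, (2, 3, 3, 2)))


def test_checkpoint_round_trip(tmp_path, tiny_bl_spec, tiny_bl_model):
    path = tmp_path / "ckpt.h5"
    io.save_checkpoint(path, tiny_bl_spec, tiny_bl_model)
    spec2, model2 = io.load_checkpoint(path)
    assert spec2 == tiny_bl_spec
    x = _tiny_batch(tiny_bl_spec)
    np.testing.assert_array_equal(
        network.forward(tiny_bl_spec, tiny_bl_model, x),
        network.forward(spec2, model2, x),
    )


def test_estimator_fits_and_predicts():
    from rvt.network import RecurrentConvClassifier
    from rvt.synth import SyntheticTaskConfig, generate_images

    ds = generate_images(SyntheticTaskConfig(
        n_classes=3, image_size=16, n_train_per_class=15, n_val_per_class=5,
        sigma_max=0.2, supercategory_map=(0, 0, 1), seed=1))
    Xtr, ytr, _, _ = ds.subset("train")
    Xva, yva, _, _ = ds.subset("val")
    clf = RecurrentConvClassifier(
        blocks=((4, 3), (6, 3)), n_timesteps=2, input_size=(16, 16, 3),
        epochs=6, batch_size=15, random_state=0)
    clf.fit(2 * Xtr - 1, ytr)
    assert clf.predict(2 * Xva - 1).shape == yva.shape
    assert clf.predict_proba(2 * Xva - 1).shape == (len(yva), 3)
    acc = (clf.predict(2 * Xva - 1) == yva).mean()
    assert acc > 1.0 / 3.0  # above chance on a low-noise task
    # sklearn protocol: params round-trip through get_params/set_params
    assert RecurrentConvClassifier(**clf.get_params()).get_params() == clf.get_params()
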