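"""Reaction-time pipeline: sites, projection, readout, double-LOO fitting,
and the inferential statistics around it."""

import itertools

import numpy as np
import pytest

from rvt.rt import (
    LN2,
    RecurrentSigmoidReadout,
    RTMatrix,
    SiteProjection,
    bh_fdr,
    binary_entropy,
    double_loo_fit,
    evaluate_correlations,
    fit_projection,
    human_consistency,
    network_rt,
    paired_permutation_test,
    place_readout_sites,
)
from rvt.synth import (
    SyntheticSubjectConfig,
    generate_entropy_trajectories,
    generate_subject_rts,
)

rng = np.random.default_rng(23)


# ----------------------------------------------------------- placement

def test_site_placement_even_candidates():
    sites = place_readout_sites([(f"l{i}", float(i)) for i in range(1, 17)], 8)
    assert [s.cumulative_cost for s in sites] == [2, 4, 6, 8, 10, 12, 14, 16]
    assert [s.site_index for s in sites] == list(range(1, 9))


def test_site_placement_matches_exhaustive_search():
    costs = sorted(rng.uniform(1, 100, 14))
    cands = [(i, c) for i, c in enumerate(costs)]
    sites = place_readout_sites(cands, 8)
    ideal = costs[-1] / 8

    def objective(subset):
        cs = [0.0] + [costs[i] for i in subset]
        return max(abs(b - a - ideal) for a, b in zip(cs, cs[1:]))

    best = min(
        (objective(sub + (13,)) for sub in itertools.combinations(range(13), 7)),
    )
    got = objective(tuple(cands.index((s.graph_position, s.cumulative_cost)) for s in sites))
    assert got == pytest.approx(best)
    assert np.all(np.diff([s.cumulative_cost for s in sites]) > 0)


def test_site_placement_keeps_existing_multireadouts():
    cands = [(t, float(t)) for t in range(1, 9)]
    sites = place_readout_sites(cands, 8)
    assert [s.graph_position for s in sites] == list(range(1, 9))
    with pytest.raises(ValueError, match="at least 8"):
        place_readout_sites(cands[:5], 8)


# ---------------------------------------------------------- projection

def test_projection_identity_with_padding_preserves_distances():
    X = rng.normal(0, 1, (40, 20))
    proj = SiteProjection(d=32, seed=0).fit(X)
    Z = proj.transform(X)
    d_in = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    d_out = np.linalg.norm(Z[:, None] - Z[None, :], axis=-1)
    np.testing.assert_allclose(d_in, d_out, atol=1e-12)


def test_projection_rank_one_captures_structure():
    u = rng.normal(0, 1, 600)
    v = rng.normal(0, 1, 600)
    v /= np.linalg.norm(v)
    X = np.outer(u, v) + rng.normal(0, 1e-4, (600, 600))
    proj = SiteProjection(d=5, seed=0).fit(X)
    var = proj._pca.explained_variance_ratio_
    assert var[0] > 0.99


def test_projection_seed_reproducible():
    X = rng.normal(0, 1, (200, 700))
    Z1 = SiteProjection(d=16, seed=3).fit(X).transform(X)
    Z2 = SiteProjection(d=16, seed=3).fit(X).transform(X)
    np.testing.assert_array_equal(Z1, Z2)
    pooled = fit_projection([X[:100], X[100:]], d=16, seed=3)
    assert pooled.transform(X).shape == (200, 16)


# ------------------------------------------------------------- readout

def _separable_loadings(n=150, s=6, d=12, seed=0):
    r = np.random.default_rng(seed)
    y = r.integers(0, 2, n)
    w = r.normal(0, 1, d)
    w /= np.linalg.norm(w)
    base = r.normal(0, 0.5, (n, d))
    P = np.stack([base + np.outer((2 * y - 1) * (t + 1), w) for t in range(s)], axis=1)
    return P, y


def test_readout_alpha_zero_degenerates_to_static_logistic():
    P, y = _separable_loadings()
    ro = RecurrentSigmoidReadout(recurrent=True, n_iterations=50, seed=1).fit(P, y)
    ro.params_["alpha"][0] = 0.0
    ys = ro.predict_proba(P)
    static = 1.0 / (1.0 + np.exp(-(P @ ro.params_["w"] + ro.params_["b"][0])))
    np.testing.assert_allclose(ys, static, atol=1e-12)


def test_readout_separates_linearly_separable_data():
    P, y = _separable_loadings(seed=2)
    ro = RecurrentSigmoidReadout(recurrent=True, seed=0).fit(P, y)
    acc = ((ro.predict_proba(P)[:, -1] > 0.5) == y).mean()
    assert acc >= 0.99


def test_readout_balanced_class_weights_and_errors():
    P, y = _separable_loadings(seed=3)
    n1 = int(y.sum())
    w1 = len(y) / (2 * n1)
    w0 = len(y) / (2 * (len(y) - n1))
    if n1 * 2 == len(y):
        assert w0 == w1
    with pytest.raises(ValueError, match="single class"):
        RecurrentSigmoidReadout().fit(P, np.zeros(len(y)))


def test_feedforward_readout_trains_per_site():
    P, y = _separable_loadings(seed=4)
    ro = RecurrentSigmoidReadout(recurrent=False, n_iterations=300, seed=0).fit(P, y)
    assert ro.params_["w"].shape == (P.shape[1], P.shape[2])
    accs = ((ro.predict_proba(P) > 0.5) == y[:, None]).mean(axis=0)
    assert accs[-1] >= accs[0]  # later sites carry stronger evidence


# ---------------------------------------------------------- network RT

def test_network_rt_oracles():
    assert network_rt(binary_entropy(np.array([0.5, 0.52, 0.5])), LN2) == 1
    ys = np.array([0.5, 0.6, 0.95])
    assert network_rt(binary_entropy(ys), 0.3) == 3
    assert network_rt(binary_entropy(np.full(8, 0.5)), 0.1) == 8
    theta_sweep = [network_rt(binary_entropy(ys), th) for th in (0.1, 0.3, 0.6, LN2)]
    assert all(a >= b for a, b in zip(theta_sweep, theta_sweep[1:]))  # monotone


# ------------------------------------------------------------ LOO fit

def _zero_noise_setup(seed=1):
    ent = generate_entropy_trajectories(96, 8, seed=seed)
    cfg = SyntheticSubjectConfig(trial_noise_sd=0.0, gain_sd=0.0, offset_sd=0.0,
                                 seed=seed + 100)
    return ent, cfg, generate_subject_rts(ent, cfg)


def test_double_loo_recovers_planted_threshold():
    ent, cfg, human = _zero_noise_setup()
    res = double_loo_fit(ent, human)
    grid = res.theta_grid
    pos = int(np.searchsorted(grid, cfg.planted_threshold))
    lo = grid[max(pos - 2, 0)]
    hi = grid[min(pos, len(grid) - 1)]
    within = np.mean((res.thresholds >= lo - 1e-12) & (res.thresholds <= hi + 1e-12))
    assert within >= 0.9
    rs = evaluate_correlations(res, human)
    assert np.nanmean(rs) > 0.99


def test_double_loo_fold_hygiene():
    """Perturbing the held-out cell leaves its prediction unchanged."""
    ent = generate_entropy_trajectories(12, 8, seed=5)
    cfg = SyntheticSubjectConfig(n_subjects=5, n_images=12, seed=6)
    human = generate_subject_rts(ent, cfg)
    res = double_loo_fit(ent, human)
    s, i = 2, 7
    bumped = RTMatrix(values=human.values.copy())
    bumped.values[s, i] += 500.0
    res2 = double_loo_fit(ent, bumped)
    assert res.predicted_rt[s, i] == res2.predicted_rt[s, i]
    assert res.thresholds[s, i] == res2.thresholds[s, i]


def test_double_loo_rejects_constant_human_matrix():
    ent = generate_entropy_trajectories(10, 8, seed=7)
    human = RTMatrix(values=np.full((4, 10), 500.0))
    with pytest.raises(ValueError, match="constant"):
        double_loo_fit(ent, human)


def test_double_loo_input_validation():
    ent = generate_entropy_trajectories(10, 8, seed=8)
    cfg = SyntheticSubjectConfig(n_subjects=2, n_images=10, seed=9)
    human = generate_subject_rts(ent, cfg)
    with pytest.raises(ValueError, match="at least 3"):
        double_loo_fit(ent, human)
    with pytest.raises(ValueError, match="image count"):
        double_loo_fit(ent[:5], generate_subject_rts(
            ent, SyntheticSubjectConfig(n_subjects=5, n_images=10, seed=9)))


# -------------------------------------------------------- correlations

def test_evaluate_correlations_affine_extremes():
    human = RTMatrix(values=rng.uniform(400, 900, (3, 20)))

    class R:  # minimal FitResult stand-in
        predicted_rt = human.values * 2.0 + 10.0

    rs = evaluate_correlations(R, human)
    np.testing.assert_allclose(rs, 1.0, atol=1e-12)
    R.predicted_rt = -human.values
    np.testing.assert_allclose(evaluate_correlations(R, human), -1.0, atol=1e-12)


def test_random_predictions_correlate_near_zero():
    human = RTMatrix(values=rng.uniform(400, 900, (1, 96)))
    mean_rs = []
    for _ in range(100):
        class R:
            predicted_rt = rng.integers(1, 9, (1, 96)).astype(float)
        mean_rs.append(evaluate_correlations(R, human)[0])
    assert abs(np.mean(mean_rs)) < 0.3


def test_human_consistency_extremes():
    identical = RTMatrix(values=np.tile(rng.uniform(400, 900, 30), (4, 1)))
    np.testing.assert_allclose(human_consistency(identical), 1.0, atol=1e-12)
    a = rng.uniform(400, 900, 30)
    anti = RTMatrix(values=np.stack([a, 1300 - a]))
    np.testing.assert_allclose(human_consistency(anti), -1.0, atol=1e-12)
    with pytest.raises(ValueError, match="at least 2"):
        human_consistency(RTMatrix(values=a[None]))


# ----------------------------------------------------------- inference

def test_permutation_identical_vectors_give_p_one():
    v = rng.normal(0.5, 0.1, 10)
    assert paired_permutation_test(v, v) == 1.0


def test_permutation_matches_exact_enumeration_atom():
    """All 20 differences equal and same sign: exact two-tailed atom is
    2 * 2^-20, floored at 1/(n_perm + 1)."""
    a = np.full(20, 0.8)
    b = np.full(20, 0.5)
    exact_atom = 2 * 2.0 ** -20  # enumeration: only all-plus/all-minus reach |obs|
    n_perm = 10_000
    p = paired_permutation_test(a, b, n_perm=n_perm, seed=0)
    assert p >= 1 / (n_perm + 1)
    assert p <= 20 * max(exact_atom, 1 / (n_perm + 1))  # overwhelming significance
    # symmetry under swapped arguments
    assert p == paired_permutation_test(b, a, n_perm=n_perm, seed=0)


def test_permutation_seed_reproducible():
    a, b = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
    assert paired_permutation_test(a, b, seed=4) == paired_permutation_test(a, b, seed=4)


def test_bh_fdr_step_up_oracle():
    def step_up(p, q):
        p = np.asarray(p, dtype=float)
        order = np.argsort(p)
        m = len(p)
        kmax = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * q / m:
                kmax = rank
        reject = np.zeros(m, dtype=bool)
        reject[order[:kmax]] = True
        return reject

    cases = [([0.01], 0.05), ([0.01, 0.02, 0.04, 0.8], 0.05), ([1.0, 1.0, 1.0], 0.05)]
    for p, q in cases:
        got, adj = bh_fdr(p, q)
        np.testing.assert_array_equal(got, step_up(p, q))
        assert np.all((adj >= np.asarray(p) - 1e-12) & (adj <= 1.0))
    # the standard step-up rejects exactly the two smallest in the toy vector
    got, _ = bh_fdr([0.01, 0.02, 0.04, 0.8], 0.05)
    assert got.tolist() == [True, True, False, False]
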