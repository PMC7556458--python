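"""Fitting network reaction times to human reaction times.

The pipeline mirrors a binary (super-category, e.g. animate/inanimate)
discrimination task: sigmoid readouts are trained at eight sites spaced
evenly in cumulative computational cost through a network, the site at which
the readout's binary entropy first falls to or below a threshold theta is the
network's reaction time, and theta is fitted to a subjects x images human
reaction-time matrix by double leave-one-out cross-validation (hold out one
subject and one image per fold; maximise the Pearson correlation between
network reaction times and the training subjects' mean reaction time on the
training images; predict the held-out cell).  Per-subject correlations are
compared across models with a paired sign-flip permutation test and the
Benjamini-Hochberg false-discovery-rate procedure, against a noise ceiling
lower-bounded by leave-one-subject-out human consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from . import nn

LN2 = float(np.log(2.0))


# ------------------------------------------------------------------- sites

@dataclass(frozen=True)
class ReadoutSite:
    site_index: int  # 1-based
    graph_position: object  # layer / time-step identifier
    cumulative_cost: float


def place_readout_sites(candidates: Sequence[tuple[object, float]], n_sites: int = 8
                        ) -> list[ReadoutSite]:
    """Choose readout sites spaced evenly in cumulative cost.

    ``candidates`` are (identifier, cumulative_cost) pairs in network order
    with strictly increasing cost.  For multi-readout networks the candidates
    are simply the existing per-step readouts (all are kept when there are
    exactly ``n_sites``).  Otherwise the last candidate (the full
    computation) is always selected and the remaining sites minimise the
    maximum deviation of between-site cost gaps from the ideal even spacing
    total_cost / n_sites, found by dynamic programming over (candidate,
    number chosen).
    """
    if len(candidates) < n_sites:
        raise ValueError(f"need at least {n_sites} candidates, got {len(candidates)}")
    ids = [c[0] for c in candidates]
    costs = np.asarray([c[1] for c in candidates], dtype=float)
    if np.any(np.diff(costs) <= 0):
        raise ValueError("candidate costs must be strictly increasing")
    m = len(costs)
    if m == n_sites:
        chosen = list(range(m))
    else:
        ideal = costs[-1] / n_sites
        NEG = -1
        # dp[i][j]: minimal max-deviation using j sites ending at candidate i
        dp = np.full((m, n_sites + 1), np.inf)
        back = np.full((m, n_sites + 1), NEG, dtype=int)
        for i in range(m):
            dp[i][1] = abs(costs[i] - ideal)  # first gap measured from zero cost
        for j in range(2, n_sites + 1):
            for i in range(j - 1, m):
                for p in range(j - 2, i):
                    cand = max(dp[p][j - 1], abs(costs[i] - costs[p] - ideal))
                    if cand < dp[i][j]:
                        dp[i][j] = cand
                        back[i][j] = p
        chosen = [m - 1]
        j = n_sites
        while j > 1:
            chosen.append(back[chosen[-1]][j])
            j -= 1
        chosen = chosen[::-1]
    return [
        ReadoutSite(site_index=k + 1, graph_position=ids[i], cumulative_cost=float(costs[i]))
        for k, i in enumerate(chosen)
    ]


# -------------------------------------------------------------- projection

class SiteProjection:
    """Linear map from site activations to ``d`` principal-component loadings.

    Fitted on training activations; for recurrent networks activations from
    all sites (time steps) are pooled into a single fit.  When the ambient
    dimension is at most ``d`` the map is the identity with zero padding,
    which preserves pairwise distances exactly.
    """

    def __init__(self, d: int = 512, seed: int = 0):
        if d < 1:
            raise ValueError("d must be >= 1")
        self.d = d
        self.seed = seed
        self._pca: PCA | None = None
        self._ambient: int | None = None

    def fit(self, activations: np.ndarray) -> "SiteProjection":
        """``activations``: (n_samples, ambient_dim), sites already pooled."""
        X = np.asarray(activations, dtype=float)
        self._ambient = X.shape[1]
        if self._ambient <= self.d:
            self._pca = None
        else:
            self._pca = PCA(
                n_components=self.d, svd_solver="randomized", random_state=self.seed
            ).fit(X)
        return self

    def transform(self, activations: np.ndarray) -> np.ndarray:
        X = np.asarray(activations, dtype=float)
        if self._pca is None:
            if X.shape[1] == self.d:
                return X
            pad = np.zeros((X.shape[0], self.d - X.shape[1]))
            return np.hstack([X, pad])
        return self._pca.transform(X)


def fit_projection(site_activations: Sequence[np.ndarray], d: int = 512,
                   seed: int = 0) -> SiteProjection:
    """Fit the PCA projection on activations pooled across all sites."""
    pooled = np.vstack([np.asarray(a, dtype=float) for a in site_activations])
    return SiteProjection(d=d, seed=seed).fit(pooled)


# ----------------------------------------------------------- binary readout

class RecurrentSigmoidReadout:
    """Recurrent binary readout y_t = sigmoid(alpha*y_{t-1} + w.p_t + b).

    One (alpha, w, b) is shared across all sites when ``recurrent=True`` (the
    recurrence parameter alpha lets evidence accumulate across sites, from
    the neutral initial state y_0 = 0.5); with ``recurrent=False`` an
    independent static logistic readout (w_s, b_s) is trained per site and
    alpha is absent.  Trained by full-batch Adam, learning rate 0.001 for
    1000 iterations, with the binary cross-entropy weighted inversely to
    class frequency.
    """

    def __init__(self, recurrent: bool = True, learning_rate: float = 0.001,
                 n_iterations: int = 1000, seed: int = 0):
        self.recurrent = recurrent
        self.learning_rate = learning_rate
        self.n_iterations = n_iterations
        self.seed = seed

    def fit(self, loadings: np.ndarray, y: np.ndarray) -> "RecurrentSigmoidReadout":
        """``loadings``: (n_samples, n_sites, d); ``y``: binary labels."""
        P = np.asarray(loadings, dtype=float)
        y = np.asarray(y, dtype=float)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set contains a single class")
        n, s, d = P.shape
        self.n_sites_ = s
        # weights inversely proportional to class frequency, mean-normalised
        w1 = n / (2.0 * np.sum(y == 1))
        w0 = n / (2.0 * np.sum(y == 0))
        sample_w = np.where(y == 1, w1, w0)

        rng = np.random.default_rng(self.seed)
        if self.recurrent:
            params = {
                "alpha": np.zeros(1),
                "w": rng.normal(0, 1.0 / np.sqrt(d), d),
                "b": np.zeros(1),
            }
        else:
            params = {
                "w": rng.normal(0, 1.0 / np.sqrt(d), (s, d)),
                "b": np.zeros(s),
            }
        opt = nn.Adam(lr=self.learning_rate, eps=1e-8)
        for _ in range(self.n_iterations):
            out, grads = self._loss_grads(params, P, y, sample_w)
            opt.step(params, grads)
        self.params_ = params
        return self

    def _forward(self, params, P):
        n, s, d = P.shape
        ys = np.empty((n, s))
        if self.recurrent:
            y_prev = np.full(n, 0.5)
            for t in range(s):
                z = params["alpha"][0] * y_prev + P[:, t] @ params["w"] + params["b"][0]
                y_prev = nn.sigmoid(z)
                ys[:, t] = y_prev
        else:
            for t in range(s):
                ys[:, t] = nn.sigmoid(P[:, t] @ params["w"][t] + params["b"][t])
        return ys

    def _loss_grads(self, params, P, y, sample_w):
        n, s, d = P.shape
        ys = self._forward(params, P)
        eps = 1e-12
        # weighted BCE averaged over sites and samples
        wnorm = sample_w / (sample_w.sum() * s)
        if not self.recurrent:
            grads = {"w": np.zeros_like(params["w"]), "b": np.zeros_like(params["b"])}
            for t in range(s):
                dz = (ys[:, t] - y) * wnorm
                grads["w"][t] = P[:, t].T @ dz
                grads["b"][t] = dz.sum()
            return ys, grads
        # backprop through the recurrence
        grads = {"alpha": np.zeros(1), "w": np.zeros(d), "b": np.zeros(1)}
        dy_next = np.zeros(n)
        for t in reversed(range(s)):
            dy = -wnorm * (y / (ys[:, t] + eps) - (1 - y) / (1 - ys[:, t] + eps))
            dy = dy + dy_next
            dz = dy * ys[:, t] * (1 - ys[:, t])
            y_prev = ys[:, t - 1] if t > 0 else np.full(n, 0.5)
            grads["alpha"][0] += dz @ y_prev
            grads["w"] += P[:, t].T @ dz
            grads["b"][0] += dz.sum()
            dy_next = dz * params["alpha"][0]
        return ys, grads

    def predict_proba(self, loadings: np.ndarray) -> np.ndarray:
        """Per-site outputs y_t in (0, 1); shape (n_samples, n_sites)."""
        return self._forward(self.params_, np.asarray(loadings, dtype=float))


# ---------------------------------------------------------- reaction times

def binary_entropy(y: np.ndarray) -> np.ndarray:
    """Two-outcome Shannon entropy in nats of sigmoid outputs."""
    y = np.clip(np.asarray(y, dtype=float), 1e-12, 1 - 1e-12)
    return -(y * np.log(y) + (1 - y) * np.log(1 - y))


def network_rt(entropies: np.ndarray, theta: float) -> np.ndarray:
    """First 1-based site whose entropy is <= theta; the last site if never.

    ``entropies`` is (n_images, n_sites) (a single image's vector is also
    accepted).
    """
    ent = np.atleast_2d(np.asarray(entropies, dtype=float))
    reached = ent <= theta
    n_sites = ent.shape[1]
    rt = np.where(reached.any(axis=1), reached.argmax(axis=1), n_sites - 1) + 1
    return rt if np.asarray(entropies).ndim == 2 else rt[0]


# --------------------------------------------------------------- RT matrix

@dataclass
class RTMatrix:
    """Subjects x images reaction times (ms for humans, site index for nets)."""

    values: np.ndarray
    subject_ids: list = None
    image_ids: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x images")
        if np.any(self.values <= 0):
            raise ValueError("reaction times must be positive")
        if self.subject_ids is None:
            self.subject_ids = [f"s{i + 1:02d}" for i in range(self.values.shape[0])]
        if self.image_ids is None:
            self.image_ids = [f"img{j + 1:03d}" for j in range(self.values.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_images(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.subject_ids, columns=self.image_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "RTMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float),
                   subject_ids=list(df.index), image_ids=list(df.columns))


# ------------------------------------------------------------ threshold fit

@dataclass
class FitResult:
    """Outcome of the double leave-one-out threshold fit."""

    thresholds: np.ndarray  # (n_subjects, n_images) fitted theta per fold
    predicted_rt: np.ndarray  # (n_subjects, n_images) predicted site index
    theta_grid: np.ndarray
    flagged_folds: int  # folds where r was undefined and theta fell back


def _rt_on_grid(entropies: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """(G, n_images) reaction times for every grid threshold."""
    ent = np.asarray(entropies, dtype=float)
    reached = ent[None, :, :] <= grid[:, None, None]
    n_sites = ent.shape[1]
    return np.where(reached.any(axis=2), reached.argmax(axis=2), n_sites - 1) + 1


def _rowwise_pearson(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of every row of A against b; rows/targets with zero
    variance give NaN."""
    Ac = A - A.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    na = np.sqrt((Ac * Ac).sum(axis=1))
    nb = np.sqrt((bc * bc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ac @ bc) / (na * nb)
    r[na == 0] = np.nan
    return r if nb > 0 else np.full(A.shape[0], np.nan)


def double_loo_fit(
    entropies: np.ndarray,
    human: RTMatrix,
    theta_grid: np.ndarray | None = None,
) -> FitResult:
    """Fit the entropy threshold by double leave-one-out cross-validation.

    ``entropies`` is (n_images, n_sites): per-image site entropies, already
    averaged across model seeds.  For every (subject, image) fold, theta is
    chosen on the remaining (subjects-1) x (images-1) cells to maximise the
    Pearson correlation between network reaction times and the training
    subjects' mean reaction time; ties go to the largest theta (earliest
    decisions).  The held-out cell's prediction is the network reaction time
    at the fitted theta.  Folds whose training correlation is undefined
    (constant vectors) are flagged and fall back to the global median of the
    fitted thresholds; if every fold is degenerate a ValueError is raised.
    """
    ent = np.asarray(entropies, dtype=float)
    S, I = human.n_subjects, human.n_images
    if ent.shape[0] != I:
        raise ValueError("entropies and human matrix disagree on image count")
    if S < 3 or I < 3:
        raise ValueError("need at least 3 subjects and 3 images")
    if theta_grid is None:
        theta_grid = np.unique(np.concatenate([ent.ravel(), [0.0, LN2]]))
    theta_grid = np.asarray(theta_grid, dtype=float)

    rt_grid = _rt_on_grid(ent, theta_grid)  # (G, I)
    colsum = human.values.sum(axis=0)

    # the grid for a fold is restricted to entropies observed on training
    # images (plus endpoints): mask out grid values contributed solely by the
    # held-out image
    has_value = (np.abs(ent.T[None, :, :] - theta_grid[:, None, None]) < 1e-15
                 ).any(axis=1)  # (G, I) -- image i exhibits grid value g
    n_owners = has_value.sum(axis=1)  # images exhibiting each grid value

    thresholds = np.full((S, I), np.nan)
    predicted = np.zeros((S, I))
    flagged = np.zeros((S, I), dtype=bool)
    for s in range(S):
        m_s = (colsum - human.values[s]) / (S - 1)  # training-subject mean RT
        for i in range(I):
            mask = np.ones(I, dtype=bool)
            mask[i] = False
            allowed = (n_owners - has_value[:, i]) > 0
            allowed |= n_owners == 0  # endpoints / user-supplied values
            r = _rowwise_pearson(rt_grid[:, mask], m_s[mask])
            r = np.where(allowed, r, np.nan)
            if np.all(np.isnan(r)):
                flagged[s, i] = True
                continue
            best = np.nanmax(r)
            # largest theta among the maximisers
            candidates = np.where(np.nan_to_num(r, nan=-np.inf) >= best - 1e-12)[0]
            theta = theta_grid[candidates.max()]
            thresholds[s, i] = theta
            predicted[s, i] = network_rt(ent[i], theta)
    if flagged.all():
        raise ValueError("constant reaction-time vectors: correlation undefined in every fold")
    if flagged.any():
        fallback = float(np.nanmedian(thresholds))
        for s, i in zip(*np.nonzero(flagged)):
            thresholds[s, i] = fallback
            predicted[s, i] = network_rt(ent[i], fallback)
    return FitResult(
        thresholds=thresholds,
        predicted_rt=predicted,
        theta_grid=theta_grid,
        flagged_folds=int(flagged.sum()),
    )


def evaluate_correlations(result: FitResult, human: RTMatrix) -> np.ndarray:
    """Per-subject Pearson r between predicted and observed reaction times.

    Subjects with constant vectors yield NaN (undefined correlation).
    """
    S = human.n_subjects
    rs = np.empty(S)
    for s in range(S):
        rs[s] = _pearson_or_nan(result.predicted_rt[s], human.values[s])
    return rs


def _pearson_or_nan(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def human_consistency(human: RTMatrix) -> np.ndarray:
    """Leave-one-subject-out correlation: each subject against the mean of
    all others.  A lower bound on the noise ceiling."""
    if human.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    total = human.values.sum(axis=0)
    rs = np.empty(human.n_subjects)
    for s in range(human.n_subjects):
        others = (total - human.values[s]) / (human.n_subjects - 1)
        rs[s] = _pearson_or_nan(human.values[s], others)
    return rs


def paired_permutation_test(
    r_a: Sequence[float],
    r_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-tailed paired sign-flip permutation test for the mean difference.

    The identity permutation is included, so p >= 1 / (n_perm + 1).
    """
    a = np.asarray(r_a, dtype=float)
    b = np.asarray(r_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("per-subject vectors must be aligned")
    d = a - b
    obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    stats = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(stats >= obs - 1e-15)) / (n_perm + 1))


def bh_fdr(p_values: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns (reject flags, adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
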