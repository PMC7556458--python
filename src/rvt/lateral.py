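"""Principal-component analysis of lateral (within-layer) weight templates.

A recurrent layer with F feature maps and kernel size K holds F^2 lateral
weight templates: one K x K patch for every ordered (source, target) feature
pair, self-connections included.  Each template is flattened, normalised to
unit Euclidean length and treated as one sample; mean-centred PCA over the
ensemble yields the lateral-weight components.  Components are reported in
both their positive and sign-flipped negative forms, with the proportion of
variance each explains and the (source, target) pairs loading most strongly
on each component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class WeightTemplate:
    source_map: int
    target_map: int
    kernel: np.ndarray  # (K, K)


@dataclass(frozen=True)
class ComponentSet:
    """k unit-norm components over flattened templates.

    ``loadings`` is (n_templates, k): the projection of each centred template
    onto each component.  ``pairs`` records the (source, target) order of the
    template rows (row-major over source then target).
    """

    components: np.ndarray  # (k, K*K)
    variance_explained: np.ndarray  # (k,)
    loadings: np.ndarray  # (F^2 - excluded, k)
    pairs: np.ndarray  # (rows, 2) of (source, target)
    kernel_size: int

    @property
    def negative_components(self) -> np.ndarray:
        return -self.components

    def component_image(self, index: int, sign: str = "positive") -> np.ndarray:
        comp = self.components[index].reshape(self.kernel_size, self.kernel_size)
        return comp if sign == "positive" else -comp


def extract_templates(lateral_weights: np.ndarray) -> list[WeightTemplate]:
    """Split a (K, K, F, F) lateral weight array into F^2 templates.

    Template ordering is row-major over (source, target); axis 2 of the
    weight array indexes the source (input) feature map and axis 3 the
    target (output) map, matching the convolution weight layout.
    """
    w = np.asarray(lateral_weights)
    if w.ndim != 4 or w.shape[0] != w.shape[1]:
        raise ValueError("lateral weights must be (K, K, F, F)")
    if w.shape[2] != w.shape[3]:
        raise ValueError("lateral connections require square feature dimensions")
    f = w.shape[2]
    return [
        WeightTemplate(source_map=s, target_map=t, kernel=w[:, :, s, t].copy())
        for s in range(f)
        for t in range(f)
    ]


def assemble_templates(templates: list[WeightTemplate], k: int, f: int) -> np.ndarray:
    """Inverse of :func:`extract_templates` (round-trip check helper)."""
    w = np.zeros((k, k, f, f))
    for tpl in templates:
        w[:, :, tpl.source_map, tpl.target_map] = tpl.kernel
    return w


def normalize_templates(templates: list[WeightTemplate]) -> tuple[list[WeightTemplate], int]:
    """Scale each flattened template to unit Euclidean norm.

    All-zero templates cannot be normalised; they are excluded and counted,
    with a warning.  Returns (normalised templates, n_excluded).
    """
    out, excluded = [], 0
    for tpl in templates:
        norm = float(np.linalg.norm(tpl.kernel))
        if norm == 0.0:
            excluded += 1
            continue
        out.append(WeightTemplate(tpl.source_map, tpl.target_map, tpl.kernel / norm))
    if excluded:
        warnings.warn(f"excluded {excluded} all-zero lateral weight template(s)")
    return out, excluded


def pca_components(templates: list[WeightTemplate], k: int = 5) -> ComponentSet:
    """Mean-centred PCA over flattened normalised templates."""
    if not templates:
        raise ValueError("no templates provided")
    ksize = templates[0].kernel.shape[0]
    X = np.stack([t.kernel.ravel() for t in templates])
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds the rank bound {min(X.shape)}")
    pca = PCA(n_components=k, svd_solver="full").fit(X)
    loadings = pca.transform(X)
    pairs = np.array([(t.source_map, t.target_map) for t in templates])
    return ComponentSet(
        components=pca.components_,
        variance_explained=pca.explained_variance_ratio_,
        loadings=loadings,
        pairs=pairs,
        kernel_size=ksize,
    )


def top_loading_pairs(components: ComponentSet, component_index: int, m: int = 5):
    """Strongest positive and negative loadings on one component.

    Returns (positive, negative): lists of (source, target, loading), the
    positive list sorted by decreasing loading and the negative list by
    increasing loading.  Ties break by (source, target) index order.
    """
    n = components.loadings.shape[0]
    if m > n:
        raise ValueError(f"m={m} exceeds the number of templates {n}")
    lo = components.loadings[:, component_index]
    src, tgt = components.pairs[:, 0], components.pairs[:, 1]
    order_desc = np.lexsort((tgt, src, -lo))
    order_asc = np.lexsort((tgt, src, lo))
    pos = [(int(src[i]), int(tgt[i]), float(lo[i])) for i in order_desc[:m]]
    neg = [(int(src[i]), int(tgt[i]), float(lo[i])) for i in order_asc[:m]]
    return pos, neg


class LateralWeightPCA(BaseEstimator, TransformerMixin):
    """Transformer wrapping the template extraction + PCA pipeline.

    ``fit`` takes the (K, K, F, F) lateral weight array of one layer;
    ``transform`` maps any such array to component loadings.  Fitted
    attributes: ``components_``, ``variance_explained_``, ``loadings_``,
    ``n_excluded_``.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y=None):
        templates = extract_templates(np.asarray(X))
        templates, self.n_excluded_ = normalize_templates(templates)
        cs = pca_components(templates, k=self.n_components)
        self.component_set_ = cs
        self.components_ = cs.components
        self.variance_explained_ = cs.variance_explained
        self.loadings_ = cs.loadings
        self.mean_ = np.stack([t.kernel.ravel() for t in templates]).mean(axis=0)
        return self

    def transform(self, X):
        templates, _ = normalize_templates(extract_templates(np.asarray(X)))
        M = np.stack([t.kernel.ravel() for t in templates])
        return (M - self.mean_) @ self.components_.T
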