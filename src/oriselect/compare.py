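"""Quantitative comparison of inferred motifs.

Normalized motifs live on a common scale (zero column sums, unit
Frobenius norm), so replicate and cross-strain comparisons reduce to
linear algebra on their unrolled 4L-vectors: Pearson similarity after
sign alignment, and PCA of an ensemble to see which strains' motifs
cluster together and along which parameter directions they separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .motif import BASES, Motif


def unroll(motif: Motif) -> np.ndarray:
    """Unroll the 4 x L parameter matrix into a 4L vector.

    Base-major order: the full A row left-to-right, then C, G, T.
    Invertible via :func:`reroll`.
    """
    return motif.theta.ravel(order="C").copy()


def reroll(vector: np.ndarray, length: int | None = None) -> Motif:
    """Inverse of :func:`unroll`."""
    vector = np.asarray(vector, dtype=float)
    if vector.size % 4:
        raise ValueError("vector length must be a multiple of 4")
    L = vector.size // 4 if length is None else length
    return Motif(theta=vector.reshape(4, L))


def _check_ensemble(motifs) -> np.ndarray:
    motifs = list(motifs)
    if not motifs:
        raise ValueError("empty motif ensemble")
    L = motifs[0].length
    for m in motifs:
        if m.length != L:
            raise ValueError("ensemble motifs have different lengths")
        if not m.normalized:
            raise ValueError("ensemble motifs must be normalized")
    return np.vstack([unroll(m) for m in motifs])


@dataclass
class MotifPCA:
    """PCA of an ensemble of normalized motifs.

    ``coordinates`` is (label x component) scores of each motif on the
    ranked principal components; ``explained_variance_ratio`` fractions
    are non-increasing and sum to <= 1.
    """

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    components: np.ndarray

    def to_tsv(self, coords_path, variance_path) -> None:
        self.coordinates.to_csv(coords_path, sep="\t")
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(self.explained_variance_ratio))],
                "explained_variance_ratio": self.explained_variance_ratio,
            }
        ).to_csv(variance_path, sep="\t", index=False)


def pca_motifs(motifs, labels=None, n_components: int | None = None) -> MotifPCA:
    """PCA on the centered unrolled vectors of >= 2 normalized motifs.

    Component signs follow a deterministic convention: the
    largest-magnitude loading of each component is made positive, so
    results do not depend on ensemble ordering (up to that sign).
    A singular ensemble (all motifs identical) yields all-zero
    coordinates and zero explained variance.
    """
    X = _check_ensemble(motifs)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 motifs")
    if labels is None:
        labels = [m.label or f"motif_{i}" for i, m in enumerate(motifs)]
    k = min(n, X.shape[1]) if n_components is None else n_components
    pca = PCA(n_components=min(k, n, X.shape[1]))
    scores = pca.fit_transform(X)
    components = pca.components_
    # deterministic sign: largest-|loading| positive
    for j in range(components.shape[0]):
        peak = np.argmax(np.abs(components[j]))
        if components[j, peak] < 0:
            components[j] *= -1
            scores[:, j] *= -1
    evr = pca.explained_variance_ratio_
    total_var = float(((X - X.mean(axis=0)) ** 2).sum())
    if not np.all(np.isfinite(evr)) or total_var < 1e-18:  # singular ensemble
        evr = np.zeros_like(evr)
        scores = np.zeros_like(scores)
    coords = pd.DataFrame(
        scores,
        index=pd.Index(labels, name="label"),
        columns=[f"PC{i+1}" for i in range(scores.shape[1])],
    )
    return MotifPCA(
        coordinates=coords,
        explained_variance_ratio=evr,
        components=components,
    )


def motif_similarity(m1: Motif, m2: Motif) -> float:
    """Sign-aligned Pearson correlation of two normalized motifs' vectors.

    Because the inputs are gauge-fixed and a rank-based objective cannot
    distinguish theta from -theta, the sign of the correlation is not
    meaningful: the vectors are aligned (second negated if the inner
    product is negative) before computing Pearson r.  Symmetric; in
    [0, 1] after alignment.
    """
    if m1.length != m2.length:
        raise ValueError("motifs have different lengths")
    if not (m1.normalized and m2.normalized):
        raise ValueError("motif_similarity requires normalized motifs")
    v1, v2 = unroll(m1), unroll(m2)
    if not v1.any() or not v2.any():
        raise ValueError("degenerate (zero) motif")
    if float(v1 @ v2) < 0:
        v2 = -v2
    r = np.corrcoef(v1, v2)[0, 1]
    return float(r)
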