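"""Spectral clustering of the patient-similarity graph and pseudo-labels.

Clusters come from the eigenvectors of the unnormalized graph Laplacian
L = D - A. Labels are extracted either with the deterministic cluster-qr
procedure (pivoted QR of the eigenvector matrix; Damle, Minden & Ying 2019)
or with seeded k-means on the embedding. The labels are unsupervised: they
depend only on the graph, never on survival times, and serve as targets for
the self-supervised stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .graph_construction import SimilarityGraph

#: eigenvalues below this (relative to the largest) count as zero
ZERO_EIGENVALUE_TOL = 1e-8


def laplacian(graph: SimilarityGraph | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized Laplacian L = D - A and the degree matrix D."""
    A = graph.adjacency if isinstance(graph, SimilarityGraph) else np.asarray(graph, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.diag(A).any():
        raise ValueError("adjacency must have zero diagonal")
    D = np.diag(A.sum(axis=1))
    return D - A, D


@dataclass
class SpectralEmbedding:
    """The n_components smallest eigenpairs of the Laplacian."""

    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns matched to eigenvalues
    n_components: int

    def n_zero_eigenvalues(self) -> int:
        """Numerically-zero eigenvalues = number of connected components
        (when all eigenvalues are retained)."""
        scale = max(abs(self.eigenvalues[-1]), 1.0)
        return int((np.abs(self.eigenvalues) <= ZERO_EIGENVALUE_TOL * scale).sum())


def spectral_embed(L: np.ndarray, n_components: int | None = None) -> SpectralEmbedding:
    """Eigendecompose L; keep the ``n_components`` smallest eigenpairs.

    Sign convention: the largest-magnitude entry of each eigenvector is made
    positive, so repeated runs return identical embeddings.
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if n_components is None:
        n_components = n
    if not 1 <= n_components <= n:
        raise ValueError(f"n_components must be in [1, {n}]")
    vals, vecs = scipy.linalg.eigh(L)  # ascending by contract
    for j in range(vecs.shape[1]):
        k = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return SpectralEmbedding(
        eigenvalues=vals[:n_components],
        eigenvectors=vecs[:, :n_components],
        n_components=n_components,
    )


@dataclass
class PseudoLabeling:
    """Cluster index per patient from spectral clustering of the BBSG."""

    patient_ids: list[str]
    labels: np.ndarray
    n_clusters: int
    method: str
    seed: int


def _cluster_qr(vectors: np.ndarray) -> np.ndarray:
    """Deterministic cluster extraction from spectral eigenvectors.

    Pivoted QR of the transposed eigenvector matrix picks one representative
    row per cluster; an orthogonal Procrustes rotation towards those
    representatives turns the embedding into approximate indicators, and each
    row is assigned to its largest coordinate.
    """
    k = vectors.shape[1]
    _, _, piv = scipy.linalg.qr(vectors.T, pivoting=True)
    ut, _, vt = np.linalg.svd(vectors[piv[:k], :].T)
    rotated = np.abs(vectors @ (ut @ vt))
    return rotated.argmax(axis=1)


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first occurrence so runs are comparable."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def assign_pseudo_labels(
    embedding: SpectralEmbedding,
    patient_ids: list[str],
    n_clusters: int,
    method: str = "cluster-qr",
    seed: int = 0,
) -> PseudoLabeling:
    """Cluster the spectral embedding into ``n_clusters`` pseudo-labels.

    Uses the ``n_clusters`` leading (smallest-eigenvalue) eigenvectors.
    cluster-qr is deterministic; k-means is seeded. Label indices are
    canonicalized by first occurrence in patient order.
    """
    n = embedding.eigenvectors.shape[0]
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} patients")
    if embedding.n_components < n_clusters:
        raise ValueError(
            f"embedding has {embedding.n_components} components; need >= {n_clusters}"
        )
    if n_clusters == 1:
        labels = np.zeros(n, dtype=int)
    else:
        vectors = embedding.eigenvectors[:, :n_clusters]
        if method == "cluster-qr":
            labels = _cluster_qr(vectors)
        elif method == "k-means":
            km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
            labels = km.fit_predict(vectors)
        else:
            raise ValueError(f"unknown method {method!r}; use 'cluster-qr' or 'k-means'")
    return PseudoLabeling(
        patient_ids=list(patient_ids),
        labels=_canonicalize(np.asarray(labels, dtype=int)),
        n_clusters=n_clusters,
        method=method,
        seed=seed,
    )


def pseudo_label_graph(
    graph: SimilarityGraph,
    n_clusters: int,
    method: str = "cluster-qr",
    seed: int = 0,
) -> PseudoLabeling:
    """Laplacian -> spectral embedding -> pseudo-labels, in one call.

    Isolated patients (degree 0) are excluded from the eigenproblem — each
    would add a spurious zero eigenvalue, swamping the component structure
    the leading eigenvectors are meant to capture — and are then assigned to
    the cluster with the highest mean (continuous) similarity. Labels still
    depend only on the graph, never on survival times.
    """
    degrees = graph.adjacency.sum(axis=1)
    isolated = degrees == 0
    n = len(graph.patient_ids)
    if isolated.any() and (~isolated).sum() >= n_clusters:
        keep = np.flatnonzero(~isolated)
        sub = graph.adjacency[np.ix_(keep, keep)]
        L = np.diag(sub.sum(axis=1)) - sub
        embedding = spectral_embed(L, n_components=max(n_clusters, 1))
        core = assign_pseudo_labels(
            embedding, [graph.patient_ids[i] for i in keep], n_clusters, method, seed
        )
        labels = np.empty(n, dtype=int)
        labels[keep] = core.labels
        for i in np.flatnonzero(isolated):
            sims = []
            for c in range(n_clusters):
                members = keep[core.labels == c]
                sims.append(graph.similarity[i, members].mean() if len(members) else -np.inf)
            labels[i] = int(np.argmax(sims))
        return PseudoLabeling(
            patient_ids=list(graph.patient_ids),
            labels=_canonicalize(labels),
            n_clusters=n_clusters,
            method=method,
            seed=seed,
        )
    L, _ = laplacian(graph)
    embedding = spectral_embed(L, n_components=max(n_clusters, 1))
    return assign_pseudo_labels(embedding, graph.patient_ids, n_clusters, method, seed)
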