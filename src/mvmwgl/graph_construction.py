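"""Patient-similarity graphs and the shared gene-interaction graph.

The patient graph (BBSG when built from standardized raw expression, RBSG when
rebuilt from learned gene representations) connects two patients when the
cosine similarity of their feature vectors reaches a threshold eta. The gene
graph is one undirected structure shared by all patients; its propagation
operator is the symmetric GCN normalization A_hat = D_hat^(-1/2) (M + I)
D_hat^(-1/2) with self-looped degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import InteractionEdgeList

logger = logging.getLogger(__name__)


@dataclass
class StandardizationStats:
    means: np.ndarray
    sds: np.ndarray  # zero-sd columns stored as sd = 0; those columns map to 0


def standardize(
    matrix: np.ndarray, fit_rows: np.ndarray | None = None
) -> tuple[np.ndarray, StandardizationStats]:
    """Column-wise z-scoring with statistics fit on ``fit_rows``.

    The fitted statistics are applied to all rows and returned for reuse on
    new data. Zero-sd columns become all-zeros with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    if fit_rows is None:
        fit_rows = np.ones(matrix.shape[0], dtype=bool)
    fit_rows = np.asarray(fit_rows, dtype=bool)
    sub = matrix[fit_rows]
    if sub.shape[0] == 0:
        raise ValueError("no fit rows for standardization")
    means = sub.mean(axis=0)
    sds = sub.std(axis=0, ddof=0)
    zero = sds == 0
    if zero.any():
        logger.warning("%d constant column(s) standardized to all-zeros", int(zero.sum()))
    stats = StandardizationStats(means=means, sds=np.where(zero, 0.0, sds))
    return apply_standardization(matrix, stats), stats


def apply_standardization(matrix: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    safe_sds = np.where(stats.sds == 0, 1.0, stats.sds)
    out = (np.asarray(matrix, dtype=float) - stats.means) / safe_sds
    return np.where(stats.sds == 0, 0.0, out)


def cosine_similarity(features: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity; symmetric with unit diagonal.

    Zero-norm rows get similarity 0 to everything (never NaN) with a warning;
    their diagonal is still forced to 1.
    """
    X = np.asarray(features, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-norm row(s); their similarities set to 0", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    Xn = X / safe[:, None]
    S = Xn @ Xn.T
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


@dataclass
class SimilarityGraph:
    """Thresholded patient-similarity graph (binary, symmetric, no self-loops)."""

    patient_ids: list[str]
    similarity: np.ndarray
    adjacency: np.ndarray
    threshold: float
    provenance: str  # "BBSG" or "RBSG"

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def threshold_graph(
    similarity: np.ndarray,
    patient_ids: list[str],
    eta: float,
    provenance: str = "BBSG",
) -> SimilarityGraph:
    """Binarize similarities: edge (p, q) iff s_pq >= eta, p != q."""
    if not 0 < eta <= 1:
        raise ValueError(f"eta must be in (0, 1], got {eta}")
    if provenance not in ("BBSG", "RBSG"):
        raise ValueError(f"provenance must be BBSG or RBSG, got {provenance!r}")
    S = np.asarray(similarity, dtype=float)
    A = (S >= eta).astype(float)
    np.fill_diagonal(A, 0.0)
    A = np.maximum(A, A.T)  # symmetric by construction, but enforce
    n_edges = int(A.sum()) // 2
    n_isolated = int((A.sum(axis=1) == 0).sum())
    if n_edges == 0:
        logger.warning("similarity graph at eta=%g is edgeless", eta)
    logger.info(
        "%s graph at eta=%g: %d edges, %d isolated patients",
        provenance, eta, n_edges, n_isolated,
    )
    return SimilarityGraph(
        patient_ids=list(patient_ids),
        similarity=S,
        adjacency=A,
        threshold=eta,
        provenance=provenance,
    )


@dataclass
class GeneInteractionGraph:
    """Undirected gene graph with GCN propagation operator.

    M is the symmetrized binary adjacency (zero diagonal); M_hat = M + I;
    D_hat the self-looped degree; A_hat = D_hat^(-1/2) M_hat D_hat^(-1/2).
    Genes without interactions are isolated nodes with A_hat_ii = 1.
    """

    gene_ids: list[str]
    M: np.ndarray
    A_hat: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def M_hat(self) -> np.ndarray:
        return self.M + np.eye(self.n_genes)

    @property
    def degrees_hat(self) -> np.ndarray:
        return self.M_hat.sum(axis=1)


def build_gig(edges: InteractionEdgeList, selected_genes: list[str]) -> GeneInteractionGraph:
    """Assemble the shared gene graph over ``selected_genes``.

    Directed input edges are symmetrized and interaction types ignored; edges
    with an endpoint outside the selected set are dropped.
    """
    index = {g: i for i, g in enumerate(selected_genes)}
    n = len(selected_genes)
    M = np.zeros((n, n))
    n_dropped = 0
    for src, _typ, dst in edges.edges:
        i, j = index.get(src), index.get(dst)
        if i is None or j is None:
            n_dropped += 1
            continue
        M[i, j] = M[j, i] = 1.0
    if n_dropped:
        logger.info("dropped %d interaction(s) outside the selected gene set", n_dropped)
    M_hat = M + np.eye(n)
    d_hat = M_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d_hat)
    A_hat = M_hat * inv_sqrt[:, None] * inv_sqrt[None, :]
    return GeneInteractionGraph(gene_ids=list(selected_genes), M=M, A_hat=A_hat)
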