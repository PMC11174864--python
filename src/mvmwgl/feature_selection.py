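"""Univariate gene ranking against survival time.

Each gene is scored by its Pearson correlation rho with survival time on the
training patients, converted to an F-statistic

    F = rho^2 / (1 - rho^2) * (n - 2),

which is a strictly increasing function of |rho|, and the top-k genes by F are
selected. Selection sees training survival times only, so validation and test
labels never influence which genes enter the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SurvivalTable

logger = logging.getLogger(__name__)


@dataclass
class GeneScoreTable:
    """Per-gene correlation, F-value, rank and selection flag."""

    gene_ids: list[str]
    correlation: np.ndarray
    f_value: np.ndarray
    rank: np.ndarray  # 0 = best
    selected: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "correlation": self.correlation,
                "f_value": self.f_value,
                "rank": self.rank,
                "selected": self.selected,
            }
        )

    def selected_genes(self) -> list[str]:
        """Selected gene ids ordered by ascending rank."""
        order = np.argsort(self.rank, kind="stable")
        return [self.gene_ids[i] for i in order if self.selected[i]]


def gene_survival_correlation(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    fit_patients: np.ndarray | None = None,
) -> np.ndarray:
    """Pearson correlation of each gene's expression with survival time.

    ``fit_patients`` is a boolean mask (default: the training split). Genes
    with zero variance on the fit patients score 0 with a warning, never NaN.
    """
    surv = surv.reindex(expr.patient_ids)
    if fit_patients is None:
        fit_patients = surv.mask("train")
    fit_patients = np.asarray(fit_patients, dtype=bool)
    n = int(fit_patients.sum())
    if n < 3:
        raise ValueError(f"need at least 3 fit patients, got {n}")

    X = expr.values[fit_patients]
    t = surv.survival_time[fit_patients]

    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())

    zero_var = X.max(axis=0) == X.min(axis=0)
    if zero_var.any():
        names = [expr.gene_ids[j] for j in np.flatnonzero(zero_var)[:10]]
        logger.warning(
            "%d zero-variance gene(s) scored 0 (e.g. %s)", int(zero_var.sum()), names
        )
    if st == 0:
        logger.warning("survival has zero variance on fit patients; all correlations 0")
        return np.zeros(expr.n_genes)

    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Xc * tc[:, None]).sum(axis=0) / (sx * st)
    rho = np.where(zero_var, 0.0, rho)
    return np.clip(rho, -1.0, 1.0)


def f_value(rho: np.ndarray | float, n: int) -> np.ndarray | float:
    """F-statistic of a Pearson correlation at sample size n.

    |rho| = 1 maps to +inf (ranks first); |rho| > 1 is a hard error.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if n < 3:
        raise ValueError("n must be >= 3")
    if (np.abs(rho_arr) > 1).any():
        raise ValueError("|rho| must be <= 1")
    with np.errstate(divide="ignore"):
        out = rho_arr**2 / (1.0 - rho_arr**2) * (n - 2)
    out = np.where(np.abs(rho_arr) == 1.0, np.inf, out)
    return float(out) if np.isscalar(rho) else out


def score_genes(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    k: int | None = None,
    fit_patients: np.ndarray | None = None,
) -> GeneScoreTable:
    """Score all genes and mark the top-k (F-descending, ties by gene id)."""
    surv = surv.reindex(expr.patient_ids)
    if fit_patients is None:
        fit_patients = surv.mask("train")
    fit_patients = np.asarray(fit_patients, dtype=bool)
    rho = gene_survival_correlation(expr, surv, fit_patients)
    F = f_value(rho, int(fit_patients.sum()))

    # Descending F, deterministic tie-break by lexicographic gene id.
    order = sorted(range(expr.n_genes), key=lambda j: (-F[j], expr.gene_ids[j]))
    rank = np.empty(expr.n_genes, dtype=int)
    rank[order] = np.arange(expr.n_genes)

    if k is None:
        k = expr.n_genes
    if not 1 <= k <= expr.n_genes:
        raise ValueError(f"k must be in [1, {expr.n_genes}], got {k}")
    selected = rank < k
    return GeneScoreTable(
        gene_ids=list(expr.gene_ids),
        correlation=rho,
        f_value=F,
        rank=rank,
        selected=selected,
    )


def select_top_genes(scores: GeneScoreTable, k: int) -> list[str]:
    """The k genes with largest F, ordered by rank (ties already broken)."""
    n = len(scores.gene_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = np.argsort(scores.rank, kind="stable")
    return [scores.gene_ids[i] for i in order[:k]]
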