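"""Synthetic cohort generator.

Produces the three artifacts the pipeline consumes — an expression matrix, a
gene-interaction edge list and a survival table — with the statistical
structure the model assumes: a minority-to-majority of survival-informative
genes whose group-specific mean shifts make latent patient groups separable in
expression space, a gene-interaction graph with module (stochastic block)
structure, and survival times driven by the latent groups plus Gaussian noise.

The defaults describe a signal-dominant regime (effect size 2.0 vs expression
noise sd 0.5, informative genes in the majority among selected genes) in which
the cosine-thresholded patient-similarity graph at eta = 0.8 is informative;
see docs/methods.md for the rationale and for what this generator deliberately
does not emulate about real tumor expression data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import ExpressionMatrix, InteractionEdgeList, SurvivalTable

logger = logging.getLogger(__name__)

SPLIT_FRACTIONS = (0.6, 0.2, 0.2)  # train / validation / test


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Survival means and noise are in months; expression is on an arbitrary
    continuous scale. ``module_sizes`` partitions the genes into interaction
    modules; informative genes are concentrated in the leading modules.
    """

    n_patients: int = 300
    n_genes: int = 60
    n_informative_genes: int = 45
    n_groups: int = 4
    group_survival_means: tuple[float, ...] = (10.0, 30.0, 70.0, 120.0)
    survival_noise_sd: float = 5.0
    module_sizes: tuple[int, ...] = (20, 20, 20)
    p_within: float = 0.3
    p_between: float = 0.02
    effect_size: float = 2.0
    expression_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("cohort must have at least one patient and one gene")
        if not 0 <= self.n_informative_genes <= self.n_genes:
            raise ValueError("n_informative_genes must be in [0, n_genes]")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if len(self.group_survival_means) != self.n_groups:
            raise ValueError("need one survival mean per group")
        if sum(self.module_sizes) != self.n_genes:
            raise ValueError("module_sizes must sum to n_genes")
        if not (0 <= self.p_between <= self.p_within <= 1):
            raise ValueError("require 0 <= p_between <= p_within <= 1")
        if self.survival_noise_sd <= 0 or self.expression_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    group_labels: np.ndarray
    informative_genes: list[str]
    spec: CohortSpec = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "group_labels": self.group_labels.tolist(),
            "informative_genes": list(self.informative_genes),
        }


def _stratified_split(groups: np.ndarray, rng: np.random.Generator) -> list[str]:
    """60/20/20 split per latent group, within one patient of exact."""
    split = np.empty(len(groups), dtype=object)
    names = ("train", "validation", "test")
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        rng.shuffle(idx)
        n = len(idx)
        counts = [int(np.floor(f * n)) for f in SPLIT_FRACTIONS]
        remainders = [f * n - c for f, c in zip(SPLIT_FRACTIONS, counts)]
        for _ in range(n - sum(counts)):
            j = int(np.argmax(remainders))
            counts[j] += 1
            remainders[j] = -1.0
        pos = 0
        for name, c in zip(names, counts):
            split[idx[pos:pos + c]] = name
            pos += c
    return [str(s) for s in split]


def _group_sign_pattern(
    gene_modules: np.ndarray,
    informative_idx: np.ndarray,
    n_groups: int,
    group_survival_means: tuple[float, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-(informative gene, group) offset signs in {-1, +1}.

    Groups are ordered by survival mean and each interaction module is
    assigned one of the n_groups - 1 contiguous split points along that
    order (round-robin over modules, times a random per-module sign flip);
    every informative gene inherits its module's pattern. Consequences the
    downstream stages rely on:

    * every informative gene's mean tracks a monotone contrast of survival,
      so it is genuinely survival-informative;
    * genes in the same module are co-regulated (identical signal plus
      independent noise), so averaging over gene-graph neighborhoods
      denoises rather than cancels — the co-expression structure real
      interaction networks exhibit;
    * with modules covering all split points the groups carry pairwise
      distinct thermometer codes, i.e. they are separable in expression
      space.
    """
    n_informative = len(informative_idx)
    if n_informative == 0 or n_groups < 2:
        return np.zeros((n_informative, max(n_groups, 1)))
    order = np.argsort(group_survival_means, kind="stable")
    rank = np.empty(n_groups, dtype=int)
    rank[order] = np.arange(n_groups)
    n_modules = int(gene_modules.max()) + 1
    module_split = 1 + (np.arange(n_modules) % (n_groups - 1))
    module_flip = rng.choice([-1.0, 1.0], size=n_modules)
    splits = module_split[gene_modules[informative_idx]]
    flips = module_flip[gene_modules[informative_idx]]
    signs = np.where(rank[None, :] >= splits[:, None], 1.0, -1.0)
    return signs * flips[:, None]


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, InteractionEdgeList, SurvivalTable, GroundTruth]:
    """Generate one cohort, fully reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    patient_ids = [f"P{i:04d}" for i in range(spec.n_patients)]
    gene_ids = [f"G{j:04d}" for j in range(spec.n_genes)]

    groups = rng.integers(spec.n_groups, size=spec.n_patients)

    # Informative genes fill the leading interaction modules.
    informative_idx = np.arange(spec.n_informative_genes)
    informative_genes = [gene_ids[j] for j in informative_idx]

    base_mean = rng.normal(8.0, 2.0, size=spec.n_genes)
    values = rng.normal(0.0, spec.expression_noise_sd, size=(spec.n_patients, spec.n_genes))
    values += base_mean[None, :]
    gene_modules = np.repeat(np.arange(len(spec.module_sizes)), spec.module_sizes)
    if spec.n_informative_genes and spec.effect_size > 0 and spec.n_groups > 1:
        signs = _group_sign_pattern(
            gene_modules, informative_idx, spec.n_groups, spec.group_survival_means, rng
        )
        values[:, informative_idx] += spec.effect_size * signs[:, groups].T

    # Gene-interaction graph: stochastic block model over the modules.
    n_mod = len(spec.module_sizes)
    p_matrix = np.full((n_mod, n_mod), spec.p_between)
    np.fill_diagonal(p_matrix, spec.p_within)
    sbm_seed = int(rng.integers(2**31))
    g = nx.stochastic_block_model(list(spec.module_sizes), p_matrix.tolist(), seed=sbm_seed)
    edges = [(gene_ids[u], "interacts-with", gene_ids[v]) for u, v in sorted(g.edges())]
    edge_list = InteractionEdgeList(edges=edges)

    survival = np.array([spec.group_survival_means[g] for g in groups])
    survival += rng.normal(0.0, spec.survival_noise_sd, size=spec.n_patients)
    n_clipped = int((survival < 0).sum())
    if n_clipped:
        logger.warning("clipped %d negative survival times to 0", n_clipped)
        survival = np.clip(survival, 0.0, None)

    split = _stratified_split(groups, rng)

    expr = ExpressionMatrix(patient_ids=patient_ids, gene_ids=gene_ids, values=values)
    surv = SurvivalTable(patient_ids=patient_ids, survival_time=survival, split=split)
    truth = GroundTruth(group_labels=groups, informative_genes=informative_genes, spec=spec)
    return expr, edge_list, surv, truth


def _two_cliques() -> tuple[ExpressionMatrix, InteractionEdgeList, SurvivalTable, GroundTruth]:
    """10 patients in 2 antipodal expression groups.

    After per-gene standardization, within-group cosine similarity is ~ +1 and
    between-group ~ -1, so thresholding at eta = 0.8 yields exactly the two
    planted 5-cliques as connected components.
    """
    rng = np.random.default_rng(20240521)
    n_per, n_genes = 5, 12
    pattern = np.concatenate([np.ones(n_genes // 2), -np.ones(n_genes // 2)])
    groups = np.repeat([0, 1], n_per)
    values = np.where(groups[:, None] == 0, pattern[None, :], -pattern[None, :])
    values = 8.0 + 2.0 * values + rng.normal(0.0, 0.05, size=(2 * n_per, n_genes))
    patient_ids = [f"P{i:04d}" for i in range(2 * n_per)]
    gene_ids = [f"G{j:04d}" for j in range(n_genes)]
    half = n_genes // 2
    edges = [
        (gene_ids[j], "interacts-with", gene_ids[j + 1])
        for j in range(n_genes - 1)
        if j + 1 != half  # two gene chains, one per module
    ]
    survival = np.where(groups == 0, 10.0, 80.0) + rng.normal(0.0, 1.0, size=2 * n_per)
    survival = np.clip(survival, 0.0, None)
    split = _stratified_split(groups, rng)
    return (
        ExpressionMatrix(patient_ids=patient_ids, gene_ids=gene_ids, values=values),
        InteractionEdgeList(edges=edges),
        SurvivalTable(patient_ids=patient_ids, survival_time=survival, split=split),
        GroundTruth(group_labels=groups, informative_genes=list(gene_ids)),
    )


def _four_groups_small() -> tuple[ExpressionMatrix, InteractionEdgeList, SurvivalTable, GroundTruth]:
    spec = CohortSpec(
        n_patients=80,
        n_genes=24,
        n_informative_genes=24,
        n_groups=4,
        group_survival_means=(10.0, 30.0, 70.0, 120.0),
        survival_noise_sd=5.0,
        module_sizes=(8, 8, 8),
        p_within=0.4,
        p_between=0.05,
        effect_size=2.0,
        expression_noise_sd=0.5,
        seed=20240404,
    )
    return generate_cohort(spec)


FIXTURES = {
    "two-cliques": _two_cliques,
    "four-groups-small": _four_groups_small,
}


def generate_fixture(name: str):
    """Return a deterministic tiny cohort from the fixture registry."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}") from None
    return factory()
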