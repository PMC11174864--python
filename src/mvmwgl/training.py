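"""Training loops and end-to-end orchestration.

Two stages share one pipeline:

1. Self-supervised graph-level classification on the gene-interaction graph
   (GIG): every patient is a copy of the shared gene graph whose node inputs
   are that patient's standardized expression levels; the model (2
   message-passing layers, global mean pooling, linear-softmax head) is
   trained with cross-entropy against spectral pseudo-labels for a fixed
   number of epochs. The per-patient concatenation of final-layer gene
   representations becomes the learned patient feature H.

2. Semi-supervised (transductive) node regression on the rebuilt patient
   similarity graph (RBSG): all patients are nodes, aggregation draws on
   train, validation and test neighbors, but the MSE loss uses training
   labels only. The returned model is the epoch with minimum validation loss.

Both stages use Adam and add an explicit squared-L2 penalty on all trainable
parameters to the loss. Single-view baselines (GIG-GCN/GAT graph-level
regression, BSG-GCN/GAT node regression on the raw-expression graph) reuse
the same machinery without the pseudo-label stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .autodiff import Adam, Tensor, constant
from .evaluation import evaluate_predictions
from .feature_selection import score_genes
from .gnn import (
    GATLayer,
    LinearSoftmaxHead,
    MLPHead,
    Module,
    global_mean_pool,
    make_layer,
)
from .graph_construction import (
    GeneInteractionGraph,
    SimilarityGraph,
    build_gig,
    cosine_similarity,
    standardize,
    threshold_graph,
)
from .io_formats import ExpressionMatrix, InteractionEdgeList, SurvivalTable
from .spectral import PseudoLabeling, pseudo_label_graph

logger = logging.getLogger(__name__)

MODEL_TAGS = {
    ("GCN", "GCN"): "MVMWGL-GCNCN",  # M1
    ("GAT", "GCN"): "MVMWGL-GATCN",  # M2
    ("GCN", "GAT"): "MVMWGL-GCNAT",  # M3
    ("GAT", "GAT"): "MVMWGL-GATAT",  # M4
}

BASELINE_KINDS = ("GIG-GCN", "GIG-GAT", "BSG-GCN", "BSG-GAT")


@dataclass
class TrainingConfig:
    """Hyperparameters of both stages.

    Defaults follow the reference configuration: 2 layers, 40 self-supervised
    epochs, learning rate 0.001, gene-representation size 4, 6 pseudo-labels,
    2000 selected genes, similarity threshold 0.8. The semi-supervised epoch
    count is chosen by minimum validation loss within ``semi_epochs_max``
    under ``patience``.
    """

    learning_rate: float = 0.001
    n_layers: int = 2
    ssl_epochs: int = 40
    ssl_batch_size: int = 32
    semi_epochs_max: int = 2000
    patience: int = 50
    lambda_gig: float = 1e-4
    lambda_bsg: float = 1e-4
    repr_dim: int = 4
    hidden_dim: int = 64
    mlp_hidden: int = 32
    n_clusters: int = 6
    k_genes: int = 2000
    eta: float = 0.8
    layer_type_gig: str = "GCN"
    layer_type_bsg: str = "GCN"
    cluster_method: str = "cluster-qr"
    ssl_plateau: bool = False  # stop SSL early once validation loss stabilizes
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.n_layers < 1 or self.ssl_epochs < 0:
            raise ValueError("invalid learning_rate / n_layers / ssl_epochs")
        if self.ssl_batch_size < 1 or self.semi_epochs_max < 1 or self.patience < 1:
            raise ValueError("invalid batch size / epoch limit / patience")
        if self.lambda_gig < 0 or self.lambda_bsg < 0:
            raise ValueError("regularization strengths must be >= 0")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        for lt in (self.layer_type_gig, self.layer_type_bsg):
            if lt not in ("GCN", "GAT"):
                raise ValueError(f"layer type must be GCN or GAT, got {lt!r}")

    @property
    def model_tag(self) -> str:
        return MODEL_TAGS[(self.layer_type_gig, self.layer_type_bsg)]


def _l2_penalty(params: list[Tensor]) -> Tensor:
    total = None
    for p in params:
        term = (p ** 2.0).sum()
        total = term if total is None else total + term
    return total if total is not None else constant(0.0)


def ssl_loss(
    probabilities,
    labels: np.ndarray,
    params: list[Tensor] | None = None,
    lambda_gig: float = 0.0,
):
    """Batch cross-entropy against pseudo-labels plus L2 regularization.

    Accepts either a Tensor (training path, returns a Tensor) or a plain
    array of class probabilities (returns a float). Exact zeros at the target
    class are clamped at 1e-12 with a warning.
    """
    is_tensor = isinstance(probabilities, Tensor)
    probs = probabilities if is_tensor else constant(np.asarray(probabilities, dtype=float))
    labels = np.asarray(labels, dtype=int)
    picked = probs.gather(labels)
    if (picked.data <= 0).any():
        logger.warning("zero predicted probability at a target class; clamping at 1e-12")
    loss = -(picked.clip_min(1e-12).log().mean())
    if params and lambda_gig > 0:
        loss = loss + lambda_gig * _l2_penalty(params)
    return loss if is_tensor else float(loss.data)


def semi_loss(
    predictions,
    targets: np.ndarray,
    params: list[Tensor] | None = None,
    lambda_bsg: float = 0.0,
):
    """Mean squared error over labeled patients plus L2 regularization."""
    is_tensor = isinstance(predictions, Tensor)
    preds = predictions if is_tensor else constant(np.asarray(predictions, dtype=float))
    residual = preds - np.asarray(targets, dtype=float)
    loss = (residual ** 2.0).mean()
    if params and lambda_bsg > 0:
        loss = loss + lambda_bsg * _l2_penalty(params)
    return loss if is_tensor else float(loss.data)


class GIGModel(Module):
    """Stacked message-passing layers + pooling + pseudo-label classifier."""

    def __init__(self, layer_type: str, n_layers: int, repr_dim: int,
                 n_clusters: int, rng: np.random.Generator):
        dims = [1] + [repr_dim] * n_layers
        self.layers = [make_layer(layer_type, a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.head = LinearSoftmaxHead(repr_dim, n_clusters, rng)
        self.repr_dim = repr_dim

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        out.extend(self.head.parameters())
        return out

    def node_representations(self, X: np.ndarray, gig: GeneInteractionGraph) -> Tensor:
        """Final-layer gene representations for a batch (b, n_genes)."""
        H = constant(np.asarray(X, dtype=float)[..., None])  # (b, n, 1)
        for layer in self.layers:
            operand = gig.A_hat if not isinstance(layer, GATLayer) else gig.M_hat
            H = layer.forward(H, operand)
        return H

    def forward(self, X: np.ndarray, gig: GeneInteractionGraph) -> tuple[Tensor, Tensor]:
        """Returns (node representations, class probabilities)."""
        H = self.node_representations(X, gig)
        probs = self.head.forward(global_mean_pool(H))
        return H, probs


class BSGModel(Module):
    """Stacked message-passing layers + MLP survival head, node level."""

    def __init__(self, layer_type: str, n_layers: int, in_dim: int, hidden_dim: int,
                 mlp_hidden: int, rng: np.random.Generator):
        dims = [in_dim] + [hidden_dim] * n_layers
        self.layers = [make_layer(layer_type, a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.head = MLPHead([hidden_dim, mlp_hidden, 1], rng)

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        out.extend(self.head.parameters())
        return out

    def forward(self, X: np.ndarray, graph: SimilarityGraph) -> tuple[Tensor, Tensor]:
        """Returns (pre-MLP embeddings z, scalar predictions)."""
        n = graph.n_patients
        mask = graph.adjacency + np.eye(n)
        A_hat = _gcn_operator(graph.adjacency)
        Z = constant(np.asarray(X, dtype=float))
        for layer in self.layers:
            operand = A_hat if not isinstance(layer, GATLayer) else mask
            Z = layer.forward(Z, operand)
        preds = self.head.forward(Z).reshape(n)
        return Z, preds


def _gcn_operator(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization of a zero-diagonal adjacency."""
    n = adjacency.shape[0]
    A_hat = adjacency + np.eye(n)
    d = A_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class GIGTrainResult:
    model: GIGModel
    H: np.ndarray  # (n_patients, k_genes * repr_dim)
    train_loss: list[float]
    val_loss: list[float]
    epochs_run: int


def train_gig(
    expr_values: np.ndarray,
    gig: GeneInteractionGraph,
    labels: PseudoLabeling,
    config: TrainingConfig,
    train_mask: np.ndarray,
    val_mask: np.ndarray | None = None,
) -> GIGTrainResult:
    """Self-supervised stage: classify pseudo-labels from patient gene graphs.

    ``expr_values`` is the standardized (patients x selected genes) matrix.
    After training, H (concatenated final-layer gene representations) is
    computed for every patient with the trained weights.
    """
    config.validate()
    X = np.asarray(expr_values, dtype=float)
    n_patients = X.shape[0]
    if X.shape[1] != gig.n_genes:
        raise ValueError("expression columns do not match the gene graph")
    train_mask = np.asarray(train_mask, dtype=bool)
    rng = np.random.default_rng(config.seed)
    model = GIGModel(config.layer_type_gig, config.n_layers, config.repr_dim,
                     labels.n_clusters, rng)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)

    train_idx = np.flatnonzero(train_mask)
    val_idx = np.flatnonzero(val_mask) if val_mask is not None else np.array([], dtype=int)
    y = np.asarray(labels.labels, dtype=int)

    train_hist: list[float] = []
    val_hist: list[float] = []
    epochs_run = 0
    for epoch in range(config.ssl_epochs):
        order = rng.permutation(train_idx)
        batch_losses = []
        for start in range(0, len(order), config.ssl_batch_size):
            batch = order[start:start + config.ssl_batch_size]
            _, probs = model.forward(X[batch], gig)
            loss = ssl_loss(probs, y[batch], model.parameters(), config.lambda_gig)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"NaN self-supervised loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            batch_losses.append(float(loss.data))
        train_hist.append(float(np.mean(batch_losses)) if batch_losses else np.nan)
        if len(val_idx):
            _, vprobs = model.forward(X[val_idx], gig)
            val_hist.append(ssl_loss(vprobs.data, y[val_idx]))
        epochs_run = epoch + 1
        if config.ssl_plateau and len(val_hist) >= 6:
            recent = val_hist[-6:]
            rel = abs(recent[-1] - recent[0]) / max(abs(recent[0]), 1e-12)
            if rel < 1e-3:
                logger.info("SSL validation loss plateaued at epoch %d", epoch)
                break

    # Concatenated final-layer gene representations for all patients.
    chunks = []
    for start in range(0, n_patients, 256):
        H_nodes = model.node_representations(X[start:start + 256], gig)
        b = H_nodes.data.shape[0]
        chunks.append(H_nodes.data.reshape(b, -1))
    H = np.vstack(chunks) if chunks else np.zeros((0, gig.n_genes * config.repr_dim))
    return GIGTrainResult(model=model, H=H, train_loss=train_hist,
                          val_loss=val_hist, epochs_run=epochs_run)


@dataclass
class BSGTrainResult:
    model: BSGModel
    embeddings: np.ndarray  # pre-MLP z at the selected epoch
    predictions: np.ndarray  # all patients, months
    train_loss: list[float]
    val_loss: list[float]
    selected_epoch: int


def train_bsg(
    features: np.ndarray,
    rbsg: SimilarityGraph,
    surv: SurvivalTable,
    config: TrainingConfig,
    layer_type: str | None = None,
) -> BSGTrainResult:
    """Transductive node regression with validation-based epoch selection.

    The whole graph (train + validation + test nodes) participates in
    aggregation every epoch; the loss is computed on training nodes only and
    the model state at the epoch of minimum validation loss is returned.
    """
    config.validate()
    X = np.asarray(features, dtype=float)
    surv = surv.reindex(rbsg.patient_ids)
    train_mask = surv.mask("train")
    val_mask = surv.mask("validation")
    if not train_mask.any():
        raise ValueError("empty training mask")
    t = surv.survival_time
    train_idx = np.flatnonzero(train_mask)
    val_idx = np.flatnonzero(val_mask)

    rng = np.random.default_rng(config.seed + 1)
    model = BSGModel(layer_type or config.layer_type_bsg, config.n_layers,
                     X.shape[1], config.hidden_dim, config.mlp_hidden, rng)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)

    train_hist: list[float] = []
    val_hist: list[float] = []
    best_val = np.inf
    best_state = model.state()
    best_epoch = 0
    for epoch in range(config.semi_epochs_max):
        _, preds = model.forward(X, rbsg)
        loss = semi_loss(preds.take_rows(train_idx), t[train_idx],
                         model.parameters(), config.lambda_bsg)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"NaN semi-supervised loss at epoch {epoch}")
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        train_hist.append(float(loss.data))
        # Validation loss from detached predictions: no gradient ever flows
        # through validation or test labels.
        if len(val_idx):
            val = semi_loss(preds.data[val_idx], t[val_idx])
        else:
            val = float(loss.data)
        val_hist.append(val)
        if val < best_val:
            best_val = val
            best_state = model.state()
            best_epoch = epoch
        if epoch - best_epoch >= config.patience:
            break

    model.load_state(best_state)
    Z, preds = model.forward(X, rbsg)
    return BSGTrainResult(
        model=model,
        embeddings=Z.data.copy(),
        predictions=preds.data.copy(),
        train_loss=train_hist,
        val_loss=val_hist,
        selected_epoch=best_epoch,
    )


@dataclass
class MVMWGLResult:
    """Everything the end-to-end pipeline produced."""

    config: TrainingConfig
    selected_genes: list[str]
    bbsg: SimilarityGraph
    pseudo_labels: PseudoLabeling
    gig_result: GIGTrainResult
    rbsg: SimilarityGraph
    bsg_result: BSGTrainResult
    predictions: np.ndarray  # all patients, pipeline order
    patient_ids: list[str]
    report: dict
    stage_seconds: dict = field(default_factory=dict)


def _prepare_inputs(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    config: TrainingConfig,
) -> tuple[ExpressionMatrix, SurvivalTable, np.ndarray, list[str]]:
    """Feature selection + train-fit standardization of selected genes."""
    surv = surv.reindex(expr.patient_ids)
    train_mask = surv.mask("train")
    scores = score_genes(expr, surv, k=config.k_genes, fit_patients=train_mask)
    selected = scores.selected_genes()
    expr_sel = expr.subset_genes(selected)
    X_std, _ = standardize(expr_sel.values, fit_rows=train_mask)
    return expr_sel, surv, X_std, selected


def run_mvmwgl(
    expr: ExpressionMatrix,
    interactions: InteractionEdgeList,
    surv: SurvivalTable,
    config: TrainingConfig,
    out_dir: str | Path | None = None,
) -> MVMWGLResult:
    """The full pipeline: selection -> BBSG -> pseudo-labels -> self-supervised
    gene-graph stage -> RBSG -> transductive regression -> evaluation."""
    config.validate()
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter()
        logger.info("stage %s", name)

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    stage("feature_selection")
    expr_sel, surv, X_std, selected = _prepare_inputs(expr, surv, config)
    done("feature_selection")

    stage("bbsg")
    bbsg = threshold_graph(cosine_similarity(X_std), expr.patient_ids, config.eta, "BBSG")
    done("bbsg")

    stage("pseudo_labels")
    labels = pseudo_label_graph(bbsg, config.n_clusters, config.cluster_method, config.seed)
    done("pseudo_labels")

    stage("gig_training")
    gig = build_gig(interactions, selected)
    gig_result = train_gig(X_std, gig, labels, config,
                           train_mask=surv.mask("train"), val_mask=surv.mask("validation"))
    done("gig_training")

    stage("rbsg")
    H_std, _ = standardize(gig_result.H, fit_rows=surv.mask("train"))
    rbsg = threshold_graph(cosine_similarity(H_std), expr.patient_ids, config.eta, "RBSG")
    done("rbsg")

    stage("bsg_training")
    bsg_result = train_bsg(H_std, rbsg, surv, config)
    done("bsg_training")

    stage("evaluation")
    test_mask = surv.mask("test")
    report = evaluate_predictions(
        [p for p, m in zip(expr.patient_ids, test_mask) if m],
        surv.survival_time[test_mask],
        bsg_result.predictions[test_mask],
        model_tag=config.model_tag,
        metadata={
            "seed": config.seed,
            "eta": config.eta,
            "k_genes": len(selected),
            "n_clusters": config.n_clusters,
            "selected_epoch": bsg_result.selected_epoch,
        },
    )
    done("evaluation")

    result = MVMWGLResult(
        config=config,
        selected_genes=selected,
        bbsg=bbsg,
        pseudo_labels=labels,
        gig_result=gig_result,
        rbsg=rbsg,
        bsg_result=bsg_result,
        predictions=bsg_result.predictions,
        patient_ids=list(expr.patient_ids),
        report=report,
        stage_seconds=timings,
    )
    if out_dir is not None:
        _persist(result, surv, Path(out_dir))
    return result


def _persist(result: MVMWGLResult, surv: SurvivalTable, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io_formats.write_pseudo_labels(
        result.pseudo_labels.patient_ids, result.pseudo_labels.labels,
        out_dir / "pseudo_labels.tsv",
    )
    io_formats.write_representations(result.patient_ids, result.gig_result.H,
                                     out_dir / "gene_representations.tsv")
    io_formats.write_representations(result.patient_ids, result.bsg_result.embeddings,
                                     out_dir / "patient_embeddings.tsv")
    io_formats.write_representations(
        result.patient_ids, result.predictions[:, None], out_dir / "predictions.tsv"
    )
    io_formats.write_report(result.report, out_dir / "report.json")
    io_formats.write_report(
        {
            "ssl_train_loss": result.gig_result.train_loss,
            "ssl_val_loss": result.gig_result.val_loss,
            "semi_train_loss": result.bsg_result.train_loss,
            "semi_val_loss": result.bsg_result.val_loss,
            "selected_epoch": result.bsg_result.selected_epoch,
            "stage_seconds": result.stage_seconds,
        },
        out_dir / "training_log.json",
    )


@dataclass
class BaselineResult:
    kind: str
    predictions: np.ndarray
    patient_ids: list[str]
    report: dict
    train_loss: list[float]
    val_loss: list[float]
    selected_epoch: int


def run_baseline(
    kind: str,
    expr: ExpressionMatrix,
    interactions: InteractionEdgeList,
    surv: SurvivalTable,
    config: TrainingConfig,
) -> BaselineResult:
    """Single-view baselines.

    GIG-* : graph-level regression on the gene-interaction graph (pooling +
    MLP head, MSE on survival directly); the patient-similarity graph is
    never built. BSG-* : node regression on the raw-expression similarity
    graph; the gene-interaction graph is never built. No pseudo-label stage
    in either.
    """
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline {kind!r}; choose from {BASELINE_KINDS}")
    config.validate()
    expr_sel, surv, X_std, selected = _prepare_inputs(expr, surv, config)
    layer_type = kind.split("-")[1]

    if kind.startswith("BSG"):
        bbsg = threshold_graph(cosine_similarity(X_std), expr.patient_ids, config.eta, "BBSG")
        bsg_result = train_bsg(X_std, bbsg, surv, config, layer_type=layer_type)
        predictions = bsg_result.predictions
        train_loss, val_loss = bsg_result.train_loss, bsg_result.val_loss
        selected_epoch = bsg_result.selected_epoch
    else:
        gig = build_gig(interactions, selected)
        predictions, train_loss, val_loss, selected_epoch = _train_gig_regression(
            X_std, gig, surv, config, layer_type
        )

    test_mask = surv.mask("test")
    report = evaluate_predictions(
        [p for p, m in zip(expr.patient_ids, test_mask) if m],
        surv.survival_time[test_mask],
        predictions[test_mask],
        model_tag=kind,
        metadata={"seed": config.seed, "eta": config.eta, "k_genes": len(selected),
                  "selected_epoch": selected_epoch},
    )
    return BaselineResult(kind=kind, predictions=predictions,
                          patient_ids=list(expr.patient_ids), report=report,
                          train_loss=train_loss, val_loss=val_loss,
                          selected_epoch=selected_epoch)


class _GIGRegressor(Module):
    """Gene-graph layers + pooling + MLP head for graph-level regression."""

    def __init__(self, layer_type: str, config: TrainingConfig, rng: np.random.Generator):
        dims = [1] + [config.repr_dim] * config.n_layers
        self.layers = [make_layer(layer_type, a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.head = MLPHead([config.repr_dim, config.mlp_hidden, 1], rng)

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        out.extend(self.head.parameters())
        return out

    def forward(self, X: np.ndarray, gig: GeneInteractionGraph) -> Tensor:
        H = constant(np.asarray(X, dtype=float)[..., None])
        for layer in self.layers:
            operand = gig.A_hat if not isinstance(layer, GATLayer) else gig.M_hat
            H = layer.forward(H, operand)
        return self.head.forward(global_mean_pool(H)).reshape(X.shape[0])


def _train_gig_regression(
    X: np.ndarray,
    gig: GeneInteractionGraph,
    surv: SurvivalTable,
    config: TrainingConfig,
    layer_type: str,
) -> tuple[np.ndarray, list[float], list[float], int]:
    rng = np.random.default_rng(config.seed + 2)
    model = _GIGRegressor(layer_type, config, rng)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    t = surv.survival_time
    train_idx = np.flatnonzero(surv.mask("train"))
    val_idx = np.flatnonzero(surv.mask("validation"))

    train_hist: list[float] = []
    val_hist: list[float] = []
    best_val, best_state, best_epoch = np.inf, model.state(), 0
    for epoch in range(config.semi_epochs_max):
        order = rng.permutation(train_idx)
        batch_losses = []
        for start in range(0, len(order), config.ssl_batch_size):
            batch = order[start:start + config.ssl_batch_size]
            preds = model.forward(X[batch], gig)
            loss = semi_loss(preds, t[batch], model.parameters(), config.lambda_bsg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"NaN baseline loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            batch_losses.append(float(loss.data))
        train_hist.append(float(np.mean(batch_losses)))
        if len(val_idx):
            vpred = model.forward(X[val_idx], gig)
            val = semi_loss(vpred.data, t[val_idx])
        else:
            val = train_hist[-1]
        val_hist.append(val)
        if val < best_val:
            best_val, best_state, best_epoch = val, model.state(), epoch
        if epoch - best_epoch >= config.patience:
            break

    model.load_state(best_state)
    chunks = [model.forward(X[s:s + 256], gig).data for s in range(0, X.shape[0], 256)]
    predictions = np.concatenate(chunks)
    return predictions, train_hist, val_hist, best_epoch


def mean_predictor(surv: SurvivalTable) -> np.ndarray:
    """Predict the training-set mean survival for every patient."""
    train = surv.mask("train")
    if not train.any():
        raise ValueError("empty training split")
    return np.full(len(surv.patient_ids), surv.survival_time[train].mean())
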