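import dataclasses
import hashlib

import numpy as np
import pytest

from mvmwgl.autodiff import Adam
from mvmwgl.graph_construction import (
    build_gig,
    cosine_similarity,
    standardize,
    threshold_graph,
)
from mvmwgl.io_formats import InteractionEdgeList, SurvivalTable
from mvmwgl.spectral import PseudoLabeling
from mvmwgl.training import (
    BSGModel,
    TrainingConfig,
    mean_predictor,
    run_baseline,
    run_mvmwgl,
    semi_loss,
    ssl_loss,
    train_bsg,
    train_gig,
)


def small_config(**overrides):
    base = TrainingConfig(k_genes=21, n_clusters=4, seed=0,
                          semi_epochs_max=200, patience=30)
    return dataclasses.replace(base, **overrides)


class TestLosses:
    def test_perfect_one_hot_zero_loss(self):
        probs = np.eye(4)[np.array([0, 1, 2, 3])]
        assert ssl_loss(probs, np.arange(4)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_probabilities_log_k(self):
        probs = np.full((5, 6), 1 / 6)
        assert ssl_loss(probs, np.zeros(5, dtype=int)) == pytest.approx(np.log(6))

    def test_regularizer_vanishes_with_zero_parameters(self, rng):
        from mvmwgl.autodiff import parameter

        probs = np.full((3, 2), 0.5)
        zero_params = [parameter(np.zeros((2, 2)))]
        with_reg = ssl_loss(probs, np.zeros(3, dtype=int))
        # plain-array path ignores params; Tensor path adds the penalty
        from mvmwgl.autodiff import constant

        t = ssl_loss(constant(probs), np.zeros(3, dtype=int), zero_params, 0.5)
        assert float(t.data) == pytest.approx(with_reg)

    def test_semi_loss_hand_value(self):
        assert semi_loss(np.array([12.0, 16.0]), np.array([10.0, 20.0])) == pytest.approx(10.0)

    def test_semi_loss_perfect_zero(self):
        t = np.array([5.0, 7.0])
        assert semi_loss(t, t) == 0.0

    def test_semi_loss_quadratic_scaling(self):
        t = np.array([10.0, 20.0])
        base = semi_loss(np.array([12.0, 16.0]), t)
        doubled = semi_loss(np.array([14.0, 12.0]), t)  # residuals (4, -8)
        assert doubled == pytest.approx(4 * base)


def prepare_gig_stage(cohort, config):
    expr, interactions, surv, truth = cohort
    surv = surv.reindex(expr.patient_ids)
    from mvmwgl.feature_selection import score_genes

    selected = score_genes(expr, surv, k=config.k_genes).selected_genes()
    X_std, _ = standardize(expr.subset_genes(selected).values, fit_rows=surv.mask("train"))
    gig = build_gig(interactions, selected)
    labels = PseudoLabeling(
        patient_ids=list(expr.patient_ids),
        labels=truth.group_labels.astype(int),
        n_clusters=4,
        method="cluster-qr",
        seed=0,
    )
    return X_std, gig, labels, surv


class TestTrainGIG:
    def test_loss_decreases_over_training(self, small_cohort):
        decreased = 0
        for seed in range(3):
            config = small_config(seed=seed)
            X, gig, labels, surv = prepare_gig_stage(small_cohort, config)
            res = train_gig(X, gig, labels, config,
                            train_mask=surv.mask("train"), val_mask=surv.mask("validation"))
            decreased += res.train_loss[-1] < res.train_loss[0]
        assert decreased >= 2

    def test_zero_epochs_is_deterministic_initialization(self, small_cohort):
        config = small_config(ssl_epochs=0)
        X, gig, labels, surv = prepare_gig_stage(small_cohort, config)
        a = train_gig(X, gig, labels, config, train_mask=surv.mask("train"))
        b = train_gig(X, gig, labels, config, train_mask=surv.mask("train"))
        np.testing.assert_array_equal(a.H, b.H)
        assert a.train_loss == []

    def test_output_shape_contract(self, small_cohort):
        config = small_config(ssl_epochs=2)
        X, gig, labels, surv = prepare_gig_stage(small_cohort, config)
        res = train_gig(X, gig, labels, config, train_mask=surv.mask("train"))
        assert res.H.shape == (X.shape[0], config.k_genes * config.repr_dim)

    def test_gat_variant_runs(self, small_cohort):
        config = small_config(ssl_epochs=2, layer_type_gig="GAT")
        X, gig, labels, surv = prepare_gig_stage(small_cohort, config)
        res = train_gig(X, gig, labels, config, train_mask=surv.mask("train"))
        assert np.isfinite(res.H).all()


class TestTrainBSG:
    def build_inputs(self, small_cohort, config):
        expr, _, surv, _ = small_cohort
        surv = surv.reindex(expr.patient_ids)
        X, _ = standardize(expr.values, fit_rows=surv.mask("train"))
        graph = threshold_graph(cosine_similarity(X), expr.patient_ids, config.eta, "RBSG")
        return X, graph, surv

    def test_beats_mean_predictor(self, small_cohort):
        wins = 0
        for seed in range(3):
            config = small_config(seed=seed)
            X, graph, surv = self.build_inputs(small_cohort, config)
            res = train_bsg(X, graph, surv, config)
            test = surv.mask("test")
            model_mae = np.abs(res.predictions[test] - surv.survival_time[test]).mean()
            mean_mae = np.abs(mean_predictor(surv)[test] - surv.survival_time[test]).mean()
            wins += model_mae < mean_mae
        assert wins >= 2

    def test_selected_epoch_is_validation_argmin(self, small_cohort):
        config = small_config()
        X, graph, surv = self.build_inputs(small_cohort, config)
        res = train_bsg(X, graph, surv, config)
        assert res.selected_epoch == int(np.argmin(res.val_loss))

    def test_same_seed_identical_results(self, small_cohort):
        config = small_config()
        X, graph, surv = self.build_inputs(small_cohort, config)
        a = train_bsg(X, graph, surv, config)
        b = train_bsg(X, graph, surv, config)
        assert a.train_loss == b.train_loss
        assert a.selected_epoch == b.selected_epoch
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_empty_training_mask_rejected(self, small_cohort):
        config = small_config()
        X, graph, surv = self.build_inputs(small_cohort, config)
        bad = SurvivalTable(surv.patient_ids, surv.survival_time,
                            ["test"] * len(surv.patient_ids))
        with pytest.raises(ValueError, match="empty training mask"):
            train_bsg(X, graph, bad, config)

    def test_training_gradients_blind_to_heldout_labels(self, small_cohort):
        """Permuting validation/test survival labels leaves every training
        gradient untouched (single-step gradient hash comparison)."""
        config = small_config()
        X, graph, surv = self.build_inputs(small_cohort, config)

        def first_step_grad_hash(table):
            rng = np.random.default_rng(123)
            model = BSGModel("GCN", config.n_layers, X.shape[1],
                             config.hidden_dim, config.mlp_hidden, rng)
            train_idx = np.flatnonzero(table.mask("train"))
            _, preds = model.forward(X, graph)
            loss = semi_loss(preds.take_rows(train_idx), table.survival_time[train_idx],
                             model.parameters(), config.lambda_bsg)
            loss.backward()
            h = hashlib.sha256()
            for p in model.parameters():
                h.update(np.ascontiguousarray(p.grad).tobytes())
            return h.hexdigest()

        heldout = ~surv.mask("train")
        t_perm = surv.survival_time.copy()
        idx = np.flatnonzero(heldout)
        t_perm[idx] = t_perm[np.roll(idx, 1)]
        permuted = SurvivalTable(surv.patient_ids, t_perm, surv.split)
        assert first_step_grad_hash(surv) == first_step_grad_hash(permuted)

    def test_train_loss_history_blind_to_heldout_labels(self, small_cohort):
        config = small_config(semi_epochs_max=20, patience=20)
        X, graph, surv = self.build_inputs(small_cohort, config)
        res_a = train_bsg(X, graph, surv, config)
        heldout = ~surv.mask("train")
        t_perm = surv.survival_time.copy()
        idx = np.flatnonzero(heldout)
        t_perm[idx] = t_perm[np.roll(idx, 1)]
        res_b = train_bsg(X, graph, SurvivalTable(surv.patient_ids, t_perm, surv.split), config)
        assert res_a.train_loss == res_b.train_loss


class TestPipeline:
    def test_end_to_end_report_schema(self, small_cohort):
        expr, interactions, surv, _ = small_cohort
        res = run_mvmwgl(expr, interactions, surv, small_config())
        assert res.report["model_tag"] == "MVMWGL-GCNCN"
        assert set(res.report["per_term"]) == {"short", "medium", "long"}
        n_terms = sum(b["n"] for b in res.report["per_term"].values())
        assert n_terms == res.report["overall"]["n"]

    @pytest.mark.parametrize(
        "gig,bsg,tag",
        [
            ("GCN", "GCN", "MVMWGL-GCNCN"),
            ("GAT", "GCN", "MVMWGL-GATCN"),
            ("GCN", "GAT", "MVMWGL-GCNAT"),
            ("GAT", "GAT", "MVMWGL-GATAT"),
        ],
    )
    def test_four_configurations_tagged(self, gig, bsg, tag):
        config = TrainingConfig(layer_type_gig=gig, layer_type_bsg=bsg)
        assert config.model_tag == tag

    def test_k_genes_too_large_propagates_error(self, small_cohort):
        expr, interactions, surv, _ = small_cohort
        with pytest.raises(ValueError):
            run_mvmwgl(expr, interactions, surv, small_config(k_genes=10_000))

    def test_artifacts_persisted(self, small_cohort, tmp_path):
        expr, interactions, surv, _ = small_cohort
        run_mvmwgl(expr, interactions, surv, small_config(), out_dir=tmp_path)
        for name in ("pseudo_labels.tsv", "gene_representations.tsv",
                     "patient_embeddings.tsv", "predictions.tsv",
                     "report.json", "training_log.json"):
            assert (tmp_path / name).exists()

    def test_pseudo_labels_identical_without_survival(self, small_cohort):
        """The unsupervised stage never sees survival: corrupting all labels
        leaves the pseudo-labeling unchanged."""
        expr, interactions, surv, _ = small_cohort
        config = small_config(semi_epochs_max=5, patience=5, ssl_epochs=1)
        res_a = run_mvmwgl(expr, interactions, surv, config)
        rng = np.random.default_rng(99)
        # permute survival within splits (selection uses train labels, so keep
        # them; pseudo-labels must not react to any label change)
        t_perm = surv.survival_time.copy()
        heldout = ~surv.mask("train")
        idx = np.flatnonzero(heldout)
        t_perm[idx] = rng.permutation(t_perm[idx])
        surv_b = SurvivalTable(surv.patient_ids, t_perm, surv.split)
        res_b = run_mvmwgl(expr, interactions, surv_b, config)
        np.testing.assert_array_equal(res_a.pseudo_labels.labels, res_b.pseudo_labels.labels)


class TestBaselines:
    @pytest.mark.parametrize("kind", ["BSG-GCN", "GIG-GCN"])
    def test_baseline_report_schema(self, small_cohort, kind):
        expr, interactions, surv, _ = small_cohort
        config = small_config(semi_epochs_max=30, patience=10)
        res = run_baseline(kind, expr, interactions, surv, config)
        assert res.report["model_tag"] == kind
        assert res.report["overall"]["n"] > 0
        assert res.selected_epoch == int(np.argmin(res.val_loss))

    def test_unknown_kind_rejected(self, small_cohort):
        expr, interactions, surv, _ = small_cohort
        with pytest.raises(ValueError, match="unknown baseline"):
            run_baseline("BSG-MLP", expr, interactions, surv, small_config())

    def test_mean_predictor_uses_train_mean(self, small_cohort):
        _, _, surv, _ = small_cohort
        surv = surv
        preds = mean_predictor(surv)
        train = surv.mask("train")
        assert preds[0] == pytest.approx(surv.survival_time[train].mean())
        assert len(np.unique(preds)) == 1
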