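"""Negative sampling, stratified folds, the masked loss and its gradients,
early stopping, and scenario filters."""

import numpy as np
import pytest

from hetdti import (
    ModelParams,
    RwrConfig,
    SplitSpec,
    TrainConfig,
    build_masks,
    make_folds,
    masked_loss,
    sample_negatives,
    train,
)
from hetdti.training import filter_homologous_positives, loss_and_grads

from conftest import tiny_config
from hetdti import generate_network


class TestSampleNegatives:
    def test_count_and_zero_entries_only(self, tiny_net):
        dti = tiny_net.matrices["drug_target"]
        n_pos = int(dti.sum())
        neg = sample_negatives(dti, 10, seed=0)
        assert len(neg) == 10 * n_pos
        assert (dti[neg[:, 0], neg[:, 1]] == 0).all()
        assert len(np.unique(neg[:, 0] * dti.shape[1] + neg[:, 1])) == len(neg)

    def test_seed_reproducibility(self, tiny_net):
        dti = tiny_net.matrices["drug_target"]
        assert np.array_equal(sample_negatives(dti, 5, 3), sample_negatives(dti, 5, 3))
        assert not np.array_equal(sample_negatives(dti, 5, 3),
                                  sample_negatives(dti, 5, 4))

    def test_capped_at_available_zeros_with_warning(self):
        dti = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.warns(UserWarning, match="capping"):
            neg = sample_negatives(dti, 10, 0)
        assert len(neg) == 4

    def test_all_ratio_returns_every_zero_cell(self):
        dti = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert len(sample_negatives(dti, "all", 0)) == 3

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            sample_negatives(np.eye(3), 0, 0)


class TestMakeFolds:
    def _pairs(self, n, start=0):
        return np.array([[i, i + start] for i in range(n)])

    def test_split_sizes_match_protocol_ratios(self):
        pos, neg = self._pairs(100), self._pairs(900, 1000)
        folds = make_folds(pos, neg, k=10, seed=0)
        sizes = [len(f.train) + len(f.val) + len(f.test) for f in folds]
        assert all(s == 1000 for s in sizes)
        for f in folds:
            assert len(f.test) == 100
            assert abs(len(f.val) - 45) <= 2
            assert abs(len(f.train) - 855) <= 2

    def test_test_sets_partition_dataset(self):
        pos, neg = self._pairs(50), self._pairs(500, 60)
        folds = make_folds(pos, neg, k=5, seed=1)
        all_pairs = np.concatenate([pos, neg])
        seen = np.concatenate([f.test[:, :2] for f in folds])
        assert len(seen) == len(all_pairs)
        assert set(map(tuple, seen)) == set(map(tuple, all_pairs))
        for f in folds:
            parts = [set(map(tuple, p[:, :2])) for p in (f.train, f.val, f.test)]
            assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
            assert len(parts[0] | parts[1] | parts[2]) == len(all_pairs)

    def test_stratification_preserves_class_ratio(self):
        pos, neg = self._pairs(110), self._pairs(1210, 200)  # 11:1 imbalance
        folds = make_folds(pos, neg, k=10, seed=2)
        for f in folds:
            n_pos = int(f.test[:, 2].sum())
            n_neg = len(f.test) - n_pos
            assert abs(n_neg - 11 * n_pos) <= 11

    def test_deterministic_under_seed(self):
        pos, neg = self._pairs(30), self._pairs(120, 50)
        f1 = make_folds(pos, neg, 3, seed=9)
        f2 = make_folds(pos, neg, 3, seed=9)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)


class TestMaskedLoss:
    def test_perfect_reconstruction_is_zero(self):
        X = {"e": np.array([[1.0, 0.0]])}
        assert masked_loss(X, X, {"e": None}) == 0.0

    def test_single_residual(self):
        orig = {"e": np.array([[1.0, 0.0], [0.0, 1.0]])}
        recon = {"e": np.array([[0.5, 0.0], [0.0, 1.0]])}
        assert masked_loss(recon, orig, {"e": None}) == pytest.approx(0.25)

    def test_zero_mask_annihilates(self):
        orig = {"e": np.ones((3, 3))}
        recon = {"e": np.full((3, 3), 99.0)}
        assert masked_loss(recon, orig, {"e": np.zeros((3, 3))}) == 0.0

    def test_l2_term_strictly_increasing_in_lambda(self, tiny_net):
        params = ModelParams.initialize(tiny_net.space, tiny_net.edge_types, 3, 0)
        X = {"e": np.zeros((2, 2))}
        losses = [masked_loss(X, X, {"e": None}, params, lam) for lam in (0, 1e-4, 1e-2)]
        assert losses[0] < losses[1] < losses[2]


class TestMaskHygiene:
    def test_masked_out_entries_do_not_touch_loss_or_grads(self, tiny_net):
        params = ModelParams.initialize(tiny_net.space, tiny_net.edge_types, 4, 0)
        rwr = RwrConfig(alpha=0.3, max_iters=5)
        pos = np.argwhere(tiny_net.matrices["drug_target"] > 0)
        masks = build_masks(tiny_net, pos[:5])
        l1, g1, _ = loss_and_grads(tiny_net, params, rwr, masks, 1e-4)
        P = masks["drug_target"]
        off = np.argwhere(P == 0)
        targets = {k: v.copy() for k, v in tiny_net.matrices.items()}
        targets["drug_target"][off[0, 0], off[0, 1]] += 123.0
        targets["drug_target"][off[7, 0], off[7, 1]] -= 7.0
        l2, g2, _ = loss_and_grads(tiny_net, params, rwr, masks, 1e-4,
                                   targets=targets)
        assert l1 == l2  # bitwise
        for k in g1:
            assert np.array_equal(g1[k], g2[k])


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        cfg = tiny_config(seed=3, counts={"drug": 6, "protein": 8, "disease": 5,
                                          "side_effect": 4},
                          densities={k: 0.12 for k in (
                              "drug_target", "drug_drug", "protein_protein",
                              "drug_disease", "drug_sideeffect", "protein_disease")})
        net, _ = generate_network(cfg)
        params = ModelParams.initialize(net.space, net.edge_types, 5, 0)
        rwr = RwrConfig(alpha=0.3, max_iters=7, tol=0.0)
        pos = np.argwhere(net.matrices["drug_target"] > 0)
        masks = build_masks(net, pos[:3])
        lam = 1e-3
        _, grads, _ = loss_and_grads(net, params, rwr, masks, lam)
        rng = np.random.default_rng(0)
        for name, arr in params.leaves():
            flat = arr.ravel()
            for _ in range(2):
                i = rng.integers(len(flat))
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                lp, _, _ = loss_and_grads(net, params, rwr, masks, lam)
                flat[i] = old - eps
                lm, _, _ = loss_and_grads(net, params, rwr, masks, lam)
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                an = grads[name].ravel()[i]
                assert abs(fd - an) <= 1e-4 * max(1e-6, abs(fd) + abs(an))


def _tiny_split(net, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.argwhere(net.matrices["drug_target"] > 0)
    neg = sample_negatives(net.matrices["drug_target"], 3, seed)

    def rows(p, label):
        out = np.empty((len(p), 3), dtype=int)
        out[:, :2] = p
        out[:, 2] = label
        return out

    pp = rng.permutation(len(pos))
    nn = rng.permutation(len(neg))
    cut_p, cut_n = len(pos) // 4, len(neg) // 4
    return SplitSpec(
        fold_id=0,
        train=np.concatenate([rows(pos[pp[2 * cut_p:]], 1), rows(neg[nn[2 * cut_n:]], 0)]),
        val=np.concatenate([rows(pos[pp[:cut_p]], 1), rows(neg[nn[:cut_n]], 0)]),
        test=np.concatenate([rows(pos[pp[cut_p:2 * cut_p]], 1),
                             rows(neg[nn[cut_n:2 * cut_n]], 0)]),
    )


class TestTrainLoop:
    def test_zero_epochs_returns_initial_params(self, tiny_net):
        split = _tiny_split(tiny_net)
        cfg = TrainConfig(dim=4, max_epochs=0, init_seed=5)
        params, history = train(tiny_net, split, cfg)
        ref = ModelParams.initialize(tiny_net.space, tiny_net.edge_types, 4, 5)
        for (_, a), (_, b) in zip(params.leaves(), ref.leaves()):
            assert np.array_equal(a, b)
        assert history == []

    def test_loss_decreases_on_smoke_run(self, tiny_net):
        split = _tiny_split(tiny_net)
        cfg = TrainConfig(dim=8, lr=0.01, lam=0.0, max_epochs=10, patience=100,
                          rwr_iters=5, init_seed=0)
        _, history = train(tiny_net, split, cfg)
        losses = [h["loss"] for h in history]
        drops = sum(b < a for a, b in zip(losses, losses[1:]))
        assert drops >= 8

    def test_early_stop_fires_after_exact_patience(self, tiny_net, monkeypatch):
        split = _tiny_split(tiny_net)
        # constant validation metric: best at first evaluation, then
        # exactly `patience` non-improving epochs
        monkeypatch.setattr("hetdti.training.auprc", lambda s, l: 0.5)
        cfg = TrainConfig(dim=4, lr=0.001, max_epochs=500, patience=7, init_seed=0)
        _, history = train(tiny_net, split, cfg)
        assert len(history) == 8  # best epoch + patience non-improving

    def test_seed_determinism_end_to_end(self, tiny_net):
        split = _tiny_split(tiny_net)
        cfg = TrainConfig(dim=4, lr=0.01, max_epochs=6, patience=100, init_seed=3)
        p1, h1 = train(tiny_net, split, cfg)
        p2, h2 = train(tiny_net, split, cfg)
        assert h1 == h2
        for (_, a), (_, b) in zip(p1.leaves(), p2.leaves()):
            assert np.array_equal(a, b)

    def test_test_pairs_never_enter_mask_or_training_graph(self, tiny_net):
        split = _tiny_split(tiny_net)
        masks = build_masks(tiny_net, split.train)
        P = masks["drug_target"]
        assert (P[split.test[:, 0], split.test[:, 1]] == 0).all()
        assert (P[split.val[:, 0], split.val[:, 1]] == 0).all()
        from hetdti.training import _strip_heldout_edges
        stripped = _strip_heldout_edges(tiny_net, split)
        test_pos = split.test[split.test[:, 2] == 1]
        assert (stripped.matrices["drug_target"][test_pos[:, 0], test_pos[:, 1]] == 0).all()


class TestHomologyFilter:
    def test_similar_partner_positives_are_removed(self):
        from hetdti.hetnet import EdgeTypeSpec, HeteroNetwork, NodeSpace
        space = NodeSpace(counts={"drug": 3, "protein": 2, "disease": 1,
                                  "side_effect": 1})
        dti = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        dsim = np.eye(3)
        dsim[0, 1] = dsim[1, 0] = 0.9  # drugs 0,1 similar, both hit protein 0
        psim = np.eye(2)
        net = HeteroNetwork(
            space=space,
            edge_types={
                "drug_target": EdgeTypeSpec("drug_target", "drug", "protein"),
                "drug_similarity": EdgeTypeSpec(
                    "drug_similarity", "drug", "drug",
                    value_kind="real_unit_interval", symmetric=True, in_walk=False),
                "protein_similarity": EdgeTypeSpec(
                    "protein_similarity", "protein", "protein",
                    value_kind="real_unit_interval", symmetric=True, in_walk=False),
            },
            matrices={"drug_target": dti, "drug_similarity": dsim,
                      "protein_similarity": psim},
        )
        kept = filter_homologous_positives(net)
        assert set(map(tuple, kept)) == {(2, 1)}
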