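import numpy as np
import pytest

from mamlp import nn
from mamlp.classifier import (DivergenceError, MAMLPClassifier, SplitError,
                              build_ensemble, ensemble_predict,
                              ensemble_probs, split_dataset, train_ensemble)
from mamlp.preprocessing import preprocess_pipeline
from mamlp.registry import AtlasRegistry, AtlasVersion, default_registry
from mamlp.simulate import SimConfig, generate_dataset


class TestSplitDataset:
    def test_cohort_split_is_2300_300(self):
        labels = np.repeat([0, 1, 2], [781, 1148, 671])
        tr, te = split_dataset(labels, per_class_test=100, seed=0)
        assert te.size == 300 and tr.size == 2300
        assert np.intersect1d(tr, te).size == 0
        counts = np.bincount(labels[te], minlength=3)
        assert counts.tolist() == [100, 100, 100]

    def test_zero_test_size(self):
        labels = np.repeat([0, 1, 2], 10)
        tr, te = split_dataset(labels, per_class_test=0, seed=0)
        assert te.size == 0 and tr.size == 30

    def test_insufficient_class_names_the_class(self):
        labels = np.repeat([0, 1, 2], [50, 200, 200])
        with pytest.raises(SplitError, match="NC"):
            split_dataset(labels, per_class_test=100, seed=0)

    def test_seeded_and_uniform(self):
        labels = np.repeat([0, 1, 2], 200)
        a = split_dataset(labels, per_class_test=20, seed=5)
        b = split_dataset(labels, per_class_test=20, seed=5)
        assert (a[1] == b[1]).all()
        c = split_dataset(labels, per_class_test=20, seed=6)
        assert not (a[1] == c[1]).all()


class TestBuildEnsemble:
    def test_packaged_registry_gives_13_subnets_8_deep(self):
        model = build_ensemble(default_registry(filtered=True), seed=0)
        depths = [spec.depth for _, spec, _ in model.subnets_]
        assert len(depths) == 13
        assert depths.count(3) == 8 and depths.count(2) == 5

    def test_single_shallow_atlas(self):
        reg = AtlasRegistry(versions=(AtlasVersion("b", "b", 41, (0, 82)),))
        model = build_ensemble(reg, seed=0)
        assert len(model.subnets_) == 1
        assert model.subnets_[0][1].depth == 2

    def test_same_seed_bit_identical_parameters(self, small_registry):
        a = build_ensemble(small_registry, seed=3)
        b = build_ensemble(small_registry, seed=3)
        for (_, _, pa), (_, _, pb) in zip(a.subnets_, b.subnets_):
            assert all((wa == wb).all()
                       for wa, wb in zip(pa.weights, pb.weights))
            assert all((ba == bb).all()
                       for ba, bb in zip(pa.biases, pb.biases))

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_ensemble(AtlasRegistry(versions=()), seed=0)


class TestVoting:
    @pytest.fixture()
    def fixed_vote_model(self):
        """Two subnets engineered (via biases) to output fixed softmaxes."""

        def make(reg_slice, target):
            # zero weights, bias = log(target) gives softmax == target
            spec = nn.SubnetSpec(atlas_name="x", input_dim=2, depth=2,
                                 hidden_dims=(2,), dropout_rate=0.0,
                                 noisy_activation=False)
            params = nn.SubnetParams(
                [np.zeros((2, 2)), np.zeros((2, 3))],
                [np.zeros(2), np.log(np.asarray(target))],
            )
            return spec, params

        reg = AtlasRegistry(versions=(
            AtlasVersion("x", "x", 10, (0, 2)),
            AtlasVersion("y", "y", 10, (2, 4)),
        ))
        model = MAMLPClassifier(registry=reg)
        model.registry_ = reg
        model.classes_ = np.arange(3)
        s1, p1 = make(None, [0.6, 0.3, 0.1])
        s2, p2 = make(None, [0.1, 0.2, 0.7])
        model.subnets_ = [[reg.versions[0], s1, p1], [reg.versions[1], s2, p2]]
        return model

    def test_scores_are_elementwise_sum(self, fixed_vote_model):
        s = ensemble_probs(np.zeros(4), fixed_vote_model)
        assert np.allclose(s, [0.7, 0.5, 0.8], atol=1e-9)

    def test_argmax_of_summed_scores(self, fixed_vote_model):
        assert ensemble_predict(np.zeros(4), fixed_vote_model) == 2

    def test_scores_sum_to_subnet_count(self, fixed_vote_model, rng):
        x = rng.normal(size=(9, 4))
        s = fixed_vote_model.decision_function(x)
        assert np.allclose(s.sum(axis=1), 2.0, atol=1e-6)

    def test_tie_breaks_to_lowest_class_index(self):
        scores = np.array([[1.0, 1.0, 0.0]])
        assert np.argmax(scores, axis=1)[0] == 0  # documented convention

    def test_matches_brute_force_sum_and_scan_oracle(self, rng):
        # 1,000 random subnet-probability sets: a model whose subnets emit
        # the given softmax vectors must agree with a hand-written
        # enumerate-sum-scan oracle
        spec = nn.SubnetSpec(atlas_name="x", input_dim=1, depth=2,
                             hidden_dims=(1,), dropout_rate=0.0,
                             noisy_activation=False)
        for trial in range(1000):
            n_sub = int(rng.integers(1, 8))
            probs = rng.dirichlet(np.ones(3), size=n_sub)
            versions = tuple(AtlasVersion(f"a{j}", f"a{j}", 10, (j, j + 1))
                             for j in range(n_sub))
            model = MAMLPClassifier(registry=AtlasRegistry(versions=versions))
            model.registry_ = AtlasRegistry(versions=versions)
            model.classes_ = np.arange(3)
            model.subnets_ = [
                [v, spec, nn.SubnetParams(
                    [np.zeros((1, 1)), np.zeros((1, 3))],
                    [np.zeros(1), np.log(p)])]
                for v, p in zip(versions, probs)
            ]
            # oracle: enumerate subnets, sum softmax, scan for max
            summed = np.zeros(3)
            for p in probs:
                summed += p
            best, best_val = 0, -np.inf
            for k in range(3):
                if summed[k] > best_val:
                    best, best_val = k, summed[k]
            x = np.zeros(n_sub)
            assert ensemble_predict(x, model) == best
            assert np.allclose(ensemble_probs(x, model), summed, atol=1e-9)

    def test_prediction_invariant_to_subnet_order(self, small_cohort, rng):
        cfg, matrix, _ = small_cohort
        mat, reg, _ = preprocess_pipeline(matrix, cfg.registry,
                                          filter_atlases=False)
        clf = MAMLPClassifier(registry=reg, epochs=3, random_state=0,
                              eval_every=10)
        clf.fit(mat.values, mat.labels)
        base = clf.predict(mat.values[:20])
        clf.subnets_ = clf.subnets_[::-1]
        assert (clf.predict(mat.values[:20]) == base).all()

    def test_single_subnet_reduces_to_its_softmax_argmax(self, rng):
        reg = AtlasRegistry(versions=(AtlasVersion("x", "x", 10, (0, 4)),))
        model = build_ensemble(reg, seed=2)
        x = rng.normal(size=(6, 4))
        _, spec, params = model.subnets_[0]
        direct = np.argmax(nn.subnet_forward(x, spec, params), axis=1)
        assert (model.predict(x) == direct).all()

    def test_uniform_subnet_never_flips_clear_margins(self):
        reg = AtlasRegistry(versions=(
            AtlasVersion("x", "x", 10, (0, 2)),
            AtlasVersion("y", "y", 10, (2, 4)),
        ))
        informative = nn.SubnetParams(
            [np.zeros((2, 2)), np.zeros((2, 3))],
            [np.zeros(2), np.log(np.array([0.2, 0.3, 0.5]))])
        uniform = nn.SubnetParams(
            [np.zeros((2, 2)), np.zeros((2, 3))],
            [np.zeros(2), np.zeros(3)])
        spec = nn.SubnetSpec(atlas_name="x", input_dim=2, depth=2,
                             hidden_dims=(2,), dropout_rate=0.0,
                             noisy_activation=False)
        model = MAMLPClassifier(registry=reg)
        model.registry_, model.classes_ = reg, np.arange(3)
        model.subnets_ = [[reg.versions[0], spec, informative],
                          [reg.versions[1], spec, uniform]]
        with_uniform = model.predict(np.zeros((1, 4)))[0]
        model.subnets_ = model.subnets_[:1]
        assert model.predict(np.zeros((1, 4)))[0] == with_uniform == 2


class TestTraining:
    def test_learns_separable_data(self, small_cohort):
        cfg, matrix, _ = small_cohort
        mat, reg, _ = preprocess_pipeline(matrix, cfg.registry,
                                          filter_atlases=False)
        tr, te = split_dataset(mat.labels, per_class_test=30, seed=0)
        clf = MAMLPClassifier(registry=reg, epochs=200, random_state=0,
                              eval_every=200)
        clf.fit(mat.values[tr], mat.labels[tr])
        acc = np.mean(clf.predict(mat.values[te]) == mat.labels[te])
        assert acc >= 0.9

    def test_no_signal_stays_at_chance(self, small_registry):
        cfg = SimConfig(class_counts=(100, 100, 100),
                        registry=small_registry, effect_size=0.0,
                        nan_rate=0.0, inf_rate=0.0, seed=11)
        matrix, _ = generate_dataset(cfg)
        mat, reg, _ = preprocess_pipeline(matrix, small_registry,
                                          filter_atlases=False)
        tr, te = split_dataset(mat.labels, per_class_test=30, seed=0)
        clf = MAMLPClassifier(registry=reg, epochs=15, random_state=0,
                              eval_every=15)
        clf.fit(mat.values[tr], mat.labels[tr])
        acc = np.mean(clf.predict(mat.values[te]) == mat.labels[te])
        se = np.sqrt((1 / 3) * (2 / 3) / te.size)
        assert abs(acc - 1 / 3) <= 3 * se

    def test_same_seed_identical_model_and_log(self, small_cohort):
        cfg, matrix, _ = small_cohort
        mat, reg, _ = preprocess_pipeline(matrix, cfg.registry,
                                          filter_atlases=False)
        runs = []
        for _ in range(2):
            clf, log = train_ensemble(
                mat, reg, config=dict(epochs=3, random_state=9,
                                      eval_every=3))
            runs.append((clf, log))
        (a, la), (b, lb) = runs
        for (_, _, pa), (_, _, pb) in zip(a.subnets_, b.subnets_):
            assert all((wa == wb).all()
                       for wa, wb in zip(pa.weights, pb.weights))
        assert la.equals(lb)

    def test_training_log_has_fig4_columns(self, small_cohort):
        cfg, matrix, _ = small_cohort
        mat, reg, _ = preprocess_pipeline(matrix, cfg.registry,
                                          filter_atlases=False)
        tr, te = split_dataset(mat.labels, per_class_test=20, seed=0)
        clf = MAMLPClassifier(registry=reg, epochs=4, random_state=0)
        clf.fit(mat.values[tr], mat.labels[tr],
                eval_set=(mat.values[te], mat.labels[te]))
        log = clf.history_
        assert {"epoch", "split", "loss", "accuracy",
                "macro_f1"} <= set(log.columns)
        assert set(log["split"]) == {"train", "test"}
        assert log[log.split == "train"]["epoch"].tolist() == [1, 2, 3, 4]

    def test_smoothed_train_loss_declines(self, small_cohort):
        cfg, matrix, _ = small_cohort
        mat, reg, _ = preprocess_pipeline(matrix, cfg.registry,
                                          filter_atlases=False)
        clf = MAMLPClassifier(registry=reg, epochs=20, random_state=1,
                              eval_every=20)
        clf.fit(mat.values, mat.labels)
        loss = clf.history_.query("split == 'train'")["loss"].to_numpy()
        smooth = np.convolve(loss, np.ones(5) / 5, mode="valid")
        assert (np.diff(smooth) <= 1e-3).all()

    def test_stability_across_seeds_without_regularization_noise(
            self, small_cohort):
        cfg, matrix, _ = small_cohort
        mat, reg, _ = preprocess_pipeline(matrix, cfg.registry,
                                          filter_atlases=False)
        tr, te = split_dataset(mat.labels, per_class_test=30, seed=0)
        accs = []
        for seed in (0, 1):
            clf = MAMLPClassifier(registry=reg, epochs=150, dropout_rate=0.0,
                                  noisy_activation=False, random_state=seed,
                                  eval_every=150)
            clf.fit(mat.values[tr], mat.labels[tr])
            accs.append(np.mean(clf.predict(mat.values[te]) == mat.labels[te]))
        assert abs(accs[0] - accs[1]) <= 0.05

    def test_ensemble_not_worse_than_weakest_subnet(self, small_cohort):
        cfg, matrix, _ = small_cohort
        mat, reg, _ = preprocess_pipeline(matrix, cfg.registry,
                                          filter_atlases=False)
        tr, te = split_dataset(mat.labels, per_class_test=30, seed=0)
        clf = MAMLPClassifier(registry=reg, epochs=20, random_state=0,
                              eval_every=20)
        clf.fit(mat.values[tr], mat.labels[tr])
        ens_acc = np.mean(clf.predict(mat.values[te]) == mat.labels[te])
        sub_accs = []
        for version, spec, params in clf.subnets_:
            sl = slice(*version.span)
            pred = np.argmax(
                nn.subnet_forward(mat.values[te][:, sl], spec, params),
                axis=1)
            sub_accs.append(np.mean(pred == mat.labels[te]))
        assert ens_acc >= min(sub_accs)

    def test_joint_training_mode_learns(self, small_cohort):
        cfg, matrix, _ = small_cohort
        mat, reg, _ = preprocess_pipeline(matrix, cfg.registry,
                                          filter_atlases=False)
        tr, te = split_dataset(mat.labels, per_class_test=30, seed=0)
        clf = MAMLPClassifier(registry=reg, epochs=300, joint_training=True,
                              random_state=0, eval_every=300)
        clf.fit(mat.values[tr], mat.labels[tr])
        acc = np.mean(clf.predict(mat.values[te]) == mat.labels[te])
        assert acc >= 0.8

    def test_width_mismatch_rejected(self, small_registry, rng):
        clf = MAMLPClassifier(registry=small_registry, epochs=1)
        with pytest.raises(nn.ShapeError):
            clf.fit(rng.normal(size=(10, 7)), np.zeros(10, dtype=int))


class TestPersistence:
    def test_save_load_round_trip_bit_exact(self, tmp_path, small_cohort):
        cfg, matrix, _ = small_cohort
        mat, reg, _ = preprocess_pipeline(matrix, cfg.registry,
                                          filter_atlases=False)
        clf = MAMLPClassifier(registry=reg, epochs=2, random_state=0,
                              eval_every=2)
        clf.fit(mat.values, mat.labels)
        clf.save(tmp_path / "model")
        other = MAMLPClassifier.load(tmp_path / "model")
        for (_, sa, pa), (_, sb, pb) in zip(clf.subnets_, other.subnets_):
            assert sa == sb
            assert all((wa == wb).all()
                       for wa, wb in zip(pa.weights, pb.weights))
            assert all((ba == bb).all()
                       for ba, bb in zip(pa.biases, pb.biases))
        x = mat.values[:5]
        assert (clf.decision_function(x) == other.decision_function(x)).all()
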