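import numpy as np
import pytest

from toxcascade import (
    CascadeConfig,
    FrameworkConfig,
    MultiTaskCollection,
    SynthSpec,
    enhance_features,
    fit,
    generate_collection,
    leakage_audit,
)


@pytest.fixture(scope="module")
def related_collection():
    spec = SynthSpec(
        T=3, sizes=(60, 60, 60), d=12, n_clusters=1,
        relatedness=0.9, feature_sparsity=0.3, noise_sd=0.3, seed=11,
    )
    return generate_collection(spec)


@pytest.fixture(scope="module")
def fitted(related_collection):
    cfg = FrameworkConfig(
        cascade=CascadeConfig(trees_per_unit=10, max_layers=2, seed=7), seed=7
    )
    return fit(related_collection, cfg)


class TestFit:
    def test_single_endpoint_degenerates_to_baseline(self, related_collection):
        solo = MultiTaskCollection([related_collection.endpoints[0]], "solo")
        cfg = FrameworkConfig(
            cascade=CascadeConfig(trees_per_unit=5, max_layers=1, seed=3), seed=3
        )
        model = fit(solo, cfg)
        eid = solo.endpoints[0].meta.endpoint_id
        res = model.results[eid]
        assert res.candidate_order == [] and res.accepted_ids == []
        # final training = own train + valid rows only
        pool = model.training_pools[eid]
        total = sum(len(idx) for _, idx in pool)
        assert total == int(solo.endpoints[0].mask("train", "valid").sum())

    def test_accepted_scores_strictly_increase(self, fitted):
        for res in fitted.results.values():
            scores = [res.baseline_valid_score] + [
                s for _, s, acc in res.trajectory if acc
            ]
            assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_trajectory_halts_at_first_rejection(self, fitted):
        # patience=0: at most the final trajectory entry may be a rejection
        for res in fitted.results.values():
            for cand, score, accepted in res.trajectory[:-1]:
                assert accepted

    def test_refit_same_seed_reproduces_everything(self, related_collection, fitted):
        cfg = FrameworkConfig(
            cascade=CascadeConfig(trees_per_unit=10, max_layers=2, seed=7), seed=7
        )
        again = fit(related_collection, cfg)
        for eid in fitted.models:
            assert fitted.results[eid].accepted_ids == again.results[eid].accepted_ids
            X_test = related_collection[eid].subset("test")[0]
            np.testing.assert_array_equal(
                fitted.predict(eid, X_test), again.predict(eid, X_test)
            )

    def test_unsplit_collection_rejected(self, related_collection):
        from toxcascade import EndpointDataset

        eps = [
            EndpointDataset(ep.meta, ep.X, ep.y, None)
            for ep in related_collection
        ]
        with pytest.raises(ValueError, match="not split"):
            fit(MultiTaskCollection(eps, "u"))


class TestFinalize:
    def test_final_pool_adds_own_validation_rows(self, fitted, related_collection):
        for eid, res in fitted.results.items():
            ep = related_collection[eid]
            pool_rows = sum(len(idx) for _, idx in fitted.training_pools[eid])
            greedy_rows = sum(res.best_train_composition.values())
            assert pool_rows == greedy_rows + int(ep.mask("valid").sum())

    def test_no_test_row_in_any_pool(self, fitted, related_collection):
        assert leakage_audit(fitted, related_collection)

    def test_audit_detects_planted_leak(self, fitted, related_collection):
        import copy

        broken = copy.copy(fitted)
        broken.training_pools = {
            k: [(e, np.asarray(i)) for e, i in v]
            for k, v in fitted.training_pools.items()
        }
        eid = related_collection.endpoint_ids[0]
        test_row = related_collection[eid].indices("test")[:1]
        broken.training_pools[eid] = broken.training_pools[eid] + [(eid, test_row)]
        with pytest.raises(RuntimeError, match="test rows"):
            leakage_audit(broken, related_collection)


class TestPredictEvaluate:
    def test_predict_is_enhance_then_cascade(self, fitted, related_collection):
        eid = related_collection.endpoint_ids[0]
        X = related_collection[eid].subset("test")[0]
        direct = fitted.models[eid].predict(enhance_features(fitted.source, X))
        np.testing.assert_array_equal(fitted.predict(eid, X), direct)

    def test_unknown_endpoint(self, fitted):
        with pytest.raises(KeyError):
            fitted.predict(99, np.zeros((2, fitted.raw_width)))

    def test_raw_width_enforced(self, fitted):
        with pytest.raises(ValueError, match="raw width"):
            fitted.predict(1, np.zeros((2, fitted.raw_width + 1)))

    def test_average_is_unweighted_mean(self, fitted, related_collection):
        reports, avg = fitted.evaluate(related_collection)
        assert len(reports) == related_collection.T
        assert avg["r2"] == pytest.approx(np.mean([r["r2"] for r in reports]))
        assert avg["rmse"] == pytest.approx(np.mean([r["rmse"] for r in reports]))

    def test_importance_lives_in_raw_feature_space(self, fitted, related_collection):
        imp = fitted.feature_importance(related_collection.endpoint_ids[0])
        assert imp.shape == (related_collection.d,)
        assert abs(imp.sum() - 1.0) < 1e-9


class TestGreedyGuards:
    def test_tiny_validation_set_skips_greedy(self):
        spec = SynthSpec(
            T=2, sizes=(12, 60), d=8, n_clusters=1, relatedness=0.9, seed=4
        )
        coll = generate_collection(spec)
        cfg = FrameworkConfig(
            cascade=CascadeConfig(trees_per_unit=5, max_layers=1, seed=4),
            min_valid_rows=5,
            seed=4,
        )
        model = fit(coll, cfg)
        small_eid = coll.endpoints[0].meta.endpoint_id
        assert int(coll[small_eid].mask("valid").sum()) < 5
        assert model.results[small_eid].skipped
        assert model.results[small_eid].accepted_ids == []
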