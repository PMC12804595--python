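import numpy as np
import pytest

from toxcascade import (
    CascadeConfig,
    MultiTaskCollection,
    aggregate_training_data,
    enhance_collection,
    enhance_features,
    fit_cascade,
    fit_source_model,
)


@pytest.fixture(scope="module")
def source(small_collection_module):
    X, y, ids = aggregate_training_data(small_collection_module)
    cfg = CascadeConfig(trees_per_unit=10, max_layers=1, seed=5)
    return fit_source_model(X, y, cfg, row_ids=ids, keep_oof=True)


@pytest.fixture(scope="module")
def small_collection_module():
    from toxcascade import SynthSpec, generate_collection

    spec = SynthSpec(
        T=3, sizes=(60, 60, 60), d=12, n_clusters=1,
        relatedness=0.9, feature_sparsity=0.3, noise_sd=0.3, seed=11,
    )
    return generate_collection(spec)


class TestAggregation:
    def test_pool_is_trainvalid_union(self, small_collection_module):
        coll = small_collection_module
        X, y, ids = aggregate_training_data(coll)
        expected = sum(int(ep.mask("train", "valid").sum()) for ep in coll)
        assert X.shape == (expected, coll.d) and len(y) == len(ids) == expected

    def test_no_test_row_enters_pool(self, small_collection_module):
        coll = small_collection_module
        _, _, ids = aggregate_training_data(coll)
        test_ids = {
            (ep.meta.endpoint_id, int(i))
            for ep in coll
            for i in ep.indices("test")
        }
        assert not (set(ids) & test_ids)

    def test_single_endpoint_identity(self, small_collection_module):
        ep = small_collection_module.endpoints[0]
        solo = MultiTaskCollection([ep], "solo")
        X, y, _ = aggregate_training_data(solo)
        Xe, ye = ep.subset("train", "valid")
        np.testing.assert_array_equal(np.sort(X, axis=0), np.sort(Xe, axis=0))
        assert len(y) == len(ye)

    def test_unsplit_endpoint_named(self, small_collection_module):
        from toxcascade import EndpointDataset

        ep = small_collection_module.endpoints[0]
        unsplit = EndpointDataset(ep.meta, ep.X, ep.y, None)
        with pytest.raises(ValueError, match=str(ep.meta.endpoint_id)):
            aggregate_training_data(MultiTaskCollection([unsplit], "u"))


class TestSourceModel:
    def test_operates_on_raw_width(self, source, small_collection_module):
        assert source.input_width == small_collection_module.d
        assert source.n_units == 4

    def test_extraction_identity_with_cascade_layer_one(self, small_collection_module):
        X, y, ids = aggregate_training_data(small_collection_module)
        cfg = CascadeConfig(trees_per_unit=10, max_layers=1, seed=5)
        src = fit_source_model(X, y, cfg, row_ids=ids)
        cascade = fit_cascade(X, y, cfg)
        np.testing.assert_array_equal(
            src.predict_units(X), cascade.layer_predict(1, X)
        )

    def test_deterministic_under_seed(self, small_collection_module):
        X, y, ids = aggregate_training_data(small_collection_module)
        cfg = CascadeConfig(trees_per_unit=10, max_layers=1, seed=5)
        a = fit_source_model(X, y, cfg, row_ids=ids)
        b = fit_source_model(X, y, cfg, row_ids=ids)
        np.testing.assert_array_equal(a.predict_units(X), b.predict_units(X))

    def test_provenance_counts(self, source, small_collection_module):
        for ep in small_collection_module:
            expected = int(ep.mask("train", "valid").sum())
            assert source.provenance[ep.meta.endpoint_id] == expected


class TestEnhancement:
    def test_width_additive_and_content_preserving(self, source, small_collection_module):
        X = small_collection_module.endpoints[0].X
        out = enhance_features(source, X)
        assert out.shape == (X.shape[0], X.shape[1] + 4)
        np.testing.assert_array_equal(out[:, : X.shape[1]], X)

    def test_enhance_twice_identical(self, source, small_collection_module):
        X = small_collection_module.endpoints[0].X
        np.testing.assert_array_equal(
            enhance_features(source, X), enhance_features(source, X)
        )

    def test_width_mismatch_rejected(self, source):
        with pytest.raises(ValueError, match="columns"):
            enhance_features(source, np.zeros((3, 5)))

    def test_collection_enhancement_keeps_labels_and_splits(
        self, source, small_collection_module
    ):
        enhanced = enhance_collection(source, small_collection_module)
        assert enhanced.d == small_collection_module.d + 4
        for a, b in zip(small_collection_module, enhanced):
            np.testing.assert_array_equal(a.y, b.y)
            np.testing.assert_array_equal(a.split, b.split)
            np.testing.assert_array_equal(a.X, b.X[:, : a.d])

    def test_oof_mode_swaps_training_rows_only(self, source, small_collection_module):
        plain = enhance_collection(source, small_collection_module, use_oof=False)
        oof = enhance_collection(source, small_collection_module, use_oof=True)
        d = small_collection_module.d
        for ep_p, ep_o, ep in zip(plain, oof, small_collection_module):
            test_rows = ep.indices("test")
            np.testing.assert_array_equal(
                ep_p.X[test_rows, d:], ep_o.X[test_rows, d:]
            )
            train_rows = ep.indices("train", "valid")
            # OOF predictions come from held-out folds, so they differ
            assert not np.allclose(ep_p.X[train_rows, d:], ep_o.X[train_rows, d:])

    def test_oof_requires_keep_oof(self, small_collection_module):
        X, y, ids = aggregate_training_data(small_collection_module)
        src = fit_source_model(
            X, y, CascadeConfig(trees_per_unit=5, max_layers=1, seed=1), row_ids=ids
        )
        with pytest.raises(ValueError, match="keep_oof"):
            enhance_collection(src, small_collection_module, use_oof=True)
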