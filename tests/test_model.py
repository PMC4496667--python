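"""End-to-end classifier behaviour: fitting, prediction, LOOCV, persistence."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from wes.evaluate import loocv, roc_auc
from wes.model import (LigandLibrary, WesClassifier, load_model, save_model)


def _XY(bench):
    return bench.pairs[["protein_id", "ligand_id"]], bench.pairs["label"]


class TestFit:
    def test_all_components_populated(self, small_fit):
        clf = small_fit
        assert set(clf.s_cut_) == {"binary", "continuous"}
        assert set(clf.null_models_) == {"binary", "continuous"}
        assert clf.kde_pos_.n > 0 and clf.kde_neg_.n > 0
        assert 0 <= clf.theta_ <= 1
        for ens in clf.ensembles_.values():
            assert ens.size >= 5
            for ch in ("binary", "continuous"):
                assert ens.weights[ch].shape[0] > 0

    def test_single_channel_mode(self, small_bench):
        lib = LigandLibrary.from_benchmark(small_bench)
        clf = WesClassifier(library=lib, channel="binary", random_state=11)
        X, y = _XY(small_bench)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        assert "binary" in clf.z_threshold_
        assert not hasattr(clf, "kde_pos_")
        assert not hasattr(clf, "theta_")
        preds = clf.predict(X.head(10))
        assert set(preds) <= {0, 1}

    def test_missing_library_fatal(self, small_bench):
        X, y = _XY(small_bench)
        with pytest.raises(ValueError, match="LigandLibrary"):
            WesClassifier().fit(X, y)

    def test_one_class_fatal(self, small_bench, small_fit):
        X, y = _XY(small_bench)
        with pytest.raises(ValueError, match="both classes"):
            clone(small_fit).fit(X[y == 1], y[y == 1])

    def test_sklearn_params_roundtrip(self, small_fit):
        params = small_fit.get_params()
        fresh = WesClassifier(**params)
        assert fresh.get_params()["q_threshold"] == params["q_threshold"]

    def test_refit_same_seed_identical(self, small_bench, small_fit, tmp_path):
        X, y = _XY(small_bench)
        clf2 = clone(small_fit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf2.fit(X, y)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_model(small_fit, p1)
        save_model(clf2, p2)
        assert p1.read_text() == p2.read_text()


class TestPredict:
    def test_self_retrieval(self, small_bench, small_fit):
        pos = small_bench.pairs[small_bench.pairs.label == 1]
        sample = pos.sample(20, random_state=0)
        calls = small_fit.predict(sample[["protein_id", "ligand_id"]])
        assert calls.mean() >= 0.9

    def test_background_specificity(self, small_bench, small_fit):
        bg = [l for l in small_bench.ligand_ids if l.startswith("BG_")][:20]
        ranked = small_fit.predict_targets(bg)
        assert ranked["call"].mean() <= 0.10

    def test_empty_target_subset(self, small_fit):
        out = small_fit.predict_targets(["BG_0000"], targets=[])
        assert out.empty

    def test_unknown_target_lists_valid(self, small_fit):
        with pytest.raises(KeyError, match="valid"):
            small_fit.predict_targets(["BG_0000"], targets=["NOPE"])

    def test_predict_proba_rows_sum_to_one(self, small_bench, small_fit):
        X, _ = _XY(small_bench)
        proba = small_fit.predict_proba(X.head(8))
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_ranked_output_sorted_per_query(self, small_bench, small_fit):
        out = small_fit.predict_targets(["BG_0001", "BG_0002"])
        for _, grp in out.groupby("ligand_id"):
            lk = grp["likelihood"].to_numpy()
            assert (np.diff(lk) <= 1e-12).all()


class TestHeldOut:
    def test_cardinality_and_auc(self, small_bench, small_fit):
        held = small_fit.score_pairs_heldout(small_bench.pairs)
        assert len(held) == len(small_bench.pairs)
        auc = roc_auc(held["likelihood"], held["label"])
        assert auc > 0.8

    def test_order_invariance(self, small_bench, small_fit):
        held1 = small_fit.score_pairs_heldout(small_bench.pairs)
        shuffled = small_bench.pairs.sample(frac=1, random_state=3)
        held2 = small_fit.score_pairs_heldout(shuffled)
        m1 = held1.set_index(["protein_id", "ligand_id"])["z_binary"]
        m2 = held2.set_index(["protein_id", "ligand_id"])["z_binary"]
        pd.testing.assert_series_equal(m1.sort_index(), m2.sort_index())

    def test_loocv_driver(self, small_bench, small_fit):
        X, y = _XY(small_bench)
        held = loocv(small_fit, X, y)
        assert len(held) == len(X)
        assert {"call", "likelihood"} <= set(held.columns)

    def test_no_leakage_from_unrelated_pair(self, small_bench, small_fit):
        # adding a duplicate positive for another protein must not move a
        # held-out pair's z-scores (cutoffs held fixed at the trained point)
        X, y = _XY(small_bench)
        probe = small_bench.pairs.iloc[[0]]
        pid = probe["protein_id"].iloc[0]
        other = small_bench.pairs[(small_bench.pairs.label == 1)
                                  & (small_bench.pairs.protein_id != pid)].iloc[[0]]
        base = clone(small_fit).set_params(s_cut=dict(small_fit.s_cut_))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = clone(base).fit(X, y)
            X2 = pd.concat([X, other[["protein_id", "ligand_id"]]],
                           ignore_index=True)
            y2 = pd.concat([y, other["label"]], ignore_index=True)
            m2 = clone(base).fit(X2, y2)
            h1 = m1.score_pairs_heldout(probe.assign(label=1),
                                        refit_thresholds=False)
            h2 = m2.score_pairs_heldout(probe.assign(label=1),
                                        refit_thresholds=False)
        assert h1["z_binary"].iloc[0] == pytest.approx(h2["z_binary"].iloc[0],
                                                       abs=1e-12)
        assert h1["z_continuous"].iloc[0] == pytest.approx(
            h2["z_continuous"].iloc[0], abs=1e-12)

    def test_tiny_ensemble_flagged(self, small_bench, small_fit):
        # keep only 2 positives for one protein: holding one out degenerates
        pairs = small_bench.pairs
        pid = sorted(small_fit.ensembles_)[0]
        keep_pos = pairs[(pairs.label == 1) & (pairs.protein_id == pid)].head(2)
        other_pos = pairs[(pairs.label == 1) & (pairs.protein_id != pid)]
        neg = pairs[pairs.label == 0]
        subset = pd.concat([keep_pos, other_pos, neg], ignore_index=True)
        clf = clone(small_fit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(subset[["protein_id", "ligand_id"]], subset["label"])
            held = clf.score_pairs_heldout(subset)
        flagged = held[held.protein_id == pid]
        assert flagged.loc[flagged.label == 1, "degenerate"].all()


class TestPersistence:
    def test_roundtrip_bit_identical_predictions(self, small_bench, small_fit,
                                                 tmp_path):
        path = tmp_path / "model.json"
        save_model(small_fit, path)
        back = load_model(path)
        X, _ = _XY(small_bench)
        a = small_fit.score_pairs(X)
        b = back.score_pairs(X)
        for col in ("raw_binary", "z_binary", "z_continuous", "likelihood"):
            assert (a[col].to_numpy() == b[col].to_numpy()).all()
        assert (a["call"] == b["call"]).all()

    def test_corrupted_file_explicit_error(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json!")
        with pytest.raises(ValueError, match="corrupted"):
            load_model(bad)

    def test_version_mismatch_refused(self, small_fit, tmp_path):
        path = tmp_path / "m.json"
        save_model(small_fit, path)
        payload = json.loads(path.read_text())
        payload["format_version"] = 999
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="version"):
            load_model(path)
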