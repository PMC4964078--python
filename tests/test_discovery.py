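"""Nearest-shrunken-centroid training, prediction, CV, signature derivation."""

import numpy as np
import pandas as pd
import pytest

import nodesig as ns
from nodesig.errors import EmptySignatureError, InvalidInputError
from nodesig.signature_discovery import default_delta_grid

from helpers import nsc_by_hand, nsc_discriminant_by_hand


def toy_instance():
    """4 genes x 6 samples, two classes of 3."""
    rng = np.random.default_rng(11)
    X = pd.DataFrame(
        rng.normal(size=(4, 6)),
        index=["g1", "g2", "g3", "g4"],
        columns=[f"s{i}" for i in range(6)],
    )
    X.loc["g1", ["s0", "s1", "s2"]] += 2.0  # informative gene
    labels = pd.Series(["A"] * 3 + ["B"] * 3, index=X.columns)
    return X, labels


class TestNscTrain:
    def test_delta_zero_centroids_unshrunken(self):
        X, labels = toy_instance()
        model = ns.nsc_train(X, labels, delta=0.0)
        pd.testing.assert_frame_equal(model.shrunken_centroids, model.class_centroids)
        pd.testing.assert_frame_equal(model.d_shrunk, model.d)

    def test_delta_above_max_kills_all_genes(self):
        X, labels = toy_instance()
        model0 = ns.nsc_train(X, labels, delta=0.0)
        big = float(model0.d.abs().to_numpy().max()) + 0.1
        model = ns.nsc_train(X, labels, delta=big)
        assert model.surviving_genes == []
        for k in model.classes:
            np.testing.assert_allclose(
                model.shrunken_centroids[k], model.overall_centroid
            )

    def test_matches_from_scratch_recomputation(self):
        X, labels = toy_instance()
        delta = 0.7
        model = ns.nsc_train(X, labels, delta=delta)
        hand = nsc_by_hand(X.to_numpy(), labels.to_numpy(), delta)
        assert model.s0 == pytest.approx(hand["s0"])
        np.testing.assert_allclose(model.pooled_sd, hand["pooled_sd"])
        for k in model.classes:
            np.testing.assert_allclose(model.d[k], hand["d"][k])
            np.testing.assert_allclose(model.d_shrunk[k], hand["d_shrunk"][k])
            np.testing.assert_allclose(
                model.shrunken_centroids[k], hand["shrunken_centroids"][k]
            )

    def test_soft_threshold_invariant(self):
        X, labels = toy_instance()
        model = ns.nsc_train(X, labels, delta=0.4)
        np.testing.assert_allclose(
            model.d_shrunk.abs().to_numpy(),
            np.maximum(model.d.abs().to_numpy() - 0.4, 0.0),
        )

    def test_surviving_gene_count_monotone_in_delta(self):
        X, labels = toy_instance()
        counts = [
            len(ns.nsc_train(X, labels, delta=d).surviving_genes)
            for d in np.linspace(0, 3, 10)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_single_class_raises(self):
        X, _ = toy_instance()
        with pytest.raises(InvalidInputError):
            ns.nsc_train(X, pd.Series(["A"] * 6, index=X.columns), delta=0.0)


class TestNscPredict:
    def test_centroid_sample_classified_to_its_class(self):
        X, labels = toy_instance()
        model = ns.nsc_train(X, labels, delta=0.2)
        for k in model.classes:
            label, _ = ns.nsc_predict(model, model.shrunken_centroids[k])
            assert label == k

    def test_no_surviving_genes_majority_class(self):
        X, labels = toy_instance()
        labels = pd.Series(["A"] * 4 + ["B"] * 2, index=X.columns)  # unequal priors
        model0 = ns.nsc_train(X, labels, delta=0.0)
        model = ns.nsc_train(X, labels, delta=float(model0.d.abs().to_numpy().max()) + 1)
        preds, _ = ns.nsc_predict(model, X)
        assert (preds == "A").all()

    def test_matches_brute_force_discriminant(self):
        X, labels = toy_instance()
        model = ns.nsc_train(X, labels, delta=0.3)
        hand = nsc_by_hand(X.to_numpy(), labels.to_numpy(), 0.3)
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(size=4), index=X.index)
        _, scores = ns.nsc_predict(model, x)
        expected = nsc_discriminant_by_hand(
            hand, x.to_numpy(), model.priors.to_dict()
        )
        for k in model.classes:
            assert scores[k] == pytest.approx(expected[k])

    def test_delta_zero_equals_diagonal_nearest_centroid(self):
        # at delta=0 the discriminant is the (s+s0)-scaled diagonal distance
        X, labels = toy_instance()
        model = ns.nsc_train(X, labels, delta=0.0)
        rng = np.random.default_rng(8)
        x = pd.Series(rng.normal(size=4), index=X.index)
        label, _ = ns.nsc_predict(model, x)
        s = (model.pooled_sd + model.s0).to_numpy()
        dists = {
            k: np.sum(
                (x.to_numpy() - model.class_centroids[k].to_numpy()) ** 2 / s**2
            )
            - 2 * np.log(model.priors[k])
            for k in model.classes
        }
        assert label == min(dists, key=dists.get)


class TestNscCv:
    def _separable(self, n=60, gap=6.0, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(20, n)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(n)],
        )
        half = n // 2
        X.iloc[:5, :half] += gap  # two clusters 6 SD apart on 5 genes
        labels = pd.Series(["A"] * half + ["B"] * (n - half), index=X.columns)
        return X, labels

    def test_separable_data_reaches_zero_error(self):
        X, labels = self._separable()
        cv = ns.nsc_cv(X, labels, seed=0)
        assert cv.cv_error.min() == 0.0

    def test_shuffled_labels_error_near_majority_rate(self):
        # under label shuffling CV error should hover around the majority rate
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(
                rng.normal(size=(15, 60)),
                index=[f"g{i}" for i in range(15)],
                columns=[f"s{i}" for i in range(60)],
            )
            labels = pd.Series(
                rng.permutation(["A"] * 30 + ["B"] * 30), index=X.columns
            )
            cv = ns.nsc_cv(X, labels, delta_grid=[0.0, 0.5, 1.0], seed=seed)
            errs.append(cv.cv_error.mean())
        assert abs(np.mean(errs) - 0.5) < 0.15

    def test_determinism_under_seed(self):
        X, labels = self._separable()
        cv1 = ns.nsc_cv(X, labels, seed=7)
        cv2 = ns.nsc_cv(X, labels, seed=7)
        assert cv1.chosen_delta == cv2.chosen_delta
        np.testing.assert_array_equal(cv1.cv_error, cv2.cv_error)
        np.testing.assert_array_equal(cv1.fold_errors, cv2.fold_errors)

    def test_chosen_delta_respects_rule(self):
        X, labels = self._separable()
        cv_min = ns.nsc_cv(X, labels, seed=0, rule="min")
        best = cv_min.cv_error.min()
        assert cv_min.cv_error[list(cv_min.delta_grid).index(cv_min.chosen_delta)] == best
        assert cv_min.chosen_delta == cv_min.delta_grid[cv_min.cv_error == best].max()
        cv_1se = ns.nsc_cv(X, labels, seed=0, rule="1se")
        assert cv_1se.chosen_delta >= cv_min.chosen_delta

    def test_empty_grid_raises(self):
        X, labels = self._separable()
        with pytest.raises(InvalidInputError):
            ns.nsc_cv(X, labels, delta_grid=[], seed=0)


class TestDeriveSignature:
    def test_directions_follow_event_class_elevation(self):
        X, labels = toy_instance()
        labels = labels.map({"A": "event", "B": "event_free"})
        model = ns.nsc_train(X, labels, delta=0.5)
        sig = ns.derive_signature(model, event_class="event")
        for g in sig.genes:
            elevated = (
                model.shrunken_centroids.loc[g.symbol, "event"]
                > model.overall_centroid.loc[g.symbol]
            )
            assert g.direction == ("poor" if elevated else "good")
        # g1 is planted higher in the event class
        assert dict((g.symbol, g.direction) for g in sig.genes)["g1"] == "poor"

    def test_no_surviving_genes_raises(self):
        X, labels = toy_instance()
        model0 = ns.nsc_train(X, labels, delta=0.0)
        model = ns.nsc_train(
            X, labels, delta=float(model0.d.abs().to_numpy().max()) + 1
        )
        with pytest.raises(EmptySignatureError):
            ns.derive_signature(model, event_class="A")


class TestOutcomeClasses:
    def test_classification_and_exclusion(self):
        from conftest import make_cohort

        c = make_cohort(
            [50.0, 130.0, 60.0, 121.0], [1, 0, 0, 1],
            ids=["a", "b", "c", "d"],
        )
        labels, excluded = ns.make_outcome_classes(c)
        assert labels.to_dict() == {"a": "event", "b": "event_free"}
        # c censored before 120 months -> excluded; d's event after 120 -> excluded
        assert sorted(excluded) == ["c", "d"]
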