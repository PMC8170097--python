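"""Leave-one-out evaluation, AUC, confusion decomposition, scenario grid."""

import numpy as np
import pandas as pd
import pytest

from speechmarkers import (ModelSpec, auc, confusion_summary, loocv_scores,
                           run_scenarios)
from speechmarkers.ml import SCENARIOS


def separable_frame(n_per_class=20, n_features=5, delta=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    X1 = rng.normal(delta, 1.0, size=(n_per_class, n_features))
    X = pd.DataFrame(np.vstack([X0, X1]),
                     columns=[f"f{i}" for i in range(n_features)])
    y = np.array(["HC"] * n_per_class + ["AD"] * n_per_class)
    return X, y


class TestLOOCV:
    def test_every_subject_held_out_once(self):
        X, y = separable_frame(n_per_class=6)
        scores, preds = loocv_scores(X, y, ModelSpec("LR"))
        assert len(scores) == len(preds) == len(y)

    def test_separable_cohort_high_auc(self):
        X, y = separable_frame()
        scores, _ = loocv_scores(X, y, ModelSpec("LR"))
        assert auc(scores, y) >= 0.95

    def test_single_class_fold_raises(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="single class"):
            loocv_scores(X, ["HC", "AD", "AD", "AD"], ModelSpec("LR"))

    def test_constant_feature_dropped_with_warning(self):
        X, y = separable_frame(n_per_class=5)
        X["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            scores, _ = loocv_scores(X, y, ModelSpec("LR"))
        assert np.all(np.isfinite(scores))

    def test_no_leakage_from_held_out_value(self):
        """A poisoned value in the held-out subject's fold-constant feature
        cannot change that subject's score (preprocessing is fitted on the
        training fold only)."""
        X, y = separable_frame(n_per_class=6)
        i = 3
        Xp = X.copy()
        Xp["poison"] = 0.0
        Xp.loc[Xp.index[i], "poison"] = 1e9
        with pytest.warns(UserWarning):
            scores_poisoned, _ = loocv_scores(Xp, y, ModelSpec("LR"))
        scores_clean, _ = loocv_scores(X, y, ModelSpec("LR"))
        # for fold i the poison feature is constant in training -> dropped
        assert scores_poisoned[i] == pytest.approx(scores_clean[i],
                                                   rel=1e-9)

    def test_median_imputation_handles_missing(self):
        X, y = separable_frame(n_per_class=6)
        X.iloc[2, 0] = np.nan
        scores, _ = loocv_scores(X, y, ModelSpec("SVM"))
        assert np.all(np.isfinite(scores))

    def test_models_reproducible(self):
        X, y = separable_frame(n_per_class=5)
        for kind in ("LR", "SVM", "MLP"):
            s1, p1 = loocv_scores(X, y, ModelSpec(kind), seed=7)
            s2, p2 = loocv_scores(X, y, ModelSpec(kind), seed=7)
            assert np.array_equal(s1, s2)
            assert np.array_equal(p1, p2)


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_agrees_with_concordant_pair_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q)
                       for p in pos for q in neg)
            assert auc(scores, labels) == pytest.approx(
                conc / (len(pos) * len(neg)), abs=1e-12)


class TestConfusionSummary:
    def _from_matrix(self, tp, fp, tn, fn, lang):
        preds = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        labels = ["AD"] * tp + ["HC"] * fp + ["HC"] * tn + ["AD"] * fn
        tags = [lang] * (tp + fp + tn + fn)
        return preds, labels, tags

    def test_published_style_matrices(self):
        # overall matrix 58/16/61/18 -> 22.22% error
        preds, labels, tags = self._from_matrix(58, 16, 61, 18, "en")
        out = confusion_summary(preds, labels, tags)
        assert out["overall"]["error_rate"] == 22.22
        # a 15/3/22/7 block -> 21.28% error, 30% of errors false positive
        preds, labels, tags = self._from_matrix(15, 3, 22, 7, "fr")
        out = confusion_summary(preds, labels, tags)
        assert out["overall"]["error_rate"] == 21.28
        assert out["overall"]["fp_share"] == 30.0

    def test_perfect_predictions(self):
        preds, labels, tags = self._from_matrix(5, 0, 5, 0, "en")
        out = confusion_summary(preds, labels, tags)
        assert out["overall"]["error_rate"] == 0.0
        assert out["overall"]["FP"] == out["overall"]["FN"] == 0

    def test_per_language_sums_to_overall(self):
        rng = np.random.default_rng(5)
        preds = rng.integers(0, 2, 40)
        labels = np.where(rng.integers(0, 2, 40), "AD", "HC")
        tags = np.where(rng.integers(0, 2, 40), "en", "fr")
        out = confusion_summary(preds, labels, tags)
        for cell in ("TP", "FP", "TN", "FN"):
            assert sum(m[cell] for m in out["per_language"].values()) == \
                out["overall"][cell]

    def test_unknown_language_raises(self):
        with pytest.raises(ValueError, match="de"):
            confusion_summary([1], ["AD"], ["de"])


@pytest.fixture(scope="module")
def grid():
    rng = np.random.default_rng(2)
    n = 10  # per group per language
    rows, labels, langs, ages = [], [], [], []
    for lang in ("en", "fr"):
        for grp in ("HC", "AD"):
            for _ in range(n):
                shift = 2.0 if grp == "AD" else 0.0
                rows.append(rng.normal(shift, 1.0, size=6))
                labels.append(grp)
                langs.append(lang)
                ages.append(rng.normal(70, 5))
    cols = ["sem1", "sem2", "syn1", "par1", "par2", "task1"]
    registry = {"sem1": "semantic", "sem2": "semantic",
                "syn1": "syntactic", "par1": "paralinguistic",
                "par2": "paralinguistic", "task1": "task"}
    X = pd.DataFrame(rows, columns=cols)
    selection = {"sem1", "sem2"}
    return run_scenarios(X, labels, langs, registry,
                         selection=selection, ages=ages, seed=0)


class TestRunScenarios:
    def test_grid_is_24_runs(self, grid):
        assert len(grid) == 24
        assert {r.scenario_id for r in grid} == {s[0] for s in SCENARIOS}

    def test_generalizable_uses_fewer_features(self, grid):
        by_id = {(r.scenario_id, r.model): r for r in grid}
        for lang in ("en", "fr", "multi"):
            assert by_id[(f"{lang}_generalizable", "LR")].n_features < \
                by_id[(f"{lang}_language_all", "LR")].n_features

    def test_per_language_matrices_sum(self, grid):
        for r in grid:
            if not r.confusion:
                continue
            for cell in ("TP", "FP", "TN", "FN"):
                assert sum(m[cell]
                           for m in r.confusion["per_language"].values()) \
                    == r.confusion["overall"][cell]

    def test_language_tag_never_a_feature(self, grid):
        for r in grid:
            assert r.n_features <= 7  # features + age only, never the tag


class TestNestedSelection:
    def test_per_fold_selection_runs_and_scores_everyone(self):
        from speechmarkers.ml import loocv_scores_nested
        rng = np.random.default_rng(8)
        n = 8
        rows, labels, langs = [], [], []
        for lang in ("en", "fr"):
            for grp in ("HC", "AD"):
                for _ in range(n):
                    shift = 2.5 if grp == "AD" else 0.0
                    rows.append(rng.normal(shift, 1.0, size=4))
                    labels.append(grp)
                    langs.append(lang)
        X = pd.DataFrame(rows, columns=["s1", "s2", "p1", "t1"])
        registry = {"s1": "semantic", "s2": "semantic",
                    "p1": "paralinguistic", "t1": "task"}
        mask = np.array([l == "en" for l in langs])
        scores, preds = loocv_scores_nested(
            X, labels, langs, registry, scenario_mask=mask,
            spec=ModelSpec("LR"))
        assert len(scores) == mask.sum()
        assert auc(scores, np.asarray(labels)[mask]) >= 0.9
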