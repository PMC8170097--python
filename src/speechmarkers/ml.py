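"""Leave-one-out classification experiments with per-language error
decomposition.

Three classifier families are evaluated: L2 logistic regression (LR), an
RBF support vector machine (SVM), and a one-hidden-layer multilayer
perceptron with logistic activation and alpha = 0.01 (MLP); other
hyperparameters stay at library defaults.  Under leave-one-out
cross-validation each subject is held out once; per fold, missing values
are imputed with training-fold medians, constant features dropped, and
features standardized to training-fold mean 0 / sd 1 before fitting
(scale-sensitive models require it; fitting these transforms on the
training fold only avoids leakage).  AUC is computed once from the pooled
held-out scores — with a single test sample per fold a per-fold AUC is
undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "ModelSpec", "ExperimentResult", "loocv_scores", "auc",
    "confusion_summary", "run_scenarios", "SCENARIOS",
]


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family and its fixed hyperparameters."""

    kind: str  # "LR" | "SVM" | "MLP"

    def build(self, seed: int = 0):
        if self.kind == "LR":
            return LogisticRegression(penalty="l2", C=1.0, max_iter=2000)
        if self.kind == "SVM":
            return SVC(kernel="rbf", C=1.0)
        if self.kind == "MLP":
            return MLPClassifier(hidden_layer_sizes=(100,),
                                 activation="logistic", alpha=0.01,
                                 random_state=seed)
        raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def probabilistic(self) -> bool:
        return self.kind in ("LR", "MLP")


@dataclass
class ExperimentResult:
    scenario_id: str
    model: str
    auc: float
    confusion: dict
    n_subjects: int
    n_features: int
    note: str = ""


def _to_indicator(labels: Sequence) -> np.ndarray:
    return np.asarray([1 if l in (1, "AD") else 0 for l in labels])


def loocv_scores(features: pd.DataFrame, labels: Sequence,
                 spec: ModelSpec, seed: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled held-out decision scores and hard predictions, one per subject.

    Raises if any training fold contains a single class.  Constant features
    in a fold are dropped for that fold with a warning.
    """
    X = features.to_numpy(dtype=float)
    y = _to_indicator(labels)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects for leave-one-out")
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    warned_constant = False
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"training fold {i} contains a single class")
        med = np.nanmedian(Xtr, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        Xtr = np.where(np.isnan(Xtr), med, Xtr)
        xte = np.where(np.isnan(X[i]), med, X[i])
        sd = Xtr.std(axis=0)
        keep = sd > 0
        if not keep.all() and not warned_constant:
            warnings.warn("constant feature(s) dropped within a fold",
                          stacklevel=2)
            warned_constant = True
        mu = Xtr.mean(axis=0)
        sd = np.where(keep, sd, 1.0)
        Xtr = (Xtr[:, keep] - mu[keep]) / sd[keep]
        xte = ((xte - mu) / sd)[keep]
        model = spec.build(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        if spec.probabilistic:
            s = float(model.predict_proba(xte[None, :])[0, 1])
            preds[i] = int(s >= 0.5)
        else:
            s = float(model.decision_function(xte[None, :])[0])
            preds[i] = int(s >= 0.0)
        scores[i] = s
    return scores, preds


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based AUC (normalized Mann-Whitney U; ties count 1/2)."""
    y = _to_indicator(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _matrix(preds: np.ndarray, y: np.ndarray) -> dict:
    tp = int(((preds == 1) & (y == 1)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    n = tp + fp + tn + fn
    out = {"TP": tp, "FP": fp, "TN": tn, "FN": fn, "n": n,
           "error_rate": round(100.0 * (fp + fn) / n, 2) if n else np.nan}
    errors = fp + fn
    out["fp_share"] = round(100.0 * fp / errors, 2) if errors else np.nan
    return out


def confusion_summary(predictions: Sequence[int], labels: Sequence,
                      language_tags: Sequence[str]) -> dict:
    """Overall and per-language 2x2 confusion matrices (AD positive).

    ``error_rate`` is a percentage to two decimals; ``fp_share`` is the
    percentage of that stratum's errors that are false positives.
    """
    preds = np.asarray(predictions, dtype=int)
    y = _to_indicator(labels)
    tags = np.asarray(language_tags)
    if not (len(preds) == len(y) == len(tags)):
        raise ValueError("inputs must have equal length")
    known = {"en", "fr"}
    unknown = set(tags) - known
    if unknown:
        raise ValueError(f"unknown language tag(s): {sorted(unknown)}")
    out = {"overall": _matrix(preds, y), "per_language": {}}
    for lang in sorted(set(tags)):
        sel = tags == lang
        out["per_language"][lang] = _matrix(preds[sel], y[sel])
    return out


def loocv_scores_nested(features: pd.DataFrame, labels: Sequence,
                        languages: Sequence[str],
                        registry: Mapping[str, str],
                        scenario_mask: np.ndarray, spec: ModelSpec,
                        alpha: float = 0.05, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """LOOCV with the generalizable-feature selection re-computed inside
    each fold.

    The default protocol selects features once on the full cohort before
    cross-validation; this variant removes that leak by screening on all
    subjects except the held-out one (rows outside the scenario are never
    held out, so they always participate in screening).  Returns pooled
    scores/predictions for the subjects in ``scenario_mask``, in row
    order.
    """
    from .xlingual import build_stats_table, select_generalizable

    labels_all = np.asarray(labels)
    tags = np.asarray(languages)
    idx = np.flatnonzero(scenario_mask)
    scores = np.empty(len(idx))
    preds = np.empty(len(idx), dtype=int)
    for k, i in enumerate(idx):
        screen = np.ones(len(labels_all), dtype=bool)
        screen[i] = False
        rows = {}
        for lang in ("en", "fr"):
            sel = screen & (tags == lang)
            rows[lang] = build_stats_table(
                features.loc[sel], labels_all[sel], lang,
                registry=registry)
        cols = sorted(select_generalizable(
            rows["en"], rows["fr"], registry, alpha=alpha).selected)
        if not cols:
            raise ValueError(f"empty nested selection at fold {i}")
        fold_mask = scenario_mask.copy()
        sub = features.loc[fold_mask, cols]
        sub_labels = labels_all[fold_mask]
        # position of subject i within the scenario rows
        pos = int(np.searchsorted(idx, i))
        s, p = _single_fold(sub.to_numpy(dtype=float),
                            _to_indicator(sub_labels), pos, spec, seed)
        scores[k], preds[k] = s, p
    return scores, preds


def _single_fold(X: np.ndarray, y: np.ndarray, i: int, spec: ModelSpec,
                 seed: int) -> tuple[float, int]:
    mask = np.ones(len(y), dtype=bool)
    mask[i] = False
    Xtr, ytr = X[mask], y[mask]
    if len(np.unique(ytr)) < 2:
        raise ValueError("training fold contains a single class")
    med = np.nanmedian(Xtr, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    Xtr = np.where(np.isnan(Xtr), med, Xtr)
    xte = np.where(np.isnan(X[i]), med, X[i])
    sd = Xtr.std(axis=0)
    keep = sd > 0
    mu = Xtr.mean(axis=0)
    sd = np.where(keep, sd, 1.0)
    Xtr = (Xtr[:, keep] - mu[keep]) / sd[keep]
    xte = ((xte - mu) / sd)[keep]
    model = spec.build(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xtr, ytr)
    if spec.probabilistic:
        s = float(model.predict_proba(xte[None, :])[0, 1])
        return s, int(s >= 0.5)
    s = float(model.decision_function(xte[None, :])[0])
    return s, int(s >= 0.0)


#: scenario grid: (scenario_id, language filter, feature-set rule)
SCENARIOS = (
    ("en_language_all", "en", "language"),
    ("fr_language_all", "fr", "language"),
    ("multi_language_all", "multi", "language"),
    ("en_generalizable", "en", "generalizable"),
    ("fr_generalizable", "fr", "generalizable"),
    ("multi_generalizable", "multi", "generalizable"),
    ("en_all_subgroups_baseline", "en", "all"),
    ("multi_age_baseline", "multi", "age"),
)

_LANGUAGE_SUBGROUPS = ("semantic", "syntactic", "paralinguistic")


def _feature_columns(rule: str, registry: Mapping[str, str],
                     selection: Optional[set[str]],
                     columns: Sequence[str]) -> list[str]:
    if rule == "language":
        return [c for c in columns
                if registry.get(c) in _LANGUAGE_SUBGROUPS]
    if rule == "all":
        return [c for c in columns if c in registry]
    if rule == "generalizable":
        return [c for c in columns if selection and c in selection]
    if rule == "age":
        return ["age"]
    raise ValueError(rule)


def run_scenarios(features: pd.DataFrame, labels: Sequence,
                  languages: Sequence[str], registry: Mapping[str, str],
                  selection: Optional[set[str]] = None,
                  ages: Optional[Sequence[float]] = None,
                  models: Sequence[str] = ("LR", "SVM", "MLP"),
                  nested: bool = False, alpha: float = 0.05,
                  seed: int = 0) -> list[ExperimentResult]:
    """The 8-scenario x 3-model experiment grid (24 results).

    Scenarios: {EN, FR, multilingual} x {all language features,
    generalizable features}, an English all-subgroups baseline, and a
    multilingual age-only baseline.  "Language features" are the semantic,
    syntactic and paralinguistic subgroups; the language tag is never a
    model input, only an error-decomposition key.
    """
    labels = np.asarray([l if isinstance(l, str) else ("AD" if l else "HC")
                         for l in labels])
    tags = np.asarray(languages)
    table = features.copy()
    if ages is not None and "age" not in table.columns:
        table = table.assign(age=np.asarray(ages, dtype=float))
    results: list[ExperimentResult] = []
    for scenario_id, lang, rule in SCENARIOS:
        sel = np.ones(len(labels), dtype=bool) if lang == "multi" \
            else tags == lang
        cols = _feature_columns(rule, registry, selection, table.columns)
        if rule == "age" and "age" not in table.columns:
            cols = []
        for kind in models:
            if not cols:
                results.append(ExperimentResult(
                    scenario_id, kind, np.nan, {}, int(sel.sum()), 0,
                    note="skipped: empty feature set"))
                continue
            spec = ModelSpec(kind)
            note = ""
            if nested and rule == "generalizable":
                reg_cols = [c for c in table.columns if c in registry]
                scores, preds = loocv_scores_nested(
                    table[reg_cols], labels, tags, registry,
                    scenario_mask=sel, spec=spec, alpha=alpha, seed=seed)
                note = "nested per-fold selection"
                n_feats = -1  # varies per fold
            else:
                scores, preds = loocv_scores(table.loc[sel, cols],
                                             labels[sel], spec, seed=seed)
                n_feats = len(cols)
            results.append(ExperimentResult(
                scenario_id, kind,
                auc(scores, labels[sel]),
                confusion_summary(preds, labels[sel], tags[sel]),
                int(sel.sum()), n_feats, note=note))
    return results
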