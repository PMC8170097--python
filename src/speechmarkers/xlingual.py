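"""Per-language inferential statistics and generalizable-feature selection.

Each feature is screened in each language with a tie-corrected
Kruskal–Wallis H test (two groups, so H is chi-square distributed with one
degree of freedom), reported raw and Bonferroni-adjusted, alongside a
point-biserial correlation with the AD/HC indicator as a cross-language
comparable effect size.  A feature is *generalizable* when its uncorrected
p-value is below alpha in both languages and it is not a task-specific
feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FeatureStats", "SelectionResult", "kruskal_wallis_h",
    "bonferroni_adjust", "point_biserial", "build_stats_table",
    "select_generalizable",
]


@dataclass
class FeatureStats:
    """One feature's per-language screening row (Table-style schema)."""

    feature_name: str
    language: str
    subgroup: str = ""
    r_pb: float = np.nan
    m_HC: float = np.nan
    m_AD: float = np.nan
    H: float = np.nan
    p: float = np.nan
    p_corr: float = np.nan
    n_HC: int = 0
    n_AD: int = 0

    @property
    def significant_uncorrected(self) -> bool:
        return bool(self.p < 0.05)

    @property
    def significant_corrected(self) -> bool:
        return bool(self.p_corr < 0.05)


@dataclass
class SelectionResult:
    selected: set[str] = field(default_factory=set)
    alpha: float = 0.05
    excluded_task_count: int = 0


def _two_groups(values: Sequence[float], groups: Sequence[int]):
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    return v[g == 0], v[g == 1]


def kruskal_wallis_h(values: Sequence[float],
                     groups: Sequence[int]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square(1) p-value.

    ``groups`` is a 0/1 indicator (HC=0, AD=1).  Missing values are
    dropped; each group must retain at least two observations.
    """
    a, b = _two_groups(values, groups)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0  # all values tied
    h, p = sps.kruskal(a, b)
    return float(h), float(p)


def bonferroni_adjust(p: float, m: int) -> float:
    """Family-wise adjusted probability min(1, p*m)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def point_biserial(values: Sequence[float],
                   groups: Sequence[int]) -> float:
    """Pearson correlation between the values and the 0/1 group indicator."""
    a, b = _two_groups(values, groups)
    v = np.concatenate([a, b])
    g = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(v) == 0:
        warnings.warn("constant feature: point-biserial undefined",
                      stacklevel=2)
        return np.nan
    return float(np.corrcoef(v, g)[0, 1])


def build_stats_table(features: pd.DataFrame, labels: Sequence[str],
                      language: str,
                      registry: Optional[Mapping[str, str]] = None,
                      bonferroni_m: Optional[int] = None
                      ) -> list[FeatureStats]:
    """Screen every feature column of *features* for one language cohort.

    *labels* holds "HC"/"AD" per row.  The Bonferroni multiplier defaults
    to the number of screened features (the runtime registry size); pass
    ``bonferroni_m`` to override (e.g. to mirror an externally fixed test
    count).
    """
    if features.shape[1] == 0:
        raise ValueError("feature table has no columns")
    y = np.asarray([1 if l == "AD" else 0 for l in labels])
    m = bonferroni_m if bonferroni_m is not None else features.shape[1]
    rows: list[FeatureStats] = []
    for name in features.columns:
        v = features[name].to_numpy(dtype=float)
        a, b = _two_groups(v, y)
        st = FeatureStats(
            feature_name=name, language=language,
            subgroup=(registry or {}).get(name, ""),
            n_HC=len(a), n_AD=len(b))
        if len(a) >= 2 and len(b) >= 2:
            st.m_HC = float(np.mean(a))
            st.m_AD = float(np.mean(b))
            if np.ptp(np.concatenate([a, b])) == 0:
                st.H, st.p = 0.0, 1.0
                st.r_pb = np.nan
            else:
                st.H, st.p = kruskal_wallis_h(v, y)
                st.r_pb = point_biserial(v, y)
            st.p_corr = bonferroni_adjust(st.p, m)
        rows.append(st)
    return rows


def stats_to_frame(rows: Sequence[FeatureStats]) -> pd.DataFrame:
    """Tabular view of screening rows (one row per feature per language)."""
    return pd.DataFrame([{
        "feature": r.feature_name, "subgroup": r.subgroup,
        "language": r.language, "r_pb": r.r_pb, "m_HC": r.m_HC,
        "m_AD": r.m_AD, "H": r.H, "p": r.p, "p_corr": r.p_corr,
        "significant_uncorrected": r.significant_uncorrected,
        "significant_corrected": r.significant_corrected,
    } for r in rows])


def select_generalizable(stats_en: Sequence[FeatureStats],
                         stats_fr: Sequence[FeatureStats],
                         registry: Mapping[str, str],
                         alpha: float = 0.05) -> SelectionResult:
    """Features with uncorrected p < alpha in BOTH languages, excluding the
    task-specific subgroup."""
    en = {r.feature_name: r for r in stats_en}
    fr = {r.feature_name: r for r in stats_fr}
    if set(en) != set(fr):
        diff = sorted(set(en) ^ set(fr))
        raise ValueError(f"mismatched feature universes: {diff}")
    selected: set[str] = set()
    excluded_task = 0
    for name, r_en in en.items():
        r_fr = fr[name]
        if not (r_en.p < alpha and r_fr.p < alpha):
            continue
        if registry.get(name) == "task":
            excluded_task += 1
            continue
        selected.add(name)
    return SelectionResult(selected=selected, alpha=alpha,
                           excluded_task_count=excluded_task)
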