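"""Cohort-level analyses: predictive-value tables, correspondence analysis,
and auxiliary group statistics.

Two binary predictors of the dementia outcome (conversion to DLB vs AD) are
evaluated against the observed three-class outcome (MCI-DLB / MCI-NC /
MCI-AD): the EEG predictor (pattern 1 at admission predicts AD, any other
pattern predicts DLB) and the clinical predictor (presence of a core or
suggestive DLB feature at admission predicts DLB).  Neither predictor ever
predicts non-conversion, so the predicted-NC column of every confusion
matrix is structurally zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .classify import PatternLabel, predict_outcome

OUTCOME_CLASSES = ("MCI-DLB", "MCI-NC", "MCI-AD")

#: Outcome group predicted by each EEG-predictor output.
_GROUP_OF = {"DLB-like": "MCI-DLB", "AD-like": "MCI-AD"}


def _round1(x: float) -> float:
    """Half-up rounding to one decimal, the convention of clinical tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionSummary:
    """Observed x predicted counts with per-class and overall percent correct.

    ``per_class_correct`` and ``overall_correct`` are unrounded;
    ``report()`` renders the one-decimal table.  ``predicted_share`` gives
    each predicted class's percentage of all subjects (the bottom row of a
    predictive-value table).
    """

    matrix: pd.DataFrame
    per_class_correct: dict
    overall_correct: float
    predicted_share: dict

    def report(self) -> pd.DataFrame:
        out = self.matrix.copy().astype(object)
        out["correct_pct"] = [
            _round1(self.per_class_correct[c]) for c in self.matrix.index
        ]
        bottom = {c: _round1(self.predicted_share[c]) for c in self.matrix.columns}
        bottom["correct_pct"] = _round1(self.overall_correct)
        out.loc["overall_pct"] = pd.Series(bottom)
        return out


def confusion(observed, predicted, classes=OUTCOME_CLASSES) -> ConfusionSummary:
    """Exact confusion counts and percent-correct summaries."""
    observed = list(observed)
    predicted = list(predicted)
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted must have equal length")
    classes = tuple(classes)
    bad = (set(observed) | set(predicted)) - set(classes)
    if bad:
        raise ValueError(f"labels outside class order: {sorted(bad)}")
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for o, p in zip(observed, predicted):
        mat.loc[o, p] += 1
    per_class = {}
    for c in classes:
        row_sum = int(mat.loc[c].sum())
        per_class[c] = 100.0 * mat.loc[c, c] / row_sum if row_sum else float("nan")
    total = len(observed)
    overall = 100.0 * sum(int(mat.loc[c, c]) for c in classes) / total
    share = {c: 100.0 * int(mat[c].sum()) / total for c in classes}
    return ConfusionSummary(
        matrix=mat,
        per_class_correct=per_class,
        overall_correct=overall,
        predicted_share=share,
    )


def eeg_predictor(cohort: pd.DataFrame) -> pd.Series:
    """Predicted outcome group from the EEG pattern at admission."""
    if cohort["pattern"].isna().any():
        raise ValueError("every subject needs an onset pattern")
    preds = [
        _GROUP_OF[predict_outcome(PatternLabel(str(p))).predicted_group]
        for p in cohort["pattern"]
    ]
    return pd.Series(preds, index=cohort.index, name="predicted_group")


def clinical_predictor(cohort: pd.DataFrame,
                       flag_column: str = "has_dlb_feature") -> pd.Series:
    """Predicted outcome group from the early-DLB clinical-feature flag."""
    if flag_column not in cohort or cohort[flag_column].isna().any():
        raise ValueError(f"every subject needs the {flag_column!r} flag")
    preds = np.where(cohort[flag_column].astype(bool), "MCI-DLB", "MCI-AD")
    return pd.Series(preds, index=cohort.index, name="predicted_group")


def abnormal_eeg_conversion_rate(cohort: pd.DataFrame) -> float:
    """Fraction of abnormal-EEG subjects whose observed outcome is MCI-DLB."""
    if "abnormal" not in cohort or "group" not in cohort:
        raise ValueError("cohort needs 'abnormal' and 'group' columns")
    abnormal = cohort[cohort["abnormal"].astype(bool)]
    if len(abnormal) == 0:
        raise ZeroDivisionError("no abnormal-EEG subjects: rate undefined")
    return float((abnormal["group"] == "MCI-DLB").mean())


# --------------------------------------------------------------------------
# Correspondence analysis
# --------------------------------------------------------------------------

@dataclass
class CAResult:
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    total_inertia: float


def correspondence_analysis(table: pd.DataFrame, n_components: int = 2) -> CAResult:
    """Simple correspondence analysis of a two-way contingency table.

    Counts are scaled to the correspondence matrix, standardized residuals
    are decomposed by SVD, and rows/columns are returned in principal
    coordinates for the leading dimensions.  Total inertia equals the
    Pearson chi-square statistic divided by the grand total.  Rows or
    columns with a zero margin are dropped with a warning.
    """
    tab = pd.DataFrame(table).astype(float)
    if (tab.values < 0).any():
        raise ValueError("contingency counts must be non-negative")
    zero_rows = tab.index[tab.sum(axis=1) == 0]
    zero_cols = tab.columns[tab.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping zero-margin rows {list(zero_rows)} / columns {list(zero_cols)}",
            UserWarning,
            stacklevel=2,
        )
        tab = tab.drop(index=zero_rows, columns=zero_cols)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns with positive margins")
    n = tab.values.sum()
    p = tab.values / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    s = (p - expected) / np.sqrt(expected)
    u, sig, vt = np.linalg.svd(s, full_matrices=False)
    k = min(n_components, sig.size)
    f = (u[:, :k] * sig[:k]) / np.sqrt(r)[:, None]
    g = (vt[:k].T * sig[:k]) / np.sqrt(c)[:, None]
    dims = [f"dim{i + 1}" for i in range(k)]
    return CAResult(
        row_coords=pd.DataFrame(f, index=tab.index, columns=dims),
        col_coords=pd.DataFrame(g, index=tab.columns, columns=dims),
        singular_values=sig,
        total_inertia=float(np.sum(sig**2)),
    )


def pattern_outcome_table(cohort: pd.DataFrame,
                          merge_unstable_alpha: bool = True) -> pd.DataFrame:
    """Pattern x outcome contingency table for correspondence analysis.

    ``merge_unstable_alpha`` pools patterns 1plus and 2 (both unstable-alpha
    variants) into one row, the grouping used for the two-dimensional
    pattern/outcome map.
    """
    pat = cohort["pattern"].astype(str)
    if merge_unstable_alpha:
        pat = pat.replace({"1plus": "1plus+2", "2": "1plus+2"})
    return pd.crosstab(pat, cohort["group"])


# --------------------------------------------------------------------------
# Auxiliary statistics (supporting plumbing over scipy.stats)
# --------------------------------------------------------------------------

def group_compare(values_by_group: dict) -> dict:
    """One-way ANOVA (with Bonferroni-adjusted pairwise Welch t tests) and
    a Kruskal-Wallis cross-check over >= 2 groups of continuous values."""
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    f, p = stats.f_oneway(*arrays)
    h, pk = stats.kruskal(*arrays)
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, pt = stats.ttest_ind(arrays[i], arrays[j])
            pairwise[(names[i], names[j])] = {
                "t": float(t),
                "p_bonferroni": float(min(1.0, pt * n_pairs)),
            }
    return {
        "anova": {"F": float(f), "p": float(p)},
        "kruskal": {"H": float(h), "p": float(pk)},
        "pairwise": pairwise,
    }


def spearman(x, y) -> dict:
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


def fisher_2x2(table) -> dict:
    odds, p = stats.fisher_exact(np.asarray(table))
    return {"odds_ratio": float(odds), "p": float(p)}
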