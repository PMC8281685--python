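"""Association statistics linking risk scores to clinical and immune features.

Fisher's exact test for 2x2 clinical contingency tables, Pearson correlation
for continuous feature associations, and a two-group Wilcoxon rank-sum
comparison for per-group feature levels (e.g. immune-cell fractions).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fisher_exact_2x2",
    "pearson_corr",
    "group_compare",
    "associate_features",
]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    The two-sided p is the total hypergeometric probability (margins fixed)
    of all tables at most as probable as the observed one.  A table with a
    zero margin carries no information: p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative count in contingency table")
    if t.sum() == 0:
        raise ValueError("empty contingency table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table: p = 1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided t-test p-value.

    p is based on t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def group_compare(values, groups) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a two-level grouping.

    Uses the exact null distribution when both groups have at most 10
    observations and the data contain no ties, and the normal approximation
    with tie correction otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {len(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a group is empty")
    no_ties = len(np.unique(values)) == len(values)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method)[1])


def associate_features(
    scores: pd.Series, features: pd.DataFrame, fdr: bool = False
) -> pd.DataFrame:
    """Risk-score vs feature correlations, one (r, p) row per feature column.

    Sample alignment is by index intersection.  With ``fdr=True`` a
    Benjamini-Hochberg adjusted ``q`` column is appended; by default the raw
    per-feature p-values are reported without multiplicity adjustment.
    """
    common = scores.index.intersection(features.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between scores and features")
    rows = []
    for col in features.columns:
        r, p = pearson_corr(scores.loc[common], features.loc[common, col])
        rows.append((col, r, p))
    out = pd.DataFrame(rows, columns=["feature", "r", "p"]).set_index("feature")
    if fdr:
        p = out["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            q[i] = running
        out["q"] = q
    return out
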