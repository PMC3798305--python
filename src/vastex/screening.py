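"""Per-feature group comparison with FDR-corrected significance.

Every feature is compared between the two classes with a pooled-variance
two-sample Student's t-test; the 19 p-values are corrected together by the
Benjamini-Hochberg step-up procedure at q = 0.05.  By default the test
operates on per-subject feature means (one value per animal), which is the
unit of replication of the study design this mirrors; ``per_subject=False``
tests per-ROI values instead, and ``train_only=True`` restricts to the
training split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ABNORMAL, NORMAL, TRAIN
from .texture import FEATURE_NAMES


def two_sample_t(x, y) -> tuple[float, float]:
    """Classical pooled-variance Student's t-test, two-sided.

    Degenerate zero-variance input returns p = 1 for equal group means and
    p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
    if pooled == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return np.inf if x.mean() > y.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class ScreeningResult:
    """Feature-wise group statistics and the FDR-selected feature subset."""

    table: pd.DataFrame          # per feature: means, SDs, t, p, significant
    selected: list[str]          # significant features, fixed report order
    q: float

    def __repr__(self) -> str:
        return (f"ScreeningResult(q={self.q}, selected={len(self.selected)}/"
                f"{len(self.table)})")


def screen(
    features: pd.DataFrame,
    q: float = 0.05,
    per_subject: bool = True,
    train_only: bool = False,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> ScreeningResult:
    """Screen all features for class separation; returns the selected subset.

    ``features`` is a per-ROI table with columns ``subject``, ``class``,
    ``role`` and one column per feature.
    """
    df = features
    if train_only:
        df = df[df["role"] == TRAIN]
    if per_subject:
        df = df.groupby(["subject", "class"], as_index=False)[
            list(feature_names)].mean()
    labels = df["class"]
    if set(labels.unique()) != {NORMAL, ABNORMAL}:
        raise ValueError("screening requires both classes to be present")
    g1 = df[labels == NORMAL]
    g2 = df[labels == ABNORMAL]
    rows = []
    for feat in feature_names:
        t, p = two_sample_t(g1[feat], g2[feat])
        rows.append({
            "feature": feat,
            "normal_mean": g1[feat].mean(), "normal_sd": g1[feat].std(ddof=1),
            "abnormal_mean": g2[feat].mean(), "abnormal_sd": g2[feat].std(ddof=1),
            "t": t, "p": p,
        })
    table = pd.DataFrame(rows).set_index("feature")
    table["significant"] = bh_fdr(table["p"].to_numpy(), q=q)
    selected = [f for f in feature_names if bool(table.loc[f, "significant"])]
    return ScreeningResult(table=table, selected=selected, q=q)
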