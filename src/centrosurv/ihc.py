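"""Immunohistochemistry weighted-index (WI) scoring.

Staining intensity is scored 0 (none) to 3 (high); the percentage of
positive cells (intensity >= 1) is pooled over all scored fields of a
tissue; the weighted index is intensity score x percent positive, so it
ranges over [0, 300].  When no pathologist-assigned intensity score is
supplied, the modal intensity among positive cells stands in for it
(ties broken toward the higher intensity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INTENSITY_COLUMNS",
    "WeightedIndex",
    "GroupComparison",
    "percent_positive",
    "weighted_index",
    "score_ihc_table",
    "compare_wi_groups",
    "read_field_counts",
]

INTENSITY_COLUMNS = ["n_int0", "n_int1", "n_int2", "n_int3"]


def _pool_counts(fields) -> np.ndarray:
    """Pool per-field intensity counts (rows) into a length-4 vector."""
    if isinstance(fields, pd.DataFrame):
        missing = [c for c in INTENSITY_COLUMNS if c not in fields.columns]
        if missing:
            raise ValueError(f"field table lacks columns {missing}")
        counts = fields[INTENSITY_COLUMNS].to_numpy(dtype=float)
    else:
        counts = np.atleast_2d(np.asarray(fields, dtype=float))
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("expected one row of 4 intensity counts per field")
    if counts.shape[0] == 0:
        raise ValueError("at least one field is required")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("every field must contain at least one cell")
    return counts.sum(axis=0)


def percent_positive(fields) -> float:
    """Percentage of cells with staining intensity >= 1, pooled over fields."""
    pooled = _pool_counts(fields)
    total = pooled.sum()
    if total == 0:
        raise ValueError("zero total cells")
    return float(100.0 * pooled[1:].sum() / total)


def _modal_positive_intensity(pooled: np.ndarray) -> int:
    """Modal intensity among positive cells; ties broken upward."""
    pos = pooled[1:]
    if pos.sum() == 0:
        return 0
    best = pos.max()
    # highest intensity achieving the maximal count
    return int(3 - np.argmax(pos[::-1] == best))


@dataclass
class WeightedIndex:
    tissue_id: str
    intensity_score: int
    percent_positive: float
    wi: float
    n_fields: int
    n_cells: int


def weighted_index(fields, intensity_score: int | None = None,
                   tissue_id: str = "") -> WeightedIndex:
    """WI = intensity score x percent positive, on pooled field counts.

    ``intensity_score`` may be supplied (the pathologist's per-tissue
    call) or derived as the modal intensity among positive cells.
    """
    pooled = _pool_counts(fields)
    pct = percent_positive(fields)
    if intensity_score is None:
        intensity_score = _modal_positive_intensity(pooled)
    intensity_score = int(intensity_score)
    if intensity_score not in (0, 1, 2, 3):
        raise ValueError(
            f"intensity_score must be in {{0,1,2,3}}, got {intensity_score}"
        )
    n_fields = len(fields) if not isinstance(fields, pd.DataFrame) \
        else fields.shape[0]
    return WeightedIndex(
        tissue_id=tissue_id,
        intensity_score=intensity_score,
        percent_positive=pct,
        wi=intensity_score * pct,
        n_fields=int(n_fields),
        n_cells=int(pooled.sum()),
    )


def score_ihc_table(field_table: pd.DataFrame,
                    intensity_scores: dict | None = None) -> pd.DataFrame:
    """Score every tissue in a tidy field-count table.

    ``field_table`` columns: tissue_id, field_id, n_int0..n_int3 (extra
    columns such as grade are carried through, first value per tissue).
    ``intensity_scores`` optionally maps tissue_id to a fixed score.
    """
    if "tissue_id" not in field_table.columns:
        raise ValueError("field table needs a tissue_id column")
    rows = []
    carry = [c for c in field_table.columns
             if c not in INTENSITY_COLUMNS + ["tissue_id", "field_id"]]
    for tid, grp in field_table.groupby("tissue_id", sort=True):
        score = None if intensity_scores is None else intensity_scores.get(tid)
        w = weighted_index(grp, intensity_score=score, tissue_id=str(tid))
        row = {
            "tissue_id": w.tissue_id,
            "intensity_score": w.intensity_score,
            "percent_positive": w.percent_positive,
            "wi": w.wi,
            "n_fields": w.n_fields,
            "n_cells": w.n_cells,
        }
        for c in carry:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    group_labels: list
    group_means: dict
    test: str                   # "t-test" or "anova"
    test_statistic: float
    p_value: float
    pairwise_adjusted_p: pd.DataFrame | None   # Tukey HSD, one row per pair
    significant: bool


def compare_wi_groups(wi_values, labels) -> GroupComparison:
    """Compare weighted indices across tissue groups.

    Two groups: two-tailed Student's t-test.  More: one-way ANOVA
    followed by Tukey's HSD for pairwise adjusted p-values.  Significance
    is declared at p < 0.05.
    """
    wi = np.asarray(wi_values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if wi.size != labels.size:
        raise ValueError("wi values and labels must align")
    groups = []
    names = sorted(pd.unique(labels).tolist(), key=str)
    for g in names:
        vals = wi[labels == g]
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 tissues")
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    means = {str(g): float(v.mean()) for g, v in zip(names, groups)}
    pairwise = None
    if len(groups) == 2:
        stat, p = stats.ttest_ind(groups[0], groups[1])
        test = "t-test"
    else:
        stat, p = stats.f_oneway(*groups)
        test = "anova"
        hsd = stats.tukey_hsd(*groups)
        rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append({
                    "group_a": str(names[i]),
                    "group_b": str(names[j]),
                    "mean_diff": float(groups[i].mean() - groups[j].mean()),
                    "adjusted_p": float(hsd.pvalue[i, j]),
                })
        pairwise = pd.DataFrame(rows)
    return GroupComparison(
        group_labels=[str(g) for g in names],
        group_means=means,
        test=test,
        test_statistic=float(stat),
        p_value=float(p),
        pairwise_adjusted_p=pairwise,
        significant=bool(p < 0.05),
    )


def read_field_counts(path) -> pd.DataFrame:
    """Read a field-count CSV (tissue_id, field_id, n_int0..n_int3)."""
    df = pd.read_csv(path)
    missing = [c for c in ["tissue_id"] + INTENSITY_COLUMNS
               if c not in df.columns]
    if missing:
        raise ValueError(f"field-count CSV lacks columns {missing}")
    return df
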