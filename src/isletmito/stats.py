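"""Stated data filters and per-group summaries.

The only filter applied to result tables is a single-pass ±2 SD outlier
rule: values outside mean ± 2 × sample SD, both computed once on the full
input, are removed. The rule is deliberately not iterated — applying it a
second time to the kept values may remove more, and that is documented
behaviour, not a bug. Group summaries report mean ± SEM after filtering.
Hypothesis testing beyond a plain Welch two-sample summary is out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError


@dataclass
class GroupSummary:
    group: str
    n_before: int
    n_after: int
    mean: float
    sem: float
    removed_ids: list = field(default_factory=list)


def remove_outliers_2sd(values, ids=None) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass ±2 SD outlier removal.

    Bounds are mean ± 2 × sample SD of the *full* input; values outside are
    removed, all others kept. Returns (kept, removed) values, or (kept_ids,
    removed_ids) alongside when ids are given.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValidationError("outlier rule needs at least 3 values")
    mu = values.mean()
    sd = values.std(ddof=1)
    keep = (values >= mu - 2 * sd) & (values <= mu + 2 * sd)
    if ids is not None:
        ids = np.asarray(ids)
        return (values[keep], values[~keep]), (ids[keep], ids[~keep])
    return values[keep], values[~keep]


def summarize_groups(df: pd.DataFrame, value_col: str, group_col: str,
                     id_col: str | None = None,
                     remove_outliers: bool = True) -> list[GroupSummary]:
    """Per-group mean ± SEM after the ±2 SD rule (applied within each group)."""
    if df.empty:
        raise ValidationError("no data to summarize")
    out = []
    for group, sub in df.groupby(group_col, sort=True):
        raw = sub[value_col].to_numpy(dtype=float)
        finite = np.isfinite(raw)
        vals = raw[finite]
        if vals.size == 0:
            import warnings
            warnings.warn(f"group {group!r} is empty; skipped", stacklevel=2)
            continue
        ids = (sub[id_col].to_numpy() if id_col else np.arange(len(sub)))[finite]
        removed_ids: list = []
        if remove_outliers and vals.size >= 3:
            (kept, _removed), (kept_ids, rem_ids) = remove_outliers_2sd(vals, ids)
            removed_ids = list(rem_ids)
            n_before = vals.size
            vals = kept
        else:
            n_before = vals.size
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        out.append(GroupSummary(group=str(group), n_before=int(n_before),
                                n_after=int(vals.size),
                                mean=float(vals.mean()), sem=sem,
                                removed_ids=removed_ids))
    return out


def welch_summary(a, b, alpha: float = 0.05) -> dict:
    """Welch two-sample summary: difference of means with a CI and p-value.

    Provided for synthetic parameter-recovery checks; full factorial
    inference is intentionally out of scope.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(1 - alpha)
    return {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "difference": float(a.mean() - b.mean()),
            "ci_low": float(ci.low), "ci_high": float(ci.high),
            "p_value": float(res.pvalue), "df": float(res.df)}
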