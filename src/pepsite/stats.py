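"""Group statistics and differential-peptide calling.

Fold changes are signed: the higher-intensity group's mean is divided by
the lower's, and the ratio carries a ``+`` when group 1 is the higher one
and a ``-`` otherwise, so that a score built from these values rises at
positions with enhanced proteolysis in group 1 and falls where proteolysis
is reduced.  A feature is called differential when p < 0.05 and its plain
group-1/group-2 ratio exceeds 2 or falls below 0.5.

Tests run on log2-transformed observed abundances (Welch two-sample t by
default; two-sided Wilcoxon rank-sum and one-way ANOVA are available).
Raw p-values drive the calls; a Benjamini-Hochberg column is provided for
users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import GroupDesign
from .qc import filter_group_presence

Method = Literal["t", "wilcoxon", "anova"]


def signed_fold_change(
    values1: Sequence[float], values2: Sequence[float], cap: float = 1024.0
) -> tuple[float, float, bool]:
    """Signed fold change between two groups of observed abundances.

    Returns ``(signed_fc, fc_ratio, capped)``.  ``fc_ratio`` is the plain
    mean1/mean2 ratio; ``signed_fc`` is +(hi/lo) when mean1 > mean2,
    -(hi/lo) when mean1 < mean2 and 0 on a tie.  A zero mean on the low
    side would make the ratio infinite; it is replaced by ``cap`` and
    flagged.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    v1, v2 = v1[~np.isnan(v1)], v2[~np.isnan(v2)]
    if v1.size == 0 or v2.size == 0:
        raise ValueError("each group needs at least one observed value")
    m1, m2 = float(v1.mean()), float(v2.mean())
    if m1 == m2:
        ratio = 1.0 if m1 != 0 else np.nan
        return 0.0, ratio, False
    hi, lo = max(m1, m2), min(m1, m2)
    capped = lo == 0
    mag = cap if capped else hi / lo
    mag = min(mag, cap)
    signed = mag if m1 > m2 else -mag
    if capped or (hi / lo if lo else np.inf) > cap:
        capped = True
    ratio = (m1 / m2) if m2 != 0 else (cap if m1 > 0 else np.nan)
    return signed, ratio, capped


def _log2_observed(values: np.ndarray, offset: float) -> np.ndarray:
    v = values[~np.isnan(values)]
    return np.log2(np.where(v == 0, offset, v))


def test_differential(
    matrix: pd.DataFrame,
    design: GroupDesign,
    comparison: tuple[str, str],
    method: Method = "t",
    welch: bool = True,
    min_n: int = 3,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    fc_cap: float = 1024.0,
) -> pd.DataFrame:
    """Per-feature two-group statistics for one comparison.

    Only features observed in at least ``min_n`` samples on both sides are
    tested.  Columns: feature, comparison, n1, n2, mean1, mean2, fc_ratio,
    signed_fc, p, p_bh, flag, call.
    """
    g1, g2 = comparison
    s1, s2 = design.samples_in(g1), design.samples_in(g2)
    if not s1 or not s2:
        raise ValueError(f"comparison {comparison} names an empty group")
    masks = filter_group_presence(matrix, design, min_n=min_n, comparisons=[comparison])
    eligible = masks.eligible(comparison)

    observed = matrix.to_numpy()
    positive = observed[~np.isnan(observed)]
    positive = positive[positive > 0]
    offset = (positive.min() / 2.0) if positive.size else 1.0

    rows = []
    for feat in matrix.index:
        if feat not in eligible:
            continue
        v1 = matrix.loc[feat, s1].to_numpy(dtype=float)
        v2 = matrix.loc[feat, s2].to_numpy(dtype=float)
        signed, ratio, capped = signed_fold_change(v1, v2, cap=fc_cap)
        l1, l2 = _log2_observed(v1, offset), _log2_observed(v2, offset)
        flag = "fc_capped" if capped else ""
        if (v1 == 0).any() or (v2 == 0).any():
            flag = (flag + ";log2_offset").strip(";")
        if method == "t":
            if l1.var(ddof=1) == 0 and l2.var(ddof=1) == 0:
                p = 1.0 if l1.mean() == l2.mean() else 0.0
                flag = (flag + ";zero_variance").strip(";")
            else:
                p = float(sps.ttest_ind(l1, l2, equal_var=not welch).pvalue)
        elif method == "wilcoxon":
            if np.array_equal(np.unique(l1), np.unique(l2)) and len(set(l1) | set(l2)) == 1:
                p, flag = 1.0, (flag + ";zero_variance").strip(";")
            else:
                p = float(sps.mannwhitneyu(l1, l2, alternative="two-sided").pvalue)
        elif method == "anova":
            raise ValueError("anova applies to >2 groups; use test_anova")
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {
                "feature": feat,
                "comparison": f"{g1}|{g2}",
                "n1": int((~np.isnan(v1)).sum()),
                "n2": int((~np.isnan(v2)).sum()),
                "mean1": float(np.nanmean(v1)),
                "mean2": float(np.nanmean(v2)),
                "fc_ratio": ratio,
                "signed_fc": signed,
                "p": p,
                "flag": flag,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["feature", "comparison", "n1", "n2", "mean1", "mean2",
                 "fc_ratio", "signed_fc", "p", "flag"],
    )
    if len(out):
        out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_bh"] = pd.Series(dtype=float)
    out["call"] = call_differential(out, p_threshold=p_threshold,
                                    fc_threshold=fc_threshold)
    return out


def test_anova(
    matrix: pd.DataFrame,
    design: GroupDesign,
    groups: Sequence[str] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """One-way ANOVA on log2 abundance across 3-4 groups."""
    groups = list(groups) if groups is not None else design.groups
    if not 3 <= len(groups) <= 4:
        raise ValueError("one-way ANOVA is used for 3 or 4 groups")
    observed = matrix.to_numpy()
    positive = observed[~np.isnan(observed)]
    positive = positive[positive > 0]
    offset = (positive.min() / 2.0) if positive.size else 1.0
    rows = []
    for feat in matrix.index:
        arrs = []
        for g in groups:
            v = matrix.loc[feat, design.samples_in(g)].to_numpy(dtype=float)
            v = _log2_observed(v, offset)
            if v.size < min_n:
                arrs = []
                break
            arrs.append(v)
        if not arrs:
            continue
        if all(a.var(ddof=1) == 0 for a in arrs) and len({a.mean() for a in arrs}) == 1:
            p = 1.0
        else:
            p = float(sps.f_oneway(*arrs).pvalue)
        rows.append({"feature": feat, "p": p})
    return pd.DataFrame(rows, columns=["feature", "p"])


def call_differential(
    results: pd.DataFrame, p_threshold: float = 0.05, fc_threshold: float = 2.0
) -> pd.Series:
    """Partition tested features into up / down / unchanged.

    up: ratio strictly > ``fc_threshold`` and p < ``p_threshold``;
    down: ratio strictly < 1/``fc_threshold`` and p < ``p_threshold``.
    """
    sig = results["p"] < p_threshold
    up = sig & (results["fc_ratio"] > fc_threshold)
    down = sig & (results["fc_ratio"] < 1.0 / fc_threshold)
    call = pd.Series("unchanged", index=results.index, name="call")
    call[up] = "up"
    call[down] = "down"
    return call


@dataclass
class DifferentialSet:
    """The differential peptides of one comparison with their signed fcs."""

    comparison: tuple[str, str]
    table: pd.DataFrame  # differential rows of a test_differential result

    @property
    def features(self) -> list[str]:
        return list(self.table["feature"])

    def signed_fc(self) -> pd.Series:
        return self.table.set_index("feature")["signed_fc"]


def differential_set(results: pd.DataFrame) -> DifferentialSet:
    g1, g2 = results["comparison"].iloc[0].split("|") if len(results) else ("", "")
    table = results[results["call"].isin(["up", "down"])].reset_index(drop=True)
    return DifferentialSet(comparison=(g1, g2), table=table)
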