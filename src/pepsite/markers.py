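"""ROC-based diagnostic evaluation and biomarker selection.

The AUC of a feature is the probability that a randomly chosen case
outranks a randomly chosen control (Mann-Whitney with the half-count tie
convention).  Because down-regulated fragments are as diagnostic as
up-regulated ones, the reported AUC is two-sided, ``max(A, 1-A)``, with
the achieving direction stored ('+' = higher in cases).

Screening peptide biomarkers must exceed the AUC threshold (default 0.90,
strictly) in every disease-vs-control comparison; candidate positions
additionally need >=2 member peptides that clear the same bar on their
own.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GroupDesign
from .qc import missingness_profile


@dataclass
class DiagnosticRecord:
    feature: str
    comparison: str
    auc: float                 # two-sided, in [0.5, 1]
    direction: str             # '+' higher in disease, '-' lower
    auc_directional: float     # P(case > control) before folding
    n_case: int
    n_control: int


def roc_auc(values, labels) -> tuple[float, str]:
    """Two-sided ROC AUC of ``values`` against binary ``labels``.

    ``labels`` is truthy for cases.  Missing values are excluded (never
    imputed).  Computed from the Mann-Whitney U statistic with ties
    counted half; requires >=2 observed values per class.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    case, ctrl = v[y], v[~y]
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("each class needs at least 2 observed values")
    u = sps.mannwhitneyu(case, ctrl, alternative="two-sided").statistic
    a = float(u) / (case.size * ctrl.size)   # P(case > control) + 0.5 P(=)
    if a >= 0.5:
        return a, "+"
    return 1.0 - a, "-"


def diagnostic_table(
    matrix: pd.DataFrame,
    design: GroupDesign,
    comparisons: Sequence[tuple[str, str]],
    max_missing: float = 0.20,
) -> pd.DataFrame:
    """Two-sided AUCs for all eligible features over the given comparisons.

    Features must pass the strict <``max_missing`` per-group missingness
    gate for a comparison's two groups; features with a class holding <2
    observed values are skipped with a reason.
    """
    rows = []
    for case, ctrl in comparisons:
        sub_design = GroupDesign(
            {s: g for s, g in design.sample_to_group.items() if g in (case, ctrl)},
            [g for g in design.group_order if g in (case, ctrl)],
        )
        samples = sub_design.samples
        profile = missingness_profile(matrix[samples], sub_design, max_missing)
        for feat in matrix.index:
            if not profile.eligible[feat]:
                continue
            values = matrix.loc[feat, samples].to_numpy(dtype=float)
            labels = np.array([sub_design.sample_to_group[s] == case for s in samples])
            try:
                auc, direction = roc_auc(values, labels)
            except ValueError:
                continue
            keep = ~np.isnan(values)
            a_dir = auc if direction == "+" else 1.0 - auc
            rows.append(
                {
                    "feature": feat,
                    "comparison": f"{case}|{ctrl}",
                    "auc": auc,
                    "direction": direction,
                    "auc_directional": a_dir,
                    "n_case": int((labels & keep).sum()),
                    "n_control": int((~labels & keep).sum()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["feature", "comparison", "auc", "direction",
                 "auc_directional", "n_case", "n_control"],
    )


def screening_biomarkers(
    diagnostics: pd.DataFrame,
    comparisons: Sequence[str] | None = None,
    threshold: float = 0.90,
) -> list[str]:
    """Features with AUC strictly above ``threshold`` in every comparison."""
    if comparisons is None:
        comparisons = sorted(diagnostics["comparison"].unique())
    out = []
    for feat, sub in diagnostics.groupby("feature"):
        present = set(sub["comparison"])
        if not set(comparisons) <= present:
            continue
        aucs = sub.set_index("comparison")["auc"]
        if all(aucs[c] > threshold for c in comparisons):
            out.append(feat)
    return sorted(out)


def candidate_positions(
    position_diagnostics: pd.DataFrame,
    peptide_diagnostics: pd.DataFrame,
    membership: Mapping[str, Sequence[str]],
    auc_threshold: float = 0.90,
    min_members: int = 2,
) -> pd.DataFrame:
    """Positions meeting the dual biomarker criteria.

    A position qualifies iff its own AUC exceeds ``auc_threshold`` and at
    least ``min_members`` member peptides individually exceed it in the
    same comparison.
    """
    pep_auc = peptide_diagnostics.set_index(["feature", "comparison"])["auc"]
    rows = []
    for _, rec in position_diagnostics.iterrows():
        if rec["auc"] <= auc_threshold:
            continue
        members = membership.get(rec["feature"], [])
        strong = [
            m for m in members
            if (m, rec["comparison"]) in pep_auc.index
            and pep_auc[(m, rec["comparison"])] > auc_threshold
        ]
        if len(strong) >= min_members:
            rows.append(
                {
                    "position": rec["feature"],
                    "comparison": rec["comparison"],
                    "auc": rec["auc"],
                    "n_strong_members": len(strong),
                    "strong_members": ";".join(sorted(strong)),
                }
            )
    return pd.DataFrame(
        rows, columns=["position", "comparison", "auc",
                       "n_strong_members", "strong_members"]
    )


# ---------------------------------------------------------------------------
# set reporting

def overlap_sets(named_sets: Mapping[str, Sequence]) -> dict:
    """All Venn region counts for up to 5 named sets, plus the membership table."""
    names = list(named_sets)
    if not 1 <= len(names) <= 5:
        raise ValueError("overlap_sets supports 1-5 sets")
    sets = {n: set(named_sets[n]) for n in names}
    universe = sorted(set().union(*sets.values()), key=str)
    regions = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            outside = [n for n in names if n not in inside]
            region = set.intersection(*(sets[n] for n in inside))
            for n in outside:
                region -= sets[n]
            regions["&".join(inside)] = len(region)
    membership = pd.DataFrame(
        {n: [x in sets[n] for x in universe] for n in names}, index=universe
    )
    return {
        "regions": regions,
        "union": len(set().union(*sets.values())),
        "intersection": len(set.intersection(*sets.values())),
        "membership": membership,
    }


def percent_shared(n_shared: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of features shared across groups, as printed in reports."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * n_shared / n_total, decimals)


def utilization_report(
    n_contributing: int,
    n_single: int,
    position_missing_fraction: float | None = None,
    peptide_missing_fraction: float | None = None,
) -> dict:
    """Peptide-utilization gain of position-based over single-peptide analysis.

    ``fold_increase`` is (contributing / single) - 1, reported to one
    decimal; the missing-value difference (percentage points) is included
    when both fractions are supplied.
    """
    if n_single <= 0:
        raise ValueError("single-peptide count must be positive")
    fold = n_contributing / n_single - 1.0
    out = {
        "n_contributing_peptides": n_contributing,
        "n_single_peptides": n_single,
        "fold_increase": round(fold, 1),
        "fold_increase_raw": fold,
    }
    if position_missing_fraction is not None and peptide_missing_fraction is not None:
        out["missing_value_reduction_pct"] = round(
            100.0 * (peptide_missing_fraction - position_missing_fraction), 1
        )
    return out
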