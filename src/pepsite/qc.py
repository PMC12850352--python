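"""Identification-quality filters, presence gates and abundance scaling.

Three gates stand between a raw peptide report and the statistics:

* fragment continuity — an identification is trusted only if its spectrum
  matched at least four consecutive b- or y-ions;
* group presence — a feature enters qualitative analysis for a group only
  with >=3 observed samples there, and enters a two-group comparison only
  with >=3 on *both* sides;
* the missingness gate — ROC/embedding exports require a missing-value
  rate strictly below 20% in every group.

Scaling follows the total-amount convention: sample columns are equalised
to the median column total, then each feature row is rescaled so its mean
over observed cells is 100 ("scaled abundance").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import GroupDesign

_ION_RE = re.compile(r"^([by])(\d+)$")


def parse_fragment_evidence(text: str) -> set[tuple[str, int]]:
    """Parse a compact evidence string like ``"b2;b3;B4, y5"``.

    Tolerant to spaces, case and comma/semicolon separators.
    """
    ions: set[tuple[str, int]] = set()
    for token in re.split(r"[;,\s]+", text.strip()):
        if not token:
            continue
        m = _ION_RE.match(token.lower())
        if m is None:
            raise ValueError(f"unparseable fragment ion {token!r}")
        series, ordinal = m.group(1), int(m.group(2))
        if ordinal < 1:
            raise ValueError(f"fragment ordinal must be >=1: {token!r}")
        ions.add((series, ordinal))
    return ions


def longest_consecutive_run(ordinals: Iterable[int]) -> int:
    """Length of the longest run of consecutive integers."""
    seen = set(ordinals)
    best = 0
    for o in seen:
        if o - 1 not in seen:  # run start
            length = 1
            while o + length in seen:
                length += 1
            best = max(best, length)
    return best


def has_fragment_continuity(ions: set[tuple[str, int]], min_run: int = 4) -> bool:
    """True iff the b series or the y series contains ``min_run`` consecutive ions."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    for series in ("b", "y"):
        if longest_consecutive_run(o for s, o in ions if s == series) >= min_run:
            return True
    return False


def filter_fragment_continuity(
    evidence: Mapping[str, str] | pd.Series,
    min_run: int = 4,
    strict: bool = False,
    all_peptides: Iterable[str] | None = None,
) -> pd.Series:
    """Per-peptide keep/drop decisions from fragment-evidence strings.

    Peptides absent from ``evidence`` (supply their ids via
    ``all_peptides``) pass by default — PRM and simulated reports carry no
    fragment evidence — unless ``strict`` is set.
    """
    evidence = dict(evidence)
    decisions: dict[str, bool] = {}
    for pep, text in evidence.items():
        decisions[pep] = has_fragment_continuity(parse_fragment_evidence(text), min_run)
    if all_peptides is not None:
        for pep in all_peptides:
            if pep not in decisions:
                decisions[pep] = not strict
    return pd.Series(decisions, name="keep", dtype=bool)


# ---------------------------------------------------------------------------
# presence and missingness

@dataclass
class PresenceMasks:
    """Eligibility masks from the >=min_n-samples-per-group rule."""

    per_group: pd.DataFrame              # features x groups, bool
    per_comparison: pd.DataFrame         # features x "g1|g2" columns, bool
    min_n: int = 3

    def eligible(self, comparison: tuple[str, str]) -> pd.Index:
        col = f"{comparison[0]}|{comparison[1]}"
        return self.per_comparison.index[self.per_comparison[col]]


def filter_group_presence(
    matrix: pd.DataFrame,
    design: GroupDesign,
    min_n: int = 3,
    comparisons: list[tuple[str, str]] | None = None,
) -> PresenceMasks:
    """Apply the at-least-``min_n``-samples rule per group and per comparison.

    A feature is kept for a group's qualitative set when observed in at
    least ``min_n`` of that group's samples, and enters a two-group
    quantitative comparison only when that holds on both sides.
    """
    counts = pd.DataFrame(
        {g: matrix[design.samples_in(g)].notna().sum(axis=1) for g in design.groups}
    )
    per_group = counts >= min_n
    if comparisons is None:
        groups = design.groups
        comparisons = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    per_comp = pd.DataFrame(
        {f"{a}|{b}": per_group[a] & per_group[b] for a, b in comparisons}
    )
    return PresenceMasks(per_group=per_group, per_comparison=per_comp, min_n=min_n)


@dataclass
class MissingnessProfile:
    fractions: pd.DataFrame   # features x groups, fraction missing in [0, 1]
    eligible: pd.Series       # strict <max_fraction in every group


def missingness_profile(
    matrix: pd.DataFrame,
    design: GroupDesign,
    max_fraction: float = 0.20,
) -> MissingnessProfile:
    """Per-feature, per-group missing fractions and the strict <20% gate."""
    fractions = pd.DataFrame(
        {
            g: matrix[design.samples_in(g)].isna().mean(axis=1)
            for g in design.groups
        }
    )
    eligible = (fractions < max_fraction).all(axis=1)
    eligible.name = "eligible"
    return MissingnessProfile(fractions=fractions, eligible=eligible)


# ---------------------------------------------------------------------------
# normalization

@dataclass
class NormalizationResult:
    matrix: pd.DataFrame
    sample_factors: pd.Series
    feature_factors: pd.Series


def normalize_scale(matrix: pd.DataFrame, row_scaling: str = "mean100") -> NormalizationResult:
    """Total-amount normalization followed by per-feature scaling to 100.

    Step 1 multiplies each sample column so its total observed abundance
    equals the median of the column totals.  Step 2 rescales each feature
    row so its mean over observed cells is 100 (``row_scaling="mean100"``),
    or its maximum is 100 (``"max100"``).  Missing cells stay missing and
    all factors are returned.  The output is tagged ``provenance="scaled"``
    (in ``DataFrame.attrs``); re-normalizing a scaled matrix is the
    identity, so the operation is idempotent on its own output.
    """
    if matrix.attrs.get("provenance") == "scaled":
        return NormalizationResult(
            matrix,
            pd.Series(1.0, index=matrix.columns),
            pd.Series(1.0, index=matrix.index),
        )
    totals = matrix.sum(axis=0, skipna=True)
    empty = matrix.columns[matrix.isna().all(axis=0)]
    if len(empty):
        raise ValueError(f"samples with no observed values: {list(empty)}")
    target = float(np.median(totals))
    sample_factors = target / totals
    scaled = matrix * sample_factors

    if row_scaling == "mean100":
        row_ref = scaled.mean(axis=1, skipna=True)
    elif row_scaling == "max100":
        row_ref = scaled.max(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown row_scaling {row_scaling!r}")
    feature_factors = 100.0 / row_ref
    feature_factors[~np.isfinite(feature_factors)] = np.nan
    out = scaled.mul(feature_factors, axis=0)
    out.attrs["provenance"] = "scaled"
    return NormalizationResult(out, sample_factors, feature_factors)
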