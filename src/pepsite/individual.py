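"""Per-sample individual aa-scores for peptide clusters.

Where the grouped score aggregates *fold changes* between groups, the
individual score gives every sample its own position value by summing
member-peptide quantities over a cluster (all peptides sharing one
labelled terminal residue).  Four routes are supported:

* ``absolute``       — sum of back-calculated amounts (heavy-labelled
                       standards + calibration curve);
* ``heavy_ratio``    — sum of endogenous/heavy intensity ratios;
* ``reference``      — sum of sample/reference intensity ratios, using
                       only members with heavy counterparts (target-only)
                       or all targeted members;
* discovery mode     — reference ratios over *all* quantified members,
                       with a union rule: a position is missing for a
                       sample only when no member is observed, which is
                       what shrinks missing-value rates relative to
                       single-peptide analysis.

In PRM mode a sample missing any required member measurement is excluded
for that position (an absent heavy partner means the endogenous peptide
went undetected); in discovery mode no sample is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import PeptideMapping, PositionLabel


@dataclass
class PeptideCluster:
    """Member peptides sharing one labelled terminal residue."""

    label: PositionLabel
    members: list[str]
    heavy_available: dict[str, bool] = field(default_factory=dict)
    reference: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cluster needs at least one member")

    def target_members(self) -> list[str]:
        return [m for m in self.members if self.heavy_available.get(m, False)]


# ---------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationCurve:
    """Linear light/heavy response vs spiked amount for one peptide."""

    peptide: str
    slope: float
    intercept: float
    r_squared: float
    amount_range: tuple[float, float]
    n_points: int

    def back_calc(self, ratio: float) -> tuple[float, bool]:
        """Amount from an observed ratio; flags extrapolation."""
        amount = (ratio - self.intercept) / self.slope
        lo, hi = self.amount_range
        return amount, not (lo <= amount <= hi)


def fit_calibration(
    amounts: Sequence[float], ratios: Sequence[float], peptide: str = ""
) -> CalibrationCurve:
    """Ordinary least squares of response ratio on spiked amount.

    Requires >=3 distinct, strictly positive amounts; a non-positive slope
    indicates a non-responsive standard and is an error.
    """
    a = np.asarray(amounts, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if a.size < 3:
        raise ValueError("calibration needs at least 3 dilution points")
    if np.any(a <= 0):
        raise ValueError("calibration amounts must be strictly positive")
    if np.unique(a).size != a.size:
        raise ValueError("calibration amounts must be distinct")
    fit = sps.linregress(a, r)
    if fit.slope <= 0:
        raise ValueError(f"non-responsive standard for {peptide!r}: slope <= 0")
    return CalibrationCurve(
        peptide=peptide,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        amount_range=(float(a.min()), float(a.max())),
        n_points=int(a.size),
    )


# ---------------------------------------------------------------------------
# reference construction

def build_reference(
    runs: pd.DataFrame,
    method: Literal["arithmetic", "geometric"] = "arithmetic",
    min_detections: int = 1,
) -> pd.DataFrame:
    """Per-peptide reference intensity from pooled-sample replicate runs.

    ``runs`` is peptides x replicates with NaN for missed detections.
    Returns a frame with columns ``reference`` (mean over observed
    replicates), ``n_detected`` and ``usable``; peptides detected in no
    replicate get NaN and are unusable.
    """
    n_detected = runs.notna().sum(axis=1)
    if method == "arithmetic":
        ref = runs.mean(axis=1, skipna=True)
    elif method == "geometric":
        ref = np.exp(np.log(runs).mean(axis=1, skipna=True))
    else:
        raise ValueError(f"unknown reference mean {method!r}")
    out = pd.DataFrame(
        {
            "reference": ref,
            "n_detected": n_detected,
            "usable": (n_detected >= max(min_detections, 1)),
        }
    )
    out.index.name = "peptide"
    return out


# ---------------------------------------------------------------------------
# scoring routes

def apply_exclusion_rule(
    cluster: PeptideCluster,
    detected: pd.DataFrame,
    members: Sequence[str] | None = None,
) -> pd.Series:
    """PRM sample inclusion: every required member must be measured.

    ``detected`` is a peptides x samples boolean (or intensity) frame; a
    sample is excluded for this position iff any required member lacks its
    measurement there.
    """
    members = list(members) if members is not None else cluster.members
    sub = detected.reindex(members)
    ok = sub.notna() if sub.dtypes.map(lambda d: d.kind == "f").any() else sub.fillna(False).astype(bool)
    included = ok.all(axis=0)
    included.name = "included"
    return included


def _masked_sum(values: pd.DataFrame, require_all: bool) -> pd.Series:
    """Column sums over observed cells; NaN where the rule fails."""
    if require_all:
        out = values.sum(axis=0, skipna=False)
    else:
        out = values.sum(axis=0, skipna=True)
        out[values.notna().sum(axis=0) == 0] = np.nan
    return out


def score_absolute(cluster: PeptideCluster, amounts: pd.DataFrame) -> pd.Series:
    """Sum of member amounts per sample (PRM exclusion rule applies)."""
    sub = amounts.reindex(cluster.members)
    score = _masked_sum(sub, require_all=True)
    score.name = cluster.label.render()
    return score


def score_heavy_ratio(
    cluster: PeptideCluster, light: pd.DataFrame, heavy: pd.DataFrame
) -> pd.Series:
    """Sum of endogenous/heavy intensity ratios per sample.

    A zero or missing heavy intensity leaves the member's ratio undefined
    and triggers the exclusion rule for that sample.
    """
    members = cluster.target_members() or cluster.members
    l = light.reindex(members)
    h = heavy.reindex(members).where(lambda x: x > 0)
    ratios = l / h
    score = _masked_sum(ratios, require_all=True)
    score.name = cluster.label.render()
    return score


def score_reference_ratio(
    cluster: PeptideCluster,
    intensities: pd.DataFrame,
    reference: pd.Series | Mapping[str, float] | None = None,
    member_mode: Literal["all", "target-only"] = "all",
    discovery: bool = False,
) -> pd.Series:
    """Sum of sample/reference intensity ratios per sample.

    ``member_mode="target-only"`` restricts to members with heavy-labelled
    counterparts.  In PRM mode (default) an unobserved member excludes the
    sample; in discovery mode the sum runs over members observed in both
    the sample and the reference — the union rule — and the position is
    missing only when no member qualifies.  Members without a usable
    reference intensity are dropped from the cluster for all samples.
    """
    ref = pd.Series(reference) if reference is not None else pd.Series(cluster.reference)
    if member_mode == "target-only":
        members = cluster.target_members()
    else:
        members = list(cluster.members)
    members = [m for m in members if m in ref.index and np.isfinite(ref.get(m, np.nan)) and ref[m] > 0]
    if not members:
        raise ValueError(f"cluster {cluster.label.render()} has no usable reference members")
    ratios = intensities.reindex(members).div(ref.reindex(members), axis=0)
    score = _masked_sum(ratios, require_all=not discovery)
    score.name = cluster.label.render()
    return score


# ---------------------------------------------------------------------------
# discovery-mode driver

def build_clusters(
    mappings: Sequence[PeptideMapping],
    quantified: Sequence[str] | None = None,
) -> list[PeptideCluster]:
    """Group quantified peptides into terminal-residue clusters.

    Every peptide contributes to the cluster of its N-terminal residue and
    of its C-terminal residue; sites where both orientations occur merge
    to a B-labelled cluster.
    """
    keep = set(quantified) if quantified is not None else None
    termini: dict[tuple[str, int, str], set[str]] = {}
    for m in mappings:
        if keep is not None and m.peptide not in keep:
            continue
        termini.setdefault((m.protein, m.start, "N"), set()).add(m.peptide)
        termini.setdefault((m.protein, m.end, "C"), set()).add(m.peptide)
    clusters: list[PeptideCluster] = []
    done: set[tuple[str, int]] = set()
    for (protein, p, orient), members in sorted(termini.items()):
        if (protein, p) in done:
            continue
        other = termini.get((protein, p, "C" if orient == "N" else "N"))
        if other is not None:
            done.add((protein, p))
            clusters.append(
                PeptideCluster(PositionLabel(protein, p, "B"), sorted(members | other))
            )
        else:
            clusters.append(PeptideCluster(PositionLabel(protein, p, orient), sorted(members)))
    return clusters


def position_score_matrix(
    matrix: pd.DataFrame,
    mappings: Sequence[PeptideMapping],
    reference: pd.Series,
) -> tuple[pd.DataFrame, list[PeptideCluster]]:
    """Reference-based discovery scoring of every terminal position.

    The member set of each cluster is frozen from the reference (members
    never observed there are dropped, so every sample's sum runs over a
    comparable denominator set); per sample the union rule applies.
    Returns the positions x samples score matrix plus the clusters used.
    """
    usable_ref = reference[np.isfinite(reference) & (reference > 0)]
    clusters = build_clusters(mappings, quantified=list(matrix.index))
    rows: dict[str, pd.Series] = {}
    used: list[PeptideCluster] = []
    for cluster in clusters:
        members = [m for m in cluster.members if m in usable_ref.index]
        if not members:
            continue
        frozen = PeptideCluster(cluster.label, members, cluster.heavy_available)
        score = score_reference_ratio(
            frozen, matrix, usable_ref, member_mode="all", discovery=True
        )
        rows[frozen.label.render()] = score
        used.append(frozen)
    out = pd.DataFrame(rows).T
    out.index.name = "position"
    return out, used
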