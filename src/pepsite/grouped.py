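"""Grouped aa-scores on bond positions and the proteolytic point taxonomy.

The grouped aa-score of bond ``j`` is the sum of signed fold changes of
every differential peptide whose span covers ``j``:

    score_j = sum_{k=1..n_j} fc_k

where a peptide occupying residues ``[s, e]`` covers, by default, exactly
its internal bonds ``{s, ..., e-1}``.  The resulting per-protein track is
a step function whose steps fall at peptide termini.  Terminal residues of
differential peptides are *changing points*: *stable* when two or more
differential peptides share the same terminal residue and orientation,
*dynamic* when only one does.  The signed step the terminus introduces
into the (cumulative) score curve,

    delta_p = score_p - score_{p-1},

annotates each changing point as a *transition point*; positions whose
transition sign agrees in every pairwise comparison are the
disease-associated *important* positions, and a per-position trend over a
severity-ordered set of comparisons flags progressively up- or
down-regulated proteolysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import PeptideMapping, PositionLabel, ProteinRecord

AssignMode = Literal["internal", "inclusive"]


@dataclass
class ScoreTrack:
    """Per-bond grouped aa-scores for one protein and one comparison."""

    protein: str
    length: int                 # residues L; bonds indexed 0..L
    comparison: str
    scores: np.ndarray          # shape (L+1,)
    counts: np.ndarray          # contributing differential peptides per bond

    def __post_init__(self) -> None:
        if self.scores.shape != (self.length + 1,):
            raise ValueError("score vector must have L+1 entries")

    @property
    def normalized_mean(self) -> float:
        """Sum of bond scores divided by the number of peptide bonds (L-1)."""
        if self.length < 2:
            return 0.0
        return float(self.scores.sum()) / (self.length - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": self.protein,
                "bond": np.arange(self.length + 1),
                "comparison": self.comparison,
                "score": self.scores,
                "n": self.counts,
            }
        )


def grouped_aa_score(
    peptides: Sequence[tuple[PeptideMapping, float]],
    protein: ProteinRecord,
    comparison: str = "",
    mode: AssignMode = "internal",
) -> ScoreTrack:
    """Accumulate signed fold changes of differential peptides onto bonds.

    Each peptide's ``signed_fc`` is added to every bond it covers:
    ``{s, ..., e-1}`` under the default internal assignment, or
    ``{s-1, ..., e}`` in inclusive mode (which lets the virtual bonds 0
    and L carry score).
    """
    L = protein.length
    scores = np.zeros(L + 1)
    counts = np.zeros(L + 1, dtype=int)
    for mapping, fc in peptides:
        if mapping.protein != protein.accession:
            raise ValueError(
                f"peptide {mapping.peptide} mapped to {mapping.protein}, "
                f"not {protein.accession}"
            )
        if mapping.end > L:
            raise ValueError(f"mapping end {mapping.end} beyond protein length {L}")
        if mode == "internal":
            lo, hi = mapping.start, mapping.end - 1
        elif mode == "inclusive":
            lo, hi = mapping.start - 1, mapping.end
        else:
            raise ValueError(f"unknown assignment mode {mode!r}")
        if hi >= lo:
            scores[lo : hi + 1] += fc
            counts[lo : hi + 1] += 1
    return ScoreTrack(protein.accession, L, comparison, scores, counts)


def cumulative_profile(tracks: Sequence[ScoreTrack]) -> ScoreTrack:
    """Element-wise sum of per-comparison tracks: the waterfall profile."""
    if not tracks:
        raise ValueError("no tracks to accumulate")
    first = tracks[0]
    scores = np.zeros_like(first.scores)
    counts = np.zeros_like(first.counts)
    for t in tracks:
        if (t.protein, t.length) != (first.protein, first.length):
            raise ValueError("tracks belong to different proteins")
        scores = scores + t.scores
        counts = counts + t.counts
    return ScoreTrack(first.protein, first.length, "cumulative", scores, counts)


# ---------------------------------------------------------------------------
# point taxonomy

@dataclass
class PointRecord:
    """One labelled aa position in one comparison."""

    label: PositionLabel
    comparison: str
    point_class: Literal["stable", "dynamic"]
    members: list[str] = field(default_factory=list)
    direction: int = 0          # sign of the members' mean signed fold change
    step: float = float("nan")  # delta_p on the score track
    step_sign: int = 0
    is_transition: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.label.protein, self.label.position, self.label.orientation)


def _sign(x: float) -> int:
    return int(np.sign(x))


def classify_points(
    peptides: Sequence[tuple[PeptideMapping, float]],
    comparison: str = "",
) -> list[PointRecord]:
    """Derive stable/dynamic changing points from one comparison's
    differential peptides.

    Every differential peptide contributes an N-terminal label at its
    start residue and a C-terminal label at its end residue.  A (protein,
    residue, orientation) seen for >=2 peptides is stable, for exactly one
    dynamic.  Where N- and C-oriented products co-exist at the same
    residue the labels merge to orientation B, keeping the best-supported
    class.
    """
    termini: dict[tuple[str, int, str], list[tuple[str, float]]] = {}
    for mapping, fc in peptides:
        termini.setdefault((mapping.protein, mapping.start, "N"), []).append(
            (mapping.peptide, fc)
        )
        termini.setdefault((mapping.protein, mapping.end, "C"), []).append(
            (mapping.peptide, fc)
        )
    records: list[PointRecord] = []
    merged: set[tuple[str, int]] = set()
    for (protein, p, orient), hits in sorted(termini.items()):
        if (protein, p) in merged:
            continue
        other = termini.get((protein, p, "C" if orient == "N" else "N"))
        if other is not None:
            merged.add((protein, p))
            n_best = max(len(hits), len(other))
            all_hits = hits + other
            records.append(
                PointRecord(
                    label=PositionLabel(protein, p, "B"),
                    comparison=comparison,
                    point_class="stable" if n_best >= 2 else "dynamic",
                    members=sorted({pep for pep, _ in all_hits}),
                    direction=_sign(float(np.mean([fc for _, fc in all_hits]))),
                )
            )
        else:
            records.append(
                PointRecord(
                    label=PositionLabel(protein, p, orient),
                    comparison=comparison,
                    point_class="stable" if len(hits) >= 2 else "dynamic",
                    members=sorted({pep for pep, _ in hits}),
                    direction=_sign(float(np.mean([fc for _, fc in hits]))),
                )
            )
    return records


def detect_transition_points(
    track: ScoreTrack,
    points: Sequence[PointRecord],
    require_nonzero_step: bool = True,
) -> list[PointRecord]:
    """Annotate changing points with the signed step of the score curve.

    The step at residue ``p`` is ``score_p - score_{p-1}`` — the jump the
    peptide termini at ``p`` introduce into the track.  With
    ``require_nonzero_step`` (default) only points with a non-zero step
    count as transition points; otherwise every changing point does, with
    its sign recorded.
    """
    out: list[PointRecord] = []
    for rec in points:
        if rec.label.protein != track.protein:
            raise ValueError(
                f"point {rec.label.render()} not on track protein {track.protein}"
            )
        p = rec.label.position
        step = float(track.scores[p] - track.scores[p - 1])
        out.append(
            replace(
                rec,
                step=step,
                step_sign=_sign(step),
                is_transition=(step != 0.0) if require_nonzero_step else True,
            )
        )
    return out


def important_positions(
    points_by_comparison: Mapping[str, Sequence[PointRecord]],
) -> list[tuple[tuple[str, int, str], int]]:
    """Positions whose transition sign is consistent across every comparison.

    A (protein, residue, orientation) is important iff every comparison
    contains a transition point there with the same non-zero step sign.
    Returns the qualifying keys with their shared sign.
    """
    comparisons = list(points_by_comparison)
    if not comparisons:
        return []
    per_comp: list[dict[tuple[str, int, str], int]] = []
    for comp in comparisons:
        per_comp.append(
            {
                rec.key: rec.step_sign
                for rec in points_by_comparison[comp]
                if rec.is_transition and rec.step_sign != 0
            }
        )
    shared = set(per_comp[0])
    for d in per_comp[1:]:
        shared &= set(d)
    out = []
    for key in sorted(shared):
        signs = {d[key] for d in per_comp}
        if len(signs) == 1:
            out.append((key, signs.pop()))
    return out


def severity_trend(
    scores: Sequence[float], epsilon: float = 0.0
) -> Literal["up", "down", "none"]:
    """Trend of a position's score along severity-ordered comparisons.

    ``up`` iff strictly increasing (each step > epsilon), ``down`` iff
    strictly decreasing, else ``none``.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        return "none"
    diffs = np.diff(arr)
    if np.all(diffs > epsilon):
        return "up"
    if np.all(diffs < -epsilon):
        return "down"
    return "none"


def protease_activity(cleavage: Mapping[str, Sequence[str]]) -> pd.Series:
    """Percent activity per predicted protease from a cleavage table.

    ``cleavage`` maps each peptide to the proteases predicted to have
    produced it.  activity(P) = 100 * count(P) / total cleavage
    assignments; the result sums to 100.
    """
    counts: dict[str, int] = {}
    for proteases in cleavage.values():
        for prot in proteases:
            counts[prot] = counts.get(prot, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no cleavage assignments")
    return pd.Series(
        {prot: 100.0 * n / total for prot, n in sorted(counts.items())},
        name="percent_activity",
    )


def points_to_frame(points: Sequence[PointRecord]) -> pd.DataFrame:
    """Flatten point records to the catalog table layout."""
    rows = [
        {
            "label": rec.label.render(),
            "protein": rec.label.protein,
            "position": rec.label.position,
            "orientation": rec.label.orientation,
            "comparison": rec.comparison,
            "class": rec.point_class,
            "n_members": len(rec.members),
            "direction": rec.direction,
            "step": rec.step,
            "step_sign": rec.step_sign,
            "transition": rec.is_transition,
            "members": ";".join(rec.members),
        }
        for rec in points
    ]
    return pd.DataFrame(
        rows,
        columns=["label", "protein", "position", "orientation", "comparison",
                 "class", "n_members", "direction", "step", "step_sign",
                 "transition", "members"],
    )
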