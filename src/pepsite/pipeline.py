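"""End-to-end grouped analysis and recovery benchmarking.

``run_grouped_analysis`` chains the standard stages — normalization,
presence filtering, differential testing, Eq.-style bond scoring, point
classification and transition annotation — for every disease-vs-control
comparison of a design.  ``recover_hotspots`` scores a run against a
simulation's ground truth: a planted dysregulated bond counts as
recovered when a stable transition point with the correct member
direction sits on that bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import PeptideMapping, ProteinDatabase, locate_peptides
from .grouped import (
    PointRecord,
    ScoreTrack,
    classify_points,
    cumulative_profile,
    detect_transition_points,
    grouped_aa_score,
    important_positions,
    points_to_frame,
)
from .io import GroupDesign
from .qc import normalize_scale
from .simulate import GroundTruth
from .stats import test_differential


@dataclass
class GroupedAnalysis:
    """All artefacts of one grouped aa-score run."""

    normalized: pd.DataFrame
    mappings: dict[str, PeptideMapping]
    comparisons: list[tuple[str, str]]
    results: dict[str, pd.DataFrame] = field(default_factory=dict)
    tracks: dict[str, dict[str, ScoreTrack]] = field(default_factory=dict)
    cumulative: dict[str, ScoreTrack] = field(default_factory=dict)
    points: dict[str, list[PointRecord]] = field(default_factory=dict)
    important: list[tuple[tuple[str, int, str], int]] = field(default_factory=list)

    def catalog(self) -> pd.DataFrame:
        frames = [points_to_frame(recs) for recs in self.points.values()]
        if not frames:
            return points_to_frame([])
        return pd.concat(frames, ignore_index=True)


def disease_vs_control(design: GroupDesign) -> list[tuple[str, str]]:
    """Each non-control group against the first (least severe) group."""
    control = design.groups[0]
    return [(g, control) for g in design.groups[1:]]


def run_grouped_analysis(
    matrix: pd.DataFrame,
    design: GroupDesign,
    db: ProteinDatabase,
    comparisons: Sequence[tuple[str, str]] | None = None,
    normalize: bool = True,
    min_n: int = 3,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    bond_assignment: str = "internal",
    require_nonzero_step: bool = True,
) -> GroupedAnalysis:
    """Run the grouped aa-score pipeline on a peptide x sample matrix."""
    comparisons = list(comparisons) if comparisons is not None else disease_vs_control(design)
    study_samples = [s for s in matrix.columns if s in design.sample_to_group]
    data = matrix[study_samples]
    if normalize:
        data = normalize_scale(data).matrix

    located = locate_peptides(list(data.index), db)
    mappings = {m.peptide: m for m in located.mappings}

    analysis = GroupedAnalysis(
        normalized=data, mappings=mappings, comparisons=comparisons
    )
    for case, ctrl in comparisons:
        comp_id = f"{case}|{ctrl}"
        res = test_differential(
            data, design, (case, ctrl),
            min_n=min_n, p_threshold=p_threshold, fc_threshold=fc_threshold,
        )
        analysis.results[comp_id] = res
        diff = res[res["call"].isin(["up", "down"])]
        pairs_by_protein: dict[str, list[tuple[PeptideMapping, float]]] = {}
        for feat, fc in zip(diff["feature"], diff["signed_fc"]):
            m = mappings.get(feat)
            if m is None:
                continue
            pairs_by_protein.setdefault(m.protein, []).append((m, float(fc)))

        comp_tracks: dict[str, ScoreTrack] = {}
        comp_points: list[PointRecord] = []
        for protein, pairs in sorted(pairs_by_protein.items()):
            track = grouped_aa_score(pairs, db[protein], comp_id, mode=bond_assignment)
            comp_tracks[protein] = track
            raw_points = classify_points(pairs, comp_id)
            comp_points.extend(
                detect_transition_points(track, raw_points, require_nonzero_step)
            )
        analysis.tracks[comp_id] = comp_tracks
        analysis.points[comp_id] = comp_points

    for protein in sorted({p for t in analysis.tracks.values() for p in t}):
        per_comp = [t[protein] for t in analysis.tracks.values() if protein in t]
        analysis.cumulative[protein] = cumulative_profile(per_comp)
    analysis.important = important_positions(analysis.points)
    return analysis


# ---------------------------------------------------------------------------
# recovery against ground truth

def predicted_hotspot_bonds(
    points: Mapping[str, Sequence[PointRecord]],
    stable_only: bool = True,
    exclude_virtual: bool = True,
    protein_lengths: Mapping[str, int] | None = None,
) -> dict[tuple[str, int], int]:
    """Candidate cleavage bonds from transition points, with directions.

    A point at residue p proposes bond p-1 (orientation N), bond p
    (orientation C), or both (B); its direction is the sign of the
    members' fold changes.  Virtual bonds 0 and L are protein termini,
    not cleavage sites, and are excluded by default.  Conflicting
    directions at one bond cancel the prediction.
    """
    votes: dict[tuple[str, int], set[int]] = {}
    for recs in points.values():
        for rec in recs:
            if not rec.is_transition or rec.direction == 0:
                continue
            if stable_only and rec.point_class != "stable":
                continue
            protein = rec.label.protein
            p = rec.label.position
            bonds = {"N": [p - 1], "C": [p], "B": [p - 1, p]}[rec.label.orientation]
            for b in bonds:
                if exclude_virtual:
                    if b == 0:
                        continue
                    if protein_lengths and b >= protein_lengths.get(protein, b + 1):
                        continue
                votes.setdefault((protein, b), set()).add(rec.direction)
    return {key: dirs.pop() for key, dirs in votes.items() if len(dirs) == 1}


def recover_hotspots(
    analysis: GroupedAnalysis,
    truth: GroundTruth,
    db: ProteinDatabase,
    stable_only: bool = True,
) -> dict:
    """Precision/recall/F1 of planted dysregulated bonds with direction."""
    lengths = {rec.accession: rec.length for rec in db}
    predicted = predicted_hotspot_bonds(
        analysis.points, stable_only=stable_only, protein_lengths=lengths
    )
    planted = truth.hotspot_map()
    tp = sum(
        1 for key, d in predicted.items() if key in planted and planted[key] == d
    )
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(planted) if planted else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "n_predicted": len(predicted),
        "n_planted": len(planted),
        "n_true_positive": tp,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "predicted": predicted,
    }
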