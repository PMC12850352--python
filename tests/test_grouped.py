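"""Grouped aa-score tracks, point taxonomy and transition detection."""

import numpy as np
import pytest

from pepsite.core import PeptideMapping, ProteinRecord
from pepsite.grouped import (
    classify_points,
    cumulative_profile,
    detect_transition_points,
    grouped_aa_score,
    important_positions,
    protease_activity,
    severity_trend,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def protein_of_length(L, acc="PROT"):
    return ProteinRecord(acc, (AA * (L // 20 + 1))[:L])


def mapping(protein, s, e):
    return PeptideMapping(protein.sequence[s - 1 : e], protein.accession, s, e)


def brute_force_track(pairs, L, mode="internal"):
    """Independent per-(peptide, bond) summation oracle."""
    scores = np.zeros(L + 1)
    for m, fc in pairs:
        for j in range(L + 1):
            lo, hi = (m.start, m.end - 1) if mode == "internal" else (m.start - 1, m.end)
            if lo <= j <= hi:
                scores[j] += fc
    return scores


class TestGroupedScore:
    def test_single_peptide_step(self):
        prot = protein_of_length(10)
        track = grouped_aa_score([(mapping(prot, 3, 6), 4.0)], prot)
        expected = np.zeros(11)
        expected[3:6] = 4.0
        np.testing.assert_array_equal(track.scores, expected)
        assert track.counts[3:6].tolist() == [1, 1, 1]

    def test_overlapping_peptides_superpose(self):
        prot = protein_of_length(10)
        track = grouped_aa_score(
            [(mapping(prot, 3, 6), 4.0), (mapping(prot, 5, 9), -2.0)], prot
        )
        assert track.scores[5] == 2.0
        assert track.scores[3] == track.scores[4] == 4.0
        assert all(track.scores[j] == -2.0 for j in (6, 7, 8))

    def test_empty_set_gives_zero_track(self):
        prot = protein_of_length(10)
        track = grouped_aa_score([], prot)
        assert track.scores.sum() == 0 and track.normalized_mean == 0.0

    def test_wrong_protein_is_an_error(self):
        prot = protein_of_length(10)
        other = PeptideMapping("AC", "OTHER", 1, 2)
        with pytest.raises(ValueError):
            grouped_aa_score([(other, 1.0)], prot)

    def test_inclusive_mode_reaches_virtual_bonds(self):
        prot = protein_of_length(10)
        track = grouped_aa_score([(mapping(prot, 1, 10), 2.0)], prot, mode="inclusive")
        assert track.scores[0] == 2.0 and track.scores[10] == 2.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(20, 200))
        prot = protein_of_length(L)
        pairs = []
        for _ in range(int(rng.integers(1, 30))):
            s = int(rng.integers(1, L))
            e = int(rng.integers(s, L + 1))
            pairs.append((mapping(prot, s, e), float(rng.normal(0, 5))))
        track = grouped_aa_score(pairs, prot)
        np.testing.assert_allclose(track.scores, brute_force_track(pairs, L), atol=1e-12)

    def test_conservation_law(self):
        rng = np.random.default_rng(11)
        L = 120
        prot = protein_of_length(L)
        pairs = []
        for _ in range(25):
            s = int(rng.integers(1, L))
            e = int(rng.integers(s, L + 1))
            pairs.append((mapping(prot, s, e), float(rng.normal(0, 3))))
        track = grouped_aa_score(pairs, prot)
        expected = sum(fc * (m.end - m.start) for m, fc in pairs)
        assert track.scores.sum() == pytest.approx(expected, abs=1e-9)

    def test_additivity_and_order_invariance(self):
        rng = np.random.default_rng(3)
        prot = protein_of_length(60)
        pairs = [
            (mapping(prot, int(s), int(s) + 5), float(f))
            for s, f in zip(rng.integers(1, 50, 10), rng.normal(0, 2, 10))
        ]
        a, b = pairs[:4], pairs[4:]
        whole = grouped_aa_score(pairs, prot).scores
        parts = grouped_aa_score(a, prot).scores + grouped_aa_score(b, prot).scores
        shuffled = grouped_aa_score(pairs[::-1], prot).scores
        np.testing.assert_allclose(whole, parts, atol=1e-12)
        np.testing.assert_allclose(whole, shuffled, atol=1e-12)

    def test_steps_only_at_peptide_termini(self):
        rng = np.random.default_rng(5)
        prot = protein_of_length(80)
        pairs = [
            (mapping(prot, int(s), int(s + ln)), float(f))
            for s, ln, f in zip(
                rng.integers(1, 60, 12), rng.integers(3, 15, 12), rng.normal(0, 2, 12)
            )
        ]
        track = grouped_aa_score(pairs, prot)
        termini = {m.start for m, _ in pairs} | {m.end for m, _ in pairs}
        for j in range(1, 81):
            if track.scores[j] != track.scores[j - 1]:
                assert j in termini

    def test_normalized_mean_uses_bond_count(self):
        prot = protein_of_length(11)
        track = grouped_aa_score([(mapping(prot, 1, 11), 5.0)], prot)
        assert track.normalized_mean == pytest.approx(5.0 * 10 / 10)


class TestCumulativeProfile:
    def test_doubling_and_identity(self):
        prot = protein_of_length(20)
        t = grouped_aa_score([(mapping(prot, 3, 9), 2.0)], prot, "A|B")
        zero = grouped_aa_score([], prot, "C|B")
        np.testing.assert_array_equal(cumulative_profile([t, t]).scores, 2 * t.scores)
        np.testing.assert_array_equal(cumulative_profile([t, zero]).scores, t.scores)

    def test_three_tracks_elementwise_sum(self):
        rng = np.random.default_rng(9)
        prot = protein_of_length(40)
        tracks = []
        for c in "abc":
            pairs = [
                (mapping(prot, int(s), int(s) + 4), float(f))
                for s, f in zip(rng.integers(1, 30, 5), rng.normal(0, 2, 5))
            ]
            tracks.append(grouped_aa_score(pairs, prot, c))
        total = cumulative_profile(tracks)
        np.testing.assert_allclose(
            total.scores, sum(t.scores for t in tracks), atol=1e-12
        )


class TestPointTaxonomy:
    def test_shared_terminus_is_stable(self):
        prot = protein_of_length(130, "IGF2")
        pairs = [
            (mapping(prot, 114, 126), -4.0),
            (mapping(prot, 116, 126), -3.0),
            (mapping(prot, 117, 126), -5.0),
        ]
        points = {r.label.render(): r for r in classify_points(pairs)}
        assert points["IGF2[126]_C"].point_class == "stable"
        assert len(points["IGF2[126]_C"].members) == 3
        assert points["IGF2[126]_C"].direction == -1
        for p in (114, 116, 117):
            assert points[f"IGF2[{p}]_N"].point_class == "dynamic"

    def test_single_peptide_gives_two_dynamic_points(self):
        prot = protein_of_length(30)
        points = classify_points([(mapping(prot, 10, 20), 2.0)])
        rendered = sorted(r.label.render() for r in points)
        assert rendered == ["PROT[10]_N", "PROT[20]_C"]
        assert all(r.point_class == "dynamic" for r in points)

    def test_adjacent_termini_stay_distinct(self):
        prot = protein_of_length(30)
        points = classify_points(
            [(mapping(prot, 5, 12), 2.0), (mapping(prot, 13, 20), 2.0)]
        )
        rendered = {r.label.render() for r in points}
        assert "PROT[12]_C" in rendered and "PROT[13]_N" in rendered
        assert not any(r.label.orientation == "B" for r in points)

    def test_same_residue_both_orientations_merges_to_b(self):
        prot = protein_of_length(30)
        points = classify_points(
            [(mapping(prot, 5, 12), 2.0), (mapping(prot, 12, 20), 3.0)]
        )
        (b_point,) = [r for r in points if r.label.orientation == "B"]
        assert b_point.label.position == 12 and b_point.point_class == "dynamic"


class TestTransitionPoints:
    def test_single_peptide_step_signs(self):
        prot = protein_of_length(10)
        pairs = [(mapping(prot, 3, 6), 4.0)]
        track = grouped_aa_score(pairs, prot)
        annotated = {
            r.label.render(): r
            for r in detect_transition_points(track, classify_points(pairs))
        }
        assert annotated["PROT[3]_N"].step == pytest.approx(4.0)
        assert annotated["PROT[3]_N"].step_sign == 1
        assert annotated["PROT[6]_C"].step == pytest.approx(-4.0)
        assert annotated["PROT[6]_C"].step_sign == -1
        assert all(r.is_transition for r in annotated.values())

    def test_flat_track_has_zero_steps(self):
        prot = protein_of_length(10)
        pairs = [(mapping(prot, 3, 6), 4.0), (mapping(prot, 3, 6), -4.0)]
        track = grouped_aa_score([], prot)
        annotated = detect_transition_points(track, classify_points(pairs))
        assert all(r.step == 0 and not r.is_transition for r in annotated)

    def test_nested_shared_c_terminus_step(self):
        prot = protein_of_length(20)
        pairs = [(mapping(prot, 4, 12), 4.0), (mapping(prot, 7, 12), 2.0)]
        track = grouped_aa_score(pairs, prot)
        annotated = {
            r.label.render(): r
            for r in detect_transition_points(track, classify_points(pairs))
        }
        assert annotated["PROT[12]_C"].step == pytest.approx(-6.0)
        assert annotated["PROT[12]_C"].point_class == "stable"

    def test_zero_step_points_kept_when_configured(self):
        prot = protein_of_length(10)
        pairs = [(mapping(prot, 3, 6), 4.0)]
        track = grouped_aa_score([], prot)  # flat: steps all zero
        annotated = detect_transition_points(
            track, classify_points(pairs), require_nonzero_step=False
        )
        assert all(r.is_transition for r in annotated)


class TestImportantPositions:
    def _points(self, sign):
        prot = protein_of_length(30)
        pairs = [(mapping(prot, 5, 12), 3.0 * sign)]
        track = grouped_aa_score(pairs, prot)
        return detect_transition_points(track, classify_points(pairs))

    def test_consistent_across_all_comparisons(self):
        by_comp = {c: self._points(+1) for c in ("TTvsCtr", "TIvsCtr", "TMvsCtr")}
        keys = {k for k, _ in important_positions(by_comp)}
        assert ("PROT", 5, "N") in keys and ("PROT", 12, "C") in keys

    def test_absent_in_one_comparison_disqualifies(self):
        by_comp = {
            "TTvsCtr": self._points(+1),
            "TIvsCtr": self._points(+1),
            "TMvsCtr": [],
        }
        assert important_positions(by_comp) == []

    def test_mixed_signs_disqualify(self):
        by_comp = {
            "TTvsCtr": self._points(+1),
            "TIvsCtr": self._points(+1),
            "TMvsCtr": self._points(-1),
        }
        assert important_positions(by_comp) == []


class TestSeverityAndProtease:
    @pytest.mark.parametrize(
        "scores,expected",
        [((1, 3, 9), "up"), ((-2, -5, -9), "down"), ((1, 5, 2), "none"),
         ((1, 1, 2), "none")],
    )
    def test_severity_trend(self, scores, expected):
        assert severity_trend(scores) == expected

    def test_severity_epsilon_tolerance(self):
        assert severity_trend((1.0, 1.05, 1.1), epsilon=0.2) == "none"

    def test_protease_activity_percentages(self):
        table = {"p1": ["A"], "p2": ["A", "B"], "p3": ["A"]}
        act = protease_activity(table)
        assert act["A"] == pytest.approx(75.0)
        assert act["B"] == pytest.approx(25.0)
        assert act.sum() == pytest.approx(100.0)

    def test_protease_activity_examples(self):
        assert protease_activity({"p": ["X"]})["X"] == 100.0
        act = protease_activity({"a": ["A", "B"], "b": ["A", "B", "C", "C"],
                                 "c": ["C", "C"]})
        assert act.tolist() == [25.0, 25.0, 50.0]
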