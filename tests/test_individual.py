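"""Individual aa-scores: calibration, the four routes, exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from pepsite.core import PeptideMapping, PositionLabel
from pepsite.individual import (
    PeptideCluster,
    apply_exclusion_rule,
    build_clusters,
    build_reference,
    fit_calibration,
    position_score_matrix,
    score_absolute,
    score_heavy_ratio,
    score_reference_ratio,
)
from pepsite.simulate import SimulationConfig, simulate_prm


def cluster(members, heavy=None):
    return PeptideCluster(
        PositionLabel("PROT", 90, "C"),
        list(members),
        heavy_available=heavy or {},
    )


class TestCalibration:
    def test_perfect_line(self):
        curve = fit_calibration([1, 2, 4], [1, 2, 4], "PEP")
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        amount, extrapolated = curve.back_calc(3.0)
        assert amount == pytest.approx(3.0) and not extrapolated

    def test_back_calc_flags_extrapolation(self):
        curve = fit_calibration([1, 2, 4], [1, 2, 4])
        _, extrapolated = curve.back_calc(10.0)
        assert extrapolated

    def test_noisy_slope_within_five_percent(self):
        rng = np.random.default_rng(12)
        amounts = np.geomspace(0.5, 32, 8)
        true_slope = 2.5
        ratios = true_slope * amounts + rng.normal(0, 0.05, 8)
        curve = fit_calibration(amounts, ratios)
        assert curve.slope == pytest.approx(true_slope, rel=0.05)
        assert curve.r_squared > 0.99

    def test_two_points_is_an_error(self):
        with pytest.raises(ValueError):
            fit_calibration([1, 2], [1, 2])

    def test_non_responsive_standard_is_an_error(self):
        with pytest.raises(ValueError):
            fit_calibration([1, 2, 4], [4, 2, 1])

    def test_non_positive_amounts_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([0, 1, 2], [0, 1, 2])


class TestScoringRoutes:
    def test_absolute_sums_amounts(self):
        amounts = pd.DataFrame(
            {"s1": [2.0, 3.5], "s2": [1.0, 1.0]}, index=["p1", "p2"]
        )
        score = score_absolute(cluster(["p1", "p2"]), amounts)
        assert score["s1"] == pytest.approx(5.5)

    def test_absolute_missing_member_excludes_sample(self):
        amounts = pd.DataFrame(
            {"s1": [2.0, np.nan], "s2": [1.0, 1.0]}, index=["p1", "p2"]
        )
        score = score_absolute(cluster(["p1", "p2"]), amounts)
        assert np.isnan(score["s1"]) and score["s2"] == pytest.approx(2.0)

    def test_heavy_ratio_sums(self):
        light = pd.DataFrame({"s1": [1.0, 3.0]}, index=["p1", "p2"])
        heavy = pd.DataFrame({"s1": [2.0, 2.0]}, index=["p1", "p2"])
        score = score_heavy_ratio(cluster(["p1", "p2"]), light, heavy)
        assert score["s1"] == pytest.approx(0.5 + 1.5)

    def test_heavy_zero_triggers_exclusion(self):
        light = pd.DataFrame({"s1": [1.0, 3.0]}, index=["p1", "p2"])
        heavy = pd.DataFrame({"s1": [2.0, 0.0]}, index=["p1", "p2"])
        score = score_heavy_ratio(cluster(["p1", "p2"]), light, heavy)
        assert np.isnan(score["s1"])

    def test_equal_ratios_scale_with_members(self):
        light = pd.DataFrame({"s1": [2.0, 2.0, 2.0]}, index=list("abc"))
        heavy = pd.DataFrame({"s1": [1.0, 1.0, 1.0]}, index=list("abc"))
        score = score_heavy_ratio(cluster(list("abc")), light, heavy)
        assert score["s1"] == pytest.approx(3 * 2.0)

    def test_reference_ratio_sums(self):
        intens = pd.DataFrame({"s1": [4.0, 1.0]}, index=["p1", "p2"])
        ref = pd.Series({"p1": 2.0, "p2": 2.0})
        score = score_reference_ratio(cluster(["p1", "p2"]), intens, ref)
        assert score["s1"] == pytest.approx(2.5)

    def test_discovery_union_rule(self):
        intens = pd.DataFrame(
            {"s1": [4.0, np.nan, 6.0], "s2": [np.nan] * 3}, index=["p1", "p2", "p3"]
        )
        ref = pd.Series({"p1": 2.0, "p2": 2.0, "p3": 3.0})
        score = score_reference_ratio(
            cluster(["p1", "p2", "p3"]), intens, ref, discovery=True
        )
        assert score["s1"] == pytest.approx(2.0 + 2.0)   # members 1 and 3
        assert np.isnan(score["s2"])                     # no member observed

    def test_target_only_mode(self):
        intens = pd.DataFrame({"s1": [4.0, 8.0]}, index=["p1", "p2"])
        ref = pd.Series({"p1": 2.0, "p2": 2.0})
        c = cluster(["p1", "p2"], heavy={"p1": True, "p2": False})
        score = score_reference_ratio(c, intens, ref, member_mode="target-only")
        assert score["s1"] == pytest.approx(2.0)

    def test_member_without_reference_dropped_for_all_samples(self):
        intens = pd.DataFrame({"s1": [4.0, 8.0]}, index=["p1", "p2"])
        ref = pd.Series({"p1": 2.0})  # p2 unusable
        score = score_reference_ratio(
            cluster(["p1", "p2"]), intens, ref, discovery=True
        )
        assert score["s1"] == pytest.approx(2.0)

    def test_scale_equivariance_of_reference_score(self):
        rng = np.random.default_rng(5)
        intens = pd.DataFrame(
            rng.lognormal(3, 1, size=(3, 4)), index=list("abc"),
            columns=[f"s{i}" for i in range(4)],
        )
        ref = pd.Series(rng.lognormal(3, 1, 3), index=list("abc"))
        base = score_reference_ratio(cluster(list("abc")), intens, ref)
        scaled = score_reference_ratio(cluster(list("abc")), intens * 7.0, ref)
        np.testing.assert_allclose(scaled, 7.0 * base)


class TestExclusionRule:
    def test_missing_member_excludes_sample(self):
        detected = pd.DataFrame(
            {"s1": [1.0, np.nan], "s2": [1.0, 1.0]}, index=["p1", "p2"]
        )
        included = apply_exclusion_rule(cluster(["p1", "p2"]), detected)
        assert not included["s1"] and included["s2"]


class TestReference:
    def test_mean_over_observed_replicates(self):
        runs = pd.DataFrame(
            [[100.0, 110.0, 90.0, np.nan, 100.0]], index=["pep"],
            columns=[f"r{i}" for i in range(5)],
        )
        ref = build_reference(runs)
        assert ref.loc["pep", "reference"] == pytest.approx(100.0)
        assert ref.loc["pep", "n_detected"] == 4
        assert ref.loc["pep", "usable"]

    def test_all_missing_is_unusable(self):
        runs = pd.DataFrame([[np.nan] * 5], index=["pep"],
                            columns=[f"r{i}" for i in range(5)])
        ref = build_reference(runs)
        assert not ref.loc["pep", "usable"]

    def test_single_detection_usable_at_default(self):
        runs = pd.DataFrame([[np.nan, 50.0, np.nan]], index=["pep"],
                            columns=list("abc"))
        ref = build_reference(runs)
        assert ref.loc["pep", "usable"] and ref.loc["pep", "n_detected"] == 1

    def test_geometric_mean_option(self):
        runs = pd.DataFrame([[10.0, 1000.0]], index=["pep"], columns=list("ab"))
        ref = build_reference(runs, method="geometric")
        assert ref.loc["pep", "reference"] == pytest.approx(100.0)


class TestDiscoveryDriver:
    def mappings(self):
        return [
            PeptideMapping("AAAA", "PROT", 10, 13),
            PeptideMapping("AAAAA", "PROT", 9, 13),
            PeptideMapping("CCCC", "PROT", 20, 23),
        ]

    def test_clusters_share_terminal_residue(self):
        clusters = {c.label.render(): c for c in build_clusters(self.mappings())}
        assert clusters["PROT[13]_C"].members == ["AAAA", "AAAAA"]
        assert clusters["PROT[10]_N"].members == ["AAAA"]

    def test_position_missingness_dominates_members(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(12)]
        matrix = pd.DataFrame(
            rng.lognormal(3, 0.5, size=(3, 12)),
            index=["AAAA", "AAAAA", "CCCC"], columns=samples,
        )
        drop = rng.random(matrix.shape) < 0.4
        matrix = matrix.mask(drop)
        ref = pd.Series(1.0, index=matrix.index)
        positions, clusters = position_score_matrix(matrix, self.mappings(), ref)
        for c in clusters:
            pos_missing = positions.loc[c.label.render()].isna().mean()
            member_missing = matrix.loc[c.members].isna().mean(axis=1)
            assert pos_missing <= member_missing.min() + 1e-12


class TestMethodConcordance:
    def test_four_routes_agree_on_noise_free_data(self):
        sim = simulate_prm(config=SimulationConfig(seed=3), noise_sigma=0.0)
        members = list(sim.amounts.index)
        curves = {
            m: fit_calibration(
                sim.calibration.query("peptide == @m")["amount"],
                sim.calibration.query("peptide == @m")["ratio"], m)
            for m in members
        }
        ratios = sim.light / sim.heavy
        amounts = pd.DataFrame(
            {s: [curves[m].back_calc(ratios.loc[m, s])[0] for m in members]
             for s in ratios.columns}, index=members,
        )
        c = PeptideCluster(PositionLabel("PROT", 90, "C"), members,
                           heavy_available={m: True for m in members})
        routes = {
            "absolute": score_absolute(c, amounts),
            "heavy": score_heavy_ratio(c, sim.light, sim.heavy),
            "ref_target": score_reference_ratio(
                c, sim.light, sim.reference, member_mode="target-only"),
            "ref_all": score_reference_ratio(c, sim.light, sim.reference),
        }
        from scipy.stats import spearmanr

        names = list(routes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                rho = spearmanr(routes[a], routes[b]).statistic
                assert rho == pytest.approx(1.0)
        # planted two-fold site effect is exact for every route
        design = sim.design
        for score in routes.values():
            case = score[design.samples_in("Case")].mean()
            ctrl = score[design.samples_in("Ctr")].mean()
            assert case / ctrl == pytest.approx(2.0, abs=1e-9)
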