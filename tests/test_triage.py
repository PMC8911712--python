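"""Control-anchored docking triage: ANOVA, Tukey letters, classification."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range

from vocscreen import (
    Role,
    ScorePanelSpec,
    ScoreSet,
    abundance_coverage,
    anova_tukey_cld,
    average_pose_scores,
    classify_compounds,
    cross_site_overlap,
    gen_scores,
    summarize_groups,
    triage_site,
)
from vocscreen.errors import DegenerateVarianceError, ValidationError
from vocscreen.triage import TriageResult, read_scores, scoresets_from_frame

from conftest import random_score_panel


def make_set(ligand, poses, role=Role.CANDIDATE, site="S"):
    return ScoreSet(ligand_id=ligand, site_id=site, role=role, pose_scores=poses)


def tukey_reject_oracle(score_sets, alpha=0.05):
    """Independent all-pairs Tukey HSD via the studentized-range distribution."""
    groups = {s.ligand_id: np.asarray(s.pose_scores, float) for s in score_sets}
    k = len(groups)
    n_total = sum(len(g) for g in groups.values())
    dfe = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / dfe
    reject = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        ga, gb = groups[a], groups[b]
        se = math.sqrt(mse / 2.0 * (1.0 / len(ga) + 1.0 / len(gb)))
        q = abs(ga.mean() - gb.mean()) / se
        p = studentized_range.sf(q, k, dfe)
        reject[frozenset((a, b))] = bool(p < alpha)
    return reject


class TestAveragePoseScores:
    def test_arithmetic_mean(self):
        assert average_pose_scores(make_set("L", [-6.0, -5.8, -5.6])) == pytest.approx(-5.8)

    def test_constant_poses(self):
        assert average_pose_scores(make_set("L", [-4.2] * 3)) == -4.2

    def test_means_match_brute_force_on_synthetic_panel(self):
        scores, _ = gen_scores(ScorePanelSpec(n_top=20, n_middle=20, n_worst=10, seed=3))
        sets = scoresets_from_frame(scores)
        assert len(sets) >= 50
        for s in sets:
            assert average_pose_scores(s) == pytest.approx(
                sum(s.pose_scores) / len(s.pose_scores)
            )

    def test_empty_pose_list_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            make_set("L", [])


class TestTukeyCld:
    def test_three_well_separated_ligands_get_distinct_letters(self):
        sets = [
            make_set("A", [-9.0, -9.1, -8.9]),
            make_set("B", [-6.0, -6.1, -5.9]),
            make_set("C", [-3.0, -3.1, -2.9]),
        ]
        grouping = anova_tukey_cld(sets)
        assert [grouping.letters[x] for x in "ABC"] == ["a", "b", "c"]
        oracle = tukey_reject_oracle(sets)
        assert all(oracle.values())

    def test_identical_pose_sets_share_a_letter(self):
        sets = [make_set("A", [-5.0, -5.2, -4.8]), make_set("B", [-5.0, -5.2, -4.8])]
        grouping = anova_tukey_cld(sets)
        assert set(grouping.letters["A"]) & set(grouping.letters["B"])

    def test_planted_two_cluster_panel_yields_two_letters(self):
        rng = np.random.default_rng(11)
        sd = 0.1
        sets = [
            make_set(f"T{i}", list(rng.normal(-9.0, sd, 3))) for i in range(3)
        ] + [make_set(f"W{i}", list(rng.normal(-4.0, sd, 3))) for i in range(3)]
        grouping = anova_tukey_cld(sets)
        assert len(set(grouping.letters.values())) == 2
        top_letters = {grouping.letters[f"T{i}"] for i in range(3)}
        assert len(top_letters) == 1

    def test_letters_separate_iff_independent_tukey_rejects(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            sets = random_score_panel(rng)
            grouping = anova_tukey_cld(sets)
            oracle = tukey_reject_oracle(sets)
            for pair, rejected in oracle.items():
                a, b = sorted(pair)
                assert grouping.share_letter(a, b) == (not rejected), (a, b)

    def test_zero_variance_everywhere_is_degenerate(self):
        sets = [make_set("A", [-5.0, -5.0, -5.0]), make_set("B", [-3.0, -3.0, -3.0])]
        with pytest.raises(DegenerateVarianceError, match="jitter"):
            anova_tukey_cld(sets)

    def test_anova_statistics_match_scipy(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(8)
        sets = random_score_panel(rng)
        grouping = anova_tukey_cld(sets)
        f, p = f_oneway(*[s.pose_scores for s in sets])
        assert grouping.f_statistic == pytest.approx(float(f))
        assert grouping.p_value == pytest.approx(float(p))


def control_panel(site="S"):
    """Panel with clean anchors for classification tests."""
    rng = np.random.default_rng(99)

    def poses(mean, sd=0.05):
        return list(rng.normal(mean, sd, 3))

    return [
        make_set("POSA", poses(-9.0), Role.POSITIVE_CONTROL, site),
        make_set("POSB", poses(-8.6), Role.POSITIVE_CONTROL, site),
        make_set("NEGA", poses(-4.0), Role.NEGATIVE_CONTROL, site),
        make_set("NEGB", poses(-4.4), Role.NEGATIVE_CONTROL, site),
        make_set("CTOP", poses(-9.0), Role.CANDIDATE, site),
        make_set("CMID", poses(-6.5), Role.CANDIDATE, site),
        make_set("CWRS", poses(-4.0), Role.CANDIDATE, site),
    ]


class TestClassification:
    def test_anchor_aligned_candidates(self):
        sets = control_panel()
        result = triage_site(sets)
        assert result.labels == {"CTOP": "TOP", "CMID": "MIDDLE", "CWRS": "WORST"}
        assert result.anchor_top[0] == "POSA"
        assert result.anchor_worst[0] == "NEGA"

    def test_missing_controls_rejected(self):
        sets = [s for s in control_panel() if s.role is Role.CANDIDATE]
        grouping = anova_tukey_cld(sets)
        with pytest.raises(ValidationError, match="control"):
            classify_compounds(grouping, sets)

    def test_classification_invariant_to_input_order(self):
        sets = control_panel()
        result = triage_site(sets)
        shuffled = sets[:]
        random.Random(4).shuffle(shuffled)
        assert triage_site(shuffled).labels == result.labels

    def test_planted_panel_recovery_at_least_90pct(self, planted_panel):
        sets, truth = planted_panel
        result = triage_site(sets)
        accuracy = np.mean([result.labels[lig] == truth[lig] for lig in truth.index])
        assert accuracy >= 0.90

    def test_candidate_between_anchors_does_not_relabel_existing(self):
        sets = control_panel()
        before = triage_site(sets).labels
        extra = make_set("CNEW", [-6.51, -6.49, -6.50], Role.CANDIDATE)
        after = triage_site(sets + [extra]).labels
        assert {k: v for k, v in after.items() if k != "CNEW"} == before


class TestCrossSiteOverlap:
    @staticmethod
    def result(site, labels):
        return TriageResult(
            site_id=site, labels=labels, anchor_top=("P", -9.0), anchor_worst=("N", -4.0)
        )

    def test_identical_results_intersect_to_the_top_set(self):
        labels = {"A": "TOP", "B": "MIDDLE", "C": "WORST"}
        overlap = cross_site_overlap([self.result("S1", labels), self.result("S2", dict(labels))])
        assert overlap.intersections["TOP"][("S1", "S2")] == {"A"}

    def test_disjoint_top_sets_have_empty_intersection(self):
        r1 = self.result("S1", {"A": "TOP", "B": "WORST"})
        r2 = self.result("S2", {"A": "WORST", "B": "TOP"})
        overlap = cross_site_overlap([r1, r2])
        assert overlap.intersections["TOP"][("S1", "S2")] == set()

    def test_random_labels_match_brute_force_set_algebra(self):
        rng = np.random.default_rng(31)
        ligands = [f"L{i}" for i in range(12)]
        sites = ["S1", "S2", "S3"]
        results = [
            self.result(
                site,
                {lig: ["TOP", "MIDDLE", "WORST"][rng.integers(3)] for lig in ligands},
            )
            for site in sites
        ]
        overlap = cross_site_overlap(results)
        for label in ("TOP", "MIDDLE", "WORST"):
            for k in (2, 3):
                for combo in itertools.combinations(sites, k):
                    expected = {
                        lig
                        for lig in ligands
                        if all(
                            next(r for r in results if r.site_id == s).labels[lig]
                            == label
                            for s in combo
                        )
                    }
                    assert overlap.intersections[label][combo] == expected

    def test_site_specific_binder_flagged(self):
        r1 = self.result("COX1", {"23": "WORST", "4": "TOP"})
        r2 = self.result("iNOSas", {"23": "WORST", "4": "TOP"})
        r3 = self.result("iNOScs", {"23": "TOP", "4": "MIDDLE"})
        overlap = cross_site_overlap([r1, r2, r3])
        assert overlap.site_specific == {"23": "iNOScs"}

    def test_mismatched_universes_rejected(self):
        r1 = self.result("S1", {"A": "TOP"})
        r2 = self.result("S2", {"B": "TOP"})
        with pytest.raises(ValidationError, match="mismatched"):
            cross_site_overlap([r1, r2])


class TestSummarizeGroups:
    @staticmethod
    def profile_backed_panel(reference_profile):
        """Candidates named by reference compound ids, controls outside."""
        rng = np.random.default_rng(17)

        def poses(mean):
            return list(rng.normal(mean, 0.05, 3))

        sets = [
            make_set("ARA", poses(-9.0), Role.POSITIVE_CONTROL, "COX1"),
            make_set("GLC", poses(-4.0), Role.NEGATIVE_CONTROL, "COX1"),
        ]
        means = {"11": -9.0, "2": -6.5, "19": -6.5, "18": -4.0}
        for lig, mean in means.items():
            sets.append(make_set(lig, poses(mean), Role.CANDIDATE, "COX1"))
        return sets

    def test_single_ligand_group_statistics_equal_that_ligand(self, reference_profile):
        sets = self.profile_backed_panel(reference_profile)
        result = triage_site(sets)
        assert result.labels["11"] == "TOP"
        summary = summarize_groups(result, reference_profile).set_index("group")
        top = summary.loc["TOP"]
        caryophyllene = reference_profile.compound(11)
        assert top["n_compounds"] == 1
        assert top["mean_abundance"] == pytest.approx(
            caryophyllene.mean_abundance(reference_profile.samples)
        )
        assert top["pct_sesquiterpene"] == 100.0

    def test_class_composition_sums_to_100(self, reference_profile):
        sets = self.profile_backed_panel(reference_profile)
        summary = summarize_groups(triage_site(sets), reference_profile)
        for _, row in summary.iterrows():
            if row["n_compounds"]:
                total = (
                    row["pct_monoterpene"]
                    + row["pct_sesquiterpene"]
                    + row["pct_other"]
                )
                assert total == pytest.approx(100.0)

    def test_descriptor_means_match_brute_force(self, reference_profile):
        sets = self.profile_backed_panel(reference_profile)
        result = triage_site(sets)
        desc = pd.DataFrame(
            {"polarizability": [20.0, 18.0, 25.0, 10.0]},
            index=["11", "2", "19", "18"],
        )
        summary = summarize_groups(result, reference_profile, descriptors=desc)
        for _, row in summary.iterrows():
            ligs = [l for l in row["ligands"].split(",") if l]
            if ligs:
                assert row["mean_polarizability"] == pytest.approx(
                    desc.loc[ligs, "polarizability"].mean()
                )
                assert row["mean_score"] == pytest.approx(
                    np.mean([result.grouping.means[l] for l in ligs])
                )

    def test_unresolvable_ligand_id_is_an_error(self, reference_profile):
        result = TriageResult(
            site_id="COX1",
            labels={"NOPE": "TOP"},
            anchor_top=("P", -9.0),
            anchor_worst=("N", -4.0),
        )
        with pytest.raises(ValidationError, match="NOPE"):
            summarize_groups(result, reference_profile)


class TestAbundanceCoverage:
    @staticmethod
    def result_for(reference_profile, top_ids, middle_ids):
        labels = {}
        for c in reference_profile.compounds:
            lig = str(c.compound_id)
            if c.compound_id in top_ids:
                labels[lig] = "TOP"
            elif c.compound_id in middle_ids:
                labels[lig] = "MIDDLE"
            else:
                labels[lig] = "WORST"
        return TriageResult(
            site_id="COX1", labels=labels, anchor_top=("P", -9.0), anchor_worst=("N", -4.0)
        )

    def test_matches_brute_force_mass_fraction(self, reference_profile):
        result = self.result_for(reference_profile, {2, 11}, {19})
        pct = abundance_coverage(result, reference_profile, groups=("TOP", "MIDDLE"))
        masses = {
            c.compound_id: c.mean_abundance(reference_profile.samples)
            for c in reference_profile.compounds
        }
        expected = (
            100.0
            * (masses[2] + masses[11] + masses[19])
            / sum(masses.values())
        )
        assert pct == pytest.approx(expected)

    def test_aggregation_rule_is_configurable(self, reference_profile):
        r1 = self.result_for(reference_profile, {2}, {11})
        r2 = self.result_for(reference_profile, {19}, set())
        top_only = abundance_coverage([r1, r2], reference_profile, groups=("TOP",))
        top_mid = abundance_coverage([r1, r2], reference_profile)
        per_site = abundance_coverage(
            [r1, r2], reference_profile, groups=("TOP",), across="per-site"
        )
        assert top_only < top_mid
        assert set(per_site) == {"COX1"} or set(per_site) == {"COX1", "COX1"}

    def test_per_site_mode_keys_on_sites(self, reference_profile):
        r1 = self.result_for(reference_profile, {2}, set())
        r2 = TriageResult(
            site_id="iNOSas",
            labels=r1.labels,
            anchor_top=("P", -9.0),
            anchor_worst=("N", -4.0),
        )
        per_site = abundance_coverage(
            [r1, r2], reference_profile, groups=("TOP",), across="per-site"
        )
        assert set(per_site) == {"COX1", "iNOSas"}


class TestScoreIO:
    def test_tabular_round_trip(self, tmp_path):
        scores, _ = gen_scores(ScorePanelSpec(seed=5))
        path = tmp_path / "scores.csv"
        scores.to_csv(path, index=False)
        sets = read_scores(path)
        assert {s.ligand_id for s in sets} == set(scores["ligand_id"])
        assert all(len(s.pose_scores) == 3 for s in sets)

    def test_vina_log_dialect(self, tmp_path):
        text = (
            "# ligand=CARYO site=COX1 role=CANDIDATE\n"
            "mode |   affinity | dist from best mode\n"
            "-----+------------+--------------------\n"
            "   1       -6.1      0.000      0.000\n"
            "   2       -6.0      1.234      2.345\n"
            "   3       -5.8      2.000      3.000\n"
            "   4       -5.1      2.500      3.500\n"
            "# ligand=ARA site=COX1 role=POSITIVE_CONTROL\n"
            "   1       -9.3      0.000      0.000\n"
            "   2       -9.1      1.000      1.500\n"
            "   3       -8.9      1.200      1.700\n"
        )
        path = tmp_path / "vina.log"
        path.write_text(text)
        sets = {s.ligand_id: s for s in read_scores(path)}
        assert sets["CARYO"].pose_scores == [-6.1, -6.0, -5.8]  # first three poses
        assert sets["ARA"].role is Role.POSITIVE_CONTROL
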