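import numpy as np
import pandas as pd
import pytest

from oracles import spearman_bruteforce
from xksilence.seq import reverse_complement
from xksilence.targets import (
    FilterThresholds,
    background_test,
    classify_and_report,
    consensus_filter,
    pair_correlation,
    predict_targets,
    seed_match,
    surrogate_expectation,
)

MIRNA = "UGUAGAUACUCCCUAAGGCUU"  # 21 nt


def _embed(site, flank_left=40, flank_right=40):
    left = ("ACGG" * 20)[:flank_left]
    right = ("CAAG" * 20)[:flank_right]
    return left + site + right


class TestSurrogateExpectation:
    def test_perfect_site_scores_zero_at_embedded_position(self):
        transcript = _embed(reverse_complement(MIRNA))
        score, start = surrogate_expectation(MIRNA, transcript)
        assert score == 0.0
        assert transcript[start : start + len(MIRNA)] == reverse_complement(MIRNA)

    def test_single_seed_mismatch_costs_two(self):
        # break pairing at miRNA position 5 (seed, doubled penalty)
        site = list(reverse_complement(MIRNA))
        pos_in_site = len(MIRNA) - 5  # 0-based site index pairing position 5
        original = site[pos_in_site]
        site[pos_in_site] = {"A": "C", "C": "A", "G": "A", "U": "C"}[original]
        score, _ = surrogate_expectation(MIRNA, _embed("".join(site)))
        assert score == 2.0

    def test_gu_wobble_outside_seed_costs_half(self):
        # make the pairing at miRNA position 17 (G, outside the seed) a
        # G:U wobble instead of the Watson-Crick G:C
        m17 = MIRNA[16]
        assert m17 == "G"
        site = list(reverse_complement(MIRNA))
        pos_in_site = len(MIRNA) - 17
        assert site[pos_in_site] == "C"
        site[pos_in_site] = "U"
        score, _ = surrogate_expectation(MIRNA, _embed("".join(site)))
        assert score == 0.5

    def test_transcript_shorter_than_mirna_gives_none(self):
        assert surrogate_expectation(MIRNA, "ACGUACGU") is None

    def test_score_above_cutoff_gives_none(self):
        assert surrogate_expectation(MIRNA, "A" * 100, cutoff=5.0) is None


def test_seed_match_requires_perfect_seed_pairing():
    transcript = _embed(reverse_complement(MIRNA))
    assert seed_match(MIRNA, transcript)
    # disrupt one seed position (position 7)
    site = list(reverse_complement(MIRNA))
    idx = len(MIRNA) - 7
    site[idx] = "A" if site[idx] != "A" else "C"
    assert not seed_match(MIRNA, _embed("".join(site)))


def test_predict_targets_emits_both_tools_for_planted_site():
    transcripts = {"t1": _embed(reverse_complement(MIRNA)), "t2": "ACGU" * 60}
    pred = predict_targets({"m1": MIRNA}, transcripts)
    t1 = pred[pred["transcript_id"] == "t1"]
    assert set(t1["tool"]) == {"expectation", "seedmatch"}
    assert (pred["style"] == "plant").all()


class TestConsensus:
    def _pred(self, rows):
        return pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "tool", "style", "score"])

    def test_two_plant_tools_pass(self):
        pred = self._pred([("m", "t", "psRNATarget", "plant", 1.0), ("m", "t", "TAPIR", "plant", 2.0)])
        assert consensus_filter(pred)["consensus"].iloc[0]

    def test_two_animal_tools_fail_three_pass(self):
        two = self._pred([("m", "t", "Miranda", "animal", 1.0), ("m", "t", "PITA", "animal", 1.0)])
        assert not consensus_filter(two)["consensus"].iloc[0]
        three = self._pred(
            [("m", "t", "Miranda", "animal", 1.0), ("m", "t", "PITA", "animal", 1.0),
             ("m", "t", "TargetSpy", "animal", 1.0)]
        )
        assert consensus_filter(three)["consensus"].iloc[0]

    def test_single_tool_fails(self):
        pred = self._pred([("m", "t", "expectation", "plant", 0.0)])
        assert not consensus_filter(pred)["consensus"].iloc[0]

    def test_duplicate_tool_rows_collapse_to_one_vote(self):
        pred = self._pred(
            [("m", "t", "TAPIR", "plant", 1.0), ("m", "t", "TAPIR", "plant", 1.0)]
        )
        out = consensus_filter(pred)
        assert out["n_plant_tools"].iloc[0] == 1
        assert not out["consensus"].iloc[0]


class TestPairCorrelation:
    def test_perfect_monotone_opposition(self):
        idx = ["s1", "s2", "s3", "s4"]
        rho, _ = pair_correlation(
            pd.Series([10, 8, 6, 4], index=idx), pd.Series([1, 2, 3, 4], index=idx)
        )
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_is_degenerate(self):
        idx = ["s1", "s2", "s3", "s4"]
        rho, r = pair_correlation(
            pd.Series([10, 8, 6, 4], index=idx), pd.Series([5, 5, 5, 5], index=idx)
        )
        assert np.isnan(rho) and np.isnan(r)

    def test_ties_match_bruteforce_mean_ranks(self):
        idx = [f"s{i}" for i in range(6)]
        x = pd.Series([3.0, 1.0, 4.0, 1.0, 5.0, 9.0], index=idx)
        y = pd.Series([2.0, 7.0, 1.0, 8.0, 2.0, 8.0], index=idx)
        rho, _ = pair_correlation(x, y)
        assert rho == pytest.approx(spearman_bruteforce(x, y), abs=1e-12)

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            pair_correlation(
                pd.Series([1, 2, 3, 4], index=["a", "b", "c", "d"]),
                pd.Series([1, 2, 3, 4], index=["a", "b", "c", "e"]),
            )


class TestBackgroundTest:
    def test_extreme_rank_passes(self):
        p = background_test(-1.0, [0.1] * 99)
        assert p == pytest.approx(0.01)
        assert p < 0.1

    def test_median_rank_fails(self):
        background = list(np.linspace(-0.5, 0.5, 101))
        p = background_test(0.0, background)
        assert 0.4 < p < 0.6

    def test_small_background_boundary(self):
        with pytest.warns(UserWarning, match="low-power"):
            p = background_test(-1.0, [0.0] * 9)
        assert p == pytest.approx(0.1)
        assert not p < 0.1  # strict threshold: boundary fails

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            background_test(-1.0, [float("nan")])


class TestThresholds:
    def test_profiles(self):
        assert FilterThresholds.profile("lenient").spearman_max == -0.4
        assert FilterThresholds.profile("strict").spearman_max == -0.7

    def test_positive_spearman_max_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(spearman_max=0.2)


class TestClassifyAndReport:
    """A constructed two-species scenario exercising every verdict."""

    @pytest.fixture()
    def scenario(self):
        samples = {
            **{f"cf_r{i}": "control_fungus" for i in (1, 2, 3)},
            **{f"wt_r{i}": "interaction_wt" for i in (1, 2, 3)},
            **{f"mut_r{i}": "interaction_mut1" for i in (1, 2, 3)},
        }
        cols = list(samples)
        mirna_norm = pd.DataFrame(
            {
                "m_down": [90, 100, 110, 10, 12, 14, 80, 95, 105],
                "m_flat": [50, 55, 45, 52, 48, 50, 51, 49, 50],
            },
            index=cols,
        ).T
        # t_anti: anticorrelated with m_down; t_flat: constant; t_weak: mild;
        # plus unrelated background transcripts for the percentile test
        fungus = pd.DataFrame(
            {
                "t_anti": [10, 9, 8, 100, 90, 95, 12, 11, 13],
                "t_flat": [50, 50, 50, 50, 50, 50, 50, 50, 50],
                "t_weak": [60, 40, 55, 70, 50, 80, 45, 66, 58],
                "t_same": [80, 85, 90, 8, 9, 10, 82, 88, 86],
            },
            index=cols,
        ).T
        rng = np.random.default_rng(0)
        background = pd.DataFrame(
            rng.normal(50, 10, size=(12, 9)),
            index=[f"bg{i}" for i in range(12)],
            columns=cols,
        )
        transcript_norm = {"fungus": pd.concat([fungus, background])}
        mirna_de = pd.DataFrame(
            {"log2FC": [-3.1, 0.1], "fdr": [0.001, 0.9], "call": ["down", "ns"]},
            index=["m_down", "m_flat"],
        )
        transcript_de = pd.DataFrame(
            {"log2FC": [3.2, 2.0, 0.4, -3.0], "fdr": [0.001, 0.001, 0.01, 0.001]},
            index=["t_anti", "t_flat", "t_weak", "t_same"],
        )
        votes = [
            ("m_down", t, tool, "plant", 1.0)
            for t in ["t_anti", "t_flat", "t_weak", "t_same"]
            for tool in ["toolA", "toolB"]
        ]
        votes.append(("m_flat", "t_anti", "toolA", "plant", 1.0))
        predictions = pd.DataFrame(
            votes, columns=["mirna_id", "transcript_id", "tool", "style", "score"]
        )
        return dict(
            predictions=predictions,
            mirna_de=mirna_de,
            transcript_de=transcript_de,
            mirna_norm=mirna_norm,
            transcript_norm=transcript_norm,
            mirna_species={"m_down": "plant", "m_flat": "plant"},
            transcript_species={
                t: "fungus" for t in list(transcript_norm["fungus"].index)
            },
            sample_conditions=samples,
        )

    def _run(self, scenario, **kw):
        thresholds = kw.pop("thresholds", FilterThresholds())
        return classify_and_report(thresholds=thresholds, **scenario)

    def test_verdicts_assigned_at_first_failing_stage(self, scenario):
        table = self._run(scenario).set_index(["mirna_id", "transcript_id"])
        assert table.loc[("m_flat", "t_anti"), "verdict"] == "rejected_consensus"
        assert table.loc[("m_down", "t_same"), "verdict"] == "rejected_expression"
        assert table.loc[("m_down", "t_flat"), "verdict"] == "rejected_correlation"
        assert table.loc[("m_down", "t_weak"), "verdict"] == "rejected_correlation"

    def test_anticorrelated_pair_retained_and_cross_kingdom(self, scenario):
        table = self._run(scenario)
        top = table.iloc[0]
        assert top["mirna_id"] == "m_down" and top["transcript_id"] == "t_anti"
        assert top["verdict"] == "retained"
        assert top["relationship"] == "cross_kingdom"
        assert top["spearman"] <= -0.7

    def test_same_species_pair_is_endogenous(self, scenario):
        scenario["mirna_species"] = {"m_down": "fungus", "m_flat": "fungus"}
        table = self._run(scenario)
        assert (table["relationship"] == "endogenous").all()

    def test_spearman_threshold_rejects_above_cutoff(self, scenario):
        strict = FilterThresholds(spearman_max=-0.99)
        table = self._run(scenario, thresholds=strict).set_index(
            ["mirna_id", "transcript_id"]
        )
        assert table.loc[("m_down", "t_anti"), "verdict"] == "rejected_correlation"

    def test_relaxing_thresholds_never_shrinks_retained_set(self, scenario):
        base = FilterThresholds()
        retained_base = set(
            map(tuple, self._run(scenario)[lambda t: t["verdict"] == "retained"][
                ["mirna_id", "transcript_id"]
            ].to_numpy())
        )
        relaxed = FilterThresholds(
            min_plant_tools=1,
            min_animal_tools=1,
            target_fdr_alpha=0.5,
            mirna_fc_threshold=0.0,
            spearman_max=-0.01,
            wilcoxon_alpha=0.9,
        )
        retained_relaxed = set(
            map(
                tuple,
                self._run(scenario, thresholds=relaxed)[
                    lambda t: t["verdict"] == "retained"
                ][["mirna_id", "transcript_id"]].to_numpy(),
            )
        )
        assert retained_base <= retained_relaxed

    def test_output_is_deterministic(self, scenario):
        a = self._run(scenario)
        b = self._run(scenario)
        pd.testing.assert_frame_equal(a, b)
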