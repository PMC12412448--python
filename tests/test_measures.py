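"""CSIM/SIM/Pr measures, exclusions, and the within-subject ANOVA."""

import numpy as np
import pandas as pd
import pytest

from mptruth import (
    aggregate,
    apply_exclusions,
    csim,
    measure_table,
    pairwise_followup,
    pr_index,
    pr_table,
    rm_anova_2x2,
    sim,
)


def _participant_trials(pid, cells):
    """Build trial records from {(plausibility, condition): [(old, fb), ...]}."""
    rows = []
    for (plaus, cond), responses in cells.items():
        for i, (old, fb) in enumerate(responses):
            rows.append(
                {
                    "participant": pid,
                    "statement": f"{plaus[:1]}_{cond[:2]}_{i}",
                    "plausibility": plaus,
                    "condition": cond,
                    "old_response": old,
                    "feedback_response": fb,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def hand_trials():
    """One participant, hand-constructed responses.

    plausible/true-feedback: 5 of 6 called old, 4 attributed "true"
    -> CSIM 0.8, SIM 4/6.
    """
    cells = {
        ("plausible", "true-feedback"): [
            ("old", "true"), ("old", "true"), ("old", "true"), ("old", "true"),
            ("old", "false"), ("new", None),
        ],
        ("plausible", "false-feedback"): [("old", "false")] * 6,
        ("plausible", "?-feedback"): [("old", "?")] * 6,
        ("plausible", "new"): [("new", None)] * 6,
        ("implausible", "true-feedback"): [("new", None)] * 6,
        ("implausible", "false-feedback"): [
            ("old", "false"), ("old", "true"), ("old", "?"),
            ("new", None), ("new", None), ("new", None),
        ],
        ("implausible", "?-feedback"): [("old", "?")] * 6,
        ("implausible", "new"): [("new", None), ("old", "true")] + [("new", None)] * 4,
    }
    return _participant_trials("p1", cells)


class TestDefinitions:
    def test_csim_hand_case(self, hand_trials):
        assert csim(hand_trials, "p1", "plausible", "true") == pytest.approx(0.8)
        assert sim(hand_trials, "p1", "plausible", "true") == pytest.approx(4 / 6)

    def test_csim_perfect_cell(self, hand_trials):
        assert csim(hand_trials, "p1", "plausible", "false") == 1.0
        assert sim(hand_trials, "p1", "plausible", "false") == 1.0

    def test_csim_undefined_on_empty_denominator(self, hand_trials):
        assert np.isnan(csim(hand_trials, "p1", "implausible", "true"))
        assert sim(hand_trials, "p1", "implausible", "true") == 0.0

    def test_csim_dominates_sim(self, sim_trials):
        table = measure_table(sim_trials)
        defined = table.dropna(subset=["csim"])
        assert (defined["csim"] >= defined["sim"] - 1e-12).all()

    def test_integer_identity(self, sim_trials):
        # csim * n_old == sim * n_targets == n_correct for every cell
        table = measure_table(sim_trials)
        defined = table.dropna(subset=["csim"])
        assert np.allclose(defined["csim"] * defined["n_old"], defined["n_correct"])
        assert np.allclose(table["sim"] * table["n_targets"], table["n_correct"])

    def test_question_feedback_not_in_measures(self, sim_trials):
        table = measure_table(sim_trials)
        assert set(table["feedback"]) == {"true", "false"}

    def test_pr_hand_case(self, hand_trials):
        # hits: 5 + 6 + 6 + 0 + 3 + 6 = 26 of 36; false alarms 1 of 12
        assert pr_index(hand_trials, "p1") == pytest.approx(26 / 36 - 1 / 12)

    def test_pr_extremes(self):
        perfect = _participant_trials("p", {
            ("plausible", "true-feedback"): [("old", "true")] * 6,
            ("plausible", "new"): [("new", None)] * 6,
        })
        assert pr_index(perfect, "p") == 1.0
        yes_everything = _participant_trials("p", {
            ("plausible", "true-feedback"): [("old", "true")] * 6,
            ("plausible", "new"): [("old", "true")] * 6,
        })
        assert pr_index(yes_everything, "p") == 0.0


class TestExclusions:
    def test_planted_violations_are_excluded(self, baseline_model, paper_theta):
        from mptruth import DesignSpec, simulate_trials

        trials, _ = simulate_trials(baseline_model, paper_theta,
                                    DesignSpec(n_participants=12), seed=30)
        pids = sorted(trials["participant"].unique())
        # plant one no-memory participant: answer "old"/"true" to everything
        bad = pids[0]
        trials.loc[trials["participant"] == bad, "old_response"] = "old"
        trials.loc[trials["participant"] == bad, "feedback_response"] = "true"
        flags = pd.DataFrame(
            {
                "participant": pids,
                "serious": [True] * 12,
                "took_notes": [False, True] + [False] * 10,
                "language_ok": [True] * 11 + [False],
            }
        )
        retained, log = apply_exclusions(trials, flags)
        assert set(log["participant"]) == {bad, pids[1], pids[11]}
        assert set(log["reason"]) == {"pr-nonpositive", "took-notes", "language"}
        assert set(retained["participant"]) == set(pids) - {bad, pids[1], pids[11]}

    def test_boundary_pr_retained_only_if_positive(self, baseline_model, paper_theta):
        from mptruth import DesignSpec, simulate_trials

        trials, _ = simulate_trials(baseline_model, paper_theta,
                                    DesignSpec(n_participants=6), seed=31)
        pr = pr_table(trials)
        retained, log = apply_exclusions(trials)
        for pid, v in pr.items():
            assert (pid in set(log["participant"])) == (v <= 0)


class TestAnova:
    def test_interaction_equals_squared_paired_t(self):
        # oracle identity on 50 random measure tables
        rng = np.random.default_rng(40)
        for _ in range(50):
            n = rng.integers(5, 30)
            y = rng.uniform(0, 1, (n, 4))
            table = pd.DataFrame(
                {
                    "participant": np.repeat(np.arange(n), 4),
                    "plausibility": np.tile(
                        ["plausible", "plausible", "implausible", "implausible"], n
                    ),
                    "feedback": np.tile(["true", "false", "true", "false"], n),
                    "sim": y.reshape(-1),
                }
            )
            res = rm_anova_2x2(table, "sim")
            from scipy import stats

            dd = (y[:, 0] - y[:, 1]) - (y[:, 2] - y[:, 3])
            t, p = stats.ttest_1samp(dd, 0.0)
            assert res["interaction"]["F"] == pytest.approx(t**2, rel=1e-10)
            assert res["interaction"]["p"] == pytest.approx(p, rel=1e-10)

    def test_agrees_with_pingouin(self, sim_trials):
        pingouin = pytest.importorskip("pingouin")
        table = measure_table(sim_trials)
        res = rm_anova_2x2(table, "sim")
        long = table.rename(columns={"sim": "dv"})[
            ["participant", "plausibility", "feedback", "dv"]
        ]
        ref = pingouin.rm_anova(
            data=long, dv="dv", within=["plausibility", "feedback"],
            subject="participant", detailed=True,
        ).set_index("Source")
        for effect, source in [
            ("plausibility", "plausibility"),
            ("feedback", "feedback"),
            ("interaction", "plausibility * feedback"),
        ]:
            assert res[effect]["F"] == pytest.approx(ref.loc[source, "F"], rel=1e-6)
            assert res[effect]["p"] == pytest.approx(ref.loc[source, "p_unc"], rel=1e-6)

    def test_constant_measure_gives_zero_f(self):
        table = pd.DataFrame(
            {
                "participant": np.repeat(np.arange(10), 4),
                "plausibility": np.tile(
                    ["plausible", "plausible", "implausible", "implausible"], 10
                ),
                "feedback": np.tile(["true", "false", "true", "false"], 10),
                "csim": 0.5,
            }
        )
        res = rm_anova_2x2(table, "csim")
        for eff in res.values():
            assert eff["F"] == 0.0

    def test_csim_listwise_deletion(self, baseline_model):
        # participants with an undefined CSIM cell drop from the CSIM ANOVA
        # but stay in the SIM ANOVA
        from mptruth import DesignSpec, make_effect_scenario, simulate_trials

        low_memory = dict(make_effect_scenario("paper-estimates"))
        for k in low_memory:
            if k.startswith("D"):
                low_memory[k] = 0.1
        low_memory.update({"b_P": 0.1, "b_I": 0.1})
        trials, _ = simulate_trials(
            baseline_model, low_memory, DesignSpec(n_participants=40), seed=50
        )
        table = measure_table(trials)
        n_incomplete = (
            table.pivot_table(index="participant", columns=["plausibility", "feedback"],
                              values="csim", dropna=False)
            .isna().any(axis=1).sum()
        )
        assert n_incomplete > 0  # the scenario plants missing cells
        res_c = rm_anova_2x2(table, "csim")
        res_s = rm_anova_2x2(table, "sim")
        assert res_c["interaction"]["n"] == 40 - n_incomplete
        assert res_s["interaction"]["n"] == 40

    def test_pairwise_followup_identical_columns(self):
        table = pd.DataFrame(
            {
                "participant": np.repeat(np.arange(8), 4),
                "plausibility": np.tile(
                    ["plausible", "plausible", "implausible", "implausible"], 8
                ),
                "feedback": np.tile(["true", "false", "true", "false"], 8),
                "sim": np.tile([0.4, 0.4, 0.6, 0.6], 8),
            }
        )
        res = pairwise_followup(table, "sim")
        assert res["plausible"]["t"] == 0.0 and res["plausible"]["p"] == 1.0

    def test_pairwise_followup_textbook_formula(self):
        a = np.array([0.8, 0.6, 0.7, 0.9, 0.5])
        b = np.array([0.6, 0.5, 0.7, 0.6, 0.4])
        table = pd.DataFrame(
            {
                "participant": np.repeat(np.arange(5), 4),
                "plausibility": np.tile(
                    ["plausible", "plausible", "implausible", "implausible"], 5
                ),
                "feedback": np.tile(["true", "false", "true", "false"], 5),
                "sim": np.column_stack([a, b, a, b]).reshape(-1),
            }
        )
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = pairwise_followup(table, "sim")
        assert res["plausible"]["t"] == pytest.approx(t_hand, rel=1e-12)
        assert res["plausible"]["df"] == 4


class TestAggregationRoundTrip:
    def test_counts_preserved(self, sim_trials):
        tab = aggregate(sim_trials)
        assert tab.grand_total == len(sim_trials)
        # per-cell totals match the trial counts
        cell_sizes = sim_trials.groupby(["plausibility", "condition"]).size()
        for lab, cnt in zip(tab.labels, tab.counts):
            assert cnt.sum() == cell_sizes[lab]

    def test_empty_input(self):
        tab = aggregate(pd.DataFrame(columns=["plausibility", "condition",
                                              "old_response", "feedback_response"]))
        assert tab.grand_total == 0.0
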