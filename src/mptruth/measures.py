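"""Behavioral measures of feedback attribution and the ANOVA stage.

Two participant-level measures of correct feedback attribution are
computed per plausibility x feedback ("true"/"false") cell:

* CSIM — conditional source identification measure: correct feedback
  attributions divided by the number of targets correctly called "old" in
  the cell (undefined when no target was called old);
* SIM — source identification measure: correct feedback attributions
  divided by all targets in the cell (always defined).

Participants with no item memory are screened with the discrimination
index ``Pr = hit rate - false-alarm rate``; ``Pr <= 0`` leads to
exclusion, alongside self-report criteria (non-serious participation,
note-taking, insufficient language skills).

The measures feed a 2 (plausibility) x 2 (feedback) within-subject ANOVA
computed from per-participant difference scores; with two-level factors
each effect's F equals the squared paired t on the corresponding contrast.
"?"-feedback trials are analysed in the processing-tree frequencies only,
not in CSIM/SIM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "measure_table",
    "csim",
    "sim",
    "pr_index",
    "pr_table",
    "apply_exclusions",
    "rm_anova_2x2",
    "pairwise_followup",
]

_FEEDBACK_CELLS = (("plausible", "true"), ("plausible", "false"),
                   ("implausible", "true"), ("implausible", "false"))


def _cell_stats(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x plausibility x feedback ('true'/'false') counts."""
    t = trials[trials["condition"].isin(["true-feedback", "false-feedback"])].copy()
    t["feedback"] = t["condition"].str.replace("-feedback", "", regex=False)
    t["called_old"] = (t["old_response"] == "old").astype(int)
    t["correct_attr"] = (
        (t["old_response"] == "old")
        & (t["feedback_response"].astype("string") == t["feedback"])
    ).astype(int)
    g = (
        t.groupby(["participant", "plausibility", "feedback"], observed=True)
        .agg(n_targets=("called_old", "size"),
             n_old=("called_old", "sum"),
             n_correct=("correct_attr", "sum"))
        .reset_index()
    )
    return g


def measure_table(trials: pd.DataFrame) -> pd.DataFrame:
    """CSIM and SIM per participant and (plausibility, feedback) cell.

    Returns a long DataFrame with columns ``participant, plausibility,
    feedback, n_targets, n_old, n_correct, csim, sim``; CSIM is NaN where
    no target in the cell was called old.
    """
    g = _cell_stats(trials)
    g["csim"] = np.where(g["n_old"] > 0, g["n_correct"] / g["n_old"], np.nan)
    g["sim"] = g["n_correct"] / g["n_targets"]
    return g


def csim(trials: pd.DataFrame, participant, plausibility: str, feedback: str) -> float:
    """Conditional source identification measure for one cell (NaN if no
    correct "old" response in the cell)."""
    if feedback not in ("true", "false"):
        raise ValueError("feedback must be 'true' or 'false'")
    g = measure_table(trials)
    row = g[(g["participant"] == participant)
            & (g["plausibility"] == plausibility) & (g["feedback"] == feedback)]
    if row.empty:
        raise KeyError(f"no trials for {participant}/{plausibility}/{feedback}")
    return float(row["csim"].iloc[0])


def sim(trials: pd.DataFrame, participant, plausibility: str, feedback: str) -> float:
    """Source identification measure for one cell (always defined)."""
    if feedback not in ("true", "false"):
        raise ValueError("feedback must be 'true' or 'false'")
    g = measure_table(trials)
    row = g[(g["participant"] == participant)
            & (g["plausibility"] == plausibility) & (g["feedback"] == feedback)]
    if row.empty:
        raise KeyError(f"no trials for {participant}/{plausibility}/{feedback}")
    return float(row["sim"].iloc[0])


def pr_table(trials: pd.DataFrame) -> pd.Series:
    """Discrimination index Pr = hit rate - false-alarm rate, per participant."""
    is_target = trials["condition"] != "new"
    called_old = trials["old_response"] == "old"
    df = pd.DataFrame(
        {"participant": trials["participant"], "target": is_target, "old": called_old}
    )
    g = df.groupby(["participant", "target"], observed=True)["old"].mean().unstack()
    if True not in g.columns or False not in g.columns:
        raise ValueError("Pr requires both target and new trials")
    return (g[True] - g[False]).rename("pr")


def pr_index(trials: pd.DataFrame, participant) -> float:
    """Discrimination index for one participant."""
    tab = pr_table(trials)
    if participant not in tab.index:
        raise KeyError(f"unknown participant {participant!r}")
    return float(tab.loc[participant])


def apply_exclusions(trials: pd.DataFrame, flags: pd.DataFrame | None = None):
    """Screen participants; returns ``(retained_trials, exclusion_log)``.

    ``flags`` (optional) carries self-report fields per participant:
    ``serious`` (bool), ``took_notes`` (bool), ``language_ok`` (bool).
    Exclusion reasons, in the order checked: language, non-serious
    participation, note-taking, and discrimination index ``Pr <= 0``.
    A participant may appear with several reasons in the log.
    """
    pr = pr_table(trials)
    reasons: list[tuple[str, str]] = []
    if flags is not None:
        flags = flags.set_index("participant") if "participant" in flags.columns else flags
        for pid, row in flags.iterrows():
            if "language_ok" in row.index and not bool(row["language_ok"]):
                reasons.append((pid, "language"))
            if "serious" in row.index and not bool(row["serious"]):
                reasons.append((pid, "non-serious"))
            if "took_notes" in row.index and bool(row["took_notes"]):
                reasons.append((pid, "took-notes"))
    for pid, v in pr.items():
        if v <= 0:
            reasons.append((pid, "pr-nonpositive"))
    log = pd.DataFrame(reasons, columns=["participant", "reason"])
    excluded = set(log["participant"])
    retained = trials[~trials["participant"].isin(excluded)].reset_index(drop=True)
    return retained, log


# ---------------------------------------------------------------------------
# ANOVA stage
# ---------------------------------------------------------------------------


def _wide_cells(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    wide = table.pivot_table(
        index="participant", columns=["plausibility", "feedback"],
        values=measure, aggfunc="first", dropna=False,
    )
    missing = [c for c in _FEEDBACK_CELLS if c not in wide.columns]
    if missing:
        raise ValueError(f"measure table lacks cells {missing}")
    return wide[list(_FEEDBACK_CELLS)]


def _effect_from_scores(scores: np.ndarray) -> dict:
    n = len(scores)
    m = scores.mean()
    sd = scores.std(ddof=1)
    if sd == 0:
        t = 0.0 if m == 0 else np.inf
    else:
        t = m / (sd / np.sqrt(n))
    F = t * t
    df2 = n - 1
    p = float(stats.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
    eta = F / (F + df2) if np.isfinite(F) else 1.0
    return {"F": float(F), "df1": 1, "df2": int(df2), "p": p,
            "partial_eta_sq": float(eta), "n": int(n)}


def rm_anova_2x2(table: pd.DataFrame, measure: str = "csim") -> dict[str, dict]:
    """2 (plausibility) x 2 (feedback) within-subject ANOVA.

    ``table`` is the output of :func:`measure_table`.  Participants with a
    missing cell are dropped listwise (only possible for CSIM).  Effects
    are computed from per-participant difference scores; for two-level
    within factors each F is exactly the squared paired t on the
    corresponding contrast, with df = (1, n - 1) and partial eta squared
    ``F / (F + df2)``.
    """
    wide = _wide_cells(table, measure).dropna()
    n = len(wide)
    if n < 2:
        raise ValueError("need at least 2 participants with complete cells")
    y = wide.to_numpy()  # columns: P-true, P-false, I-true, I-false
    plaus = (y[:, 0] + y[:, 1]) / 2 - (y[:, 2] + y[:, 3]) / 2
    feedback = (y[:, 0] + y[:, 2]) / 2 - (y[:, 1] + y[:, 3]) / 2
    interaction = (y[:, 0] - y[:, 1]) - (y[:, 2] - y[:, 3])
    return {
        "plausibility": _effect_from_scores(plaus),
        "feedback": _effect_from_scores(feedback),
        "interaction": _effect_from_scores(interaction),
    }


def pairwise_followup(table: pd.DataFrame, measure: str = "sim") -> dict[str, dict]:
    """Paired t tests of "true" vs "false" cells within each plausibility."""
    wide = _wide_cells(table, measure).dropna()
    out = {}
    for plaus, (c_true, c_false) in {
        "plausible": (("plausible", "true"), ("plausible", "false")),
        "implausible": (("implausible", "true"), ("implausible", "false")),
    }.items():
        a, b = wide[c_true].to_numpy(), wide[c_false].to_numpy()
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        out[plaus] = {
            "t": float(t), "df": len(a) - 1, "p": float(p),
            "mean_diff": float(np.mean(a - b)),
        }
    return out
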