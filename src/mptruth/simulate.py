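"""Synthetic trial-level data with the study's design.

The emulated design: each participant contributes 48 test trials — per
plausibility condition (plausible/implausible), 6 studied statements with
"true" feedback, 6 with "false" feedback, 6 with "?" feedback, and 6 new
statements.  Responses are drawn from the processing-tree category
probabilities at a chosen parameter vector; all participants share one
parameter vector (complete pooling, matching the aggregate fitting
strategy), optionally with beta-distributed heterogeneity for robustness
checks.

A master seed spawns one substream per participant, so regeneration with
the same seed is bit-identical and independent of participant count
prefixes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .estimation import FrequencyTable
from .model import CATEGORIES, ITEM_TYPES, PLAUSIBILITY, MptModel, build_feedback_model

__all__ = [
    "DesignSpec",
    "GroundTruth",
    "simulate_trials",
    "simulate_frequencies",
    "aggregate",
    "make_effect_scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class DesignSpec:
    """Test-phase design: participants x (plausibility x item type) cells."""

    n_participants: int = 328
    items_per_cell: int = 6

    def __post_init__(self):
        if self.n_participants < 1 or self.items_per_cell < 1:
            raise ValueError("design sizes must be positive")

    @property
    def trials_per_participant(self) -> int:
        return self.items_per_cell * len(PLAUSIBILITY) * len(ITEM_TYPES)

    @property
    def n_observations(self) -> int:
        return self.n_participants * self.trials_per_participant


@dataclass
class GroundTruth:
    """Generating parameters and settings stored alongside a dataset."""

    theta: dict[str, float]
    design: DesignSpec
    seed: int
    scenario: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "theta": self.theta,
                    "design": asdict(self.design),
                    "seed": self.seed,
                    "scenario": self.scenario,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["theta"], DesignSpec(**d["design"]), d["seed"], d.get("scenario"))


_RESPONSE_TO_OLDNEW = {"true": "old", "false": "old", "?": "old", "new": "new"}


def _tree_probs(model: MptModel, theta) -> np.ndarray:
    probs = model.category_probabilities(theta)
    if [t.condition for t in model.trees] != [
        (pl, it) for pl in PLAUSIBILITY for it in ITEM_TYPES
    ]:
        raise ValueError("simulate requires the full 8-tree feedback model")
    return probs


def simulate_trials(
    model: MptModel,
    theta,
    design: DesignSpec = DesignSpec(),
    seed: int = 0,
    heterogeneity: float | None = None,
):
    """Simulate trial-level responses; returns ``(trials, GroundTruth)``.

    ``trials`` is a DataFrame with columns ``participant, statement,
    plausibility, condition, old_response, feedback_response`` (the feedback
    attribution is present exactly when the old/new response is "old").
    With ``heterogeneity`` set, each participant's parameter vector is drawn
    from Beta distributions with the scenario values as means and the given
    precision (sum of Beta shape parameters).
    """
    probs = _tree_probs(model, theta)
    full_theta = model.expand_theta(theta)
    # heterogeneity draws per constraint class (aliases stay tied)
    names = model.free_parameters
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(design.n_participants)
    cells = [(pl, it) for pl in PLAUSIBILITY for it in ITEM_TYPES]
    m = design.items_per_cell

    statement_ids = np.concatenate([
        np.array([
            f"{'P' if cell[0] == 'plausible' else 'I'}"
            f"_{cell[1].replace('-feedback', '').replace('?', 'q')}_{i + 1:02d}"
            for i in range(m)
        ])
        for cell in cells
    ])
    # response-category code per participant x trial (cells concatenated)
    codes = np.empty((design.n_participants, len(cells) * m), dtype=np.int8)
    cum = np.cumsum(probs, axis=1)
    for p_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        if heterogeneity is not None:
            nu = float(heterogeneity)
            vals = {}
            for n in names:
                mu = min(max(full_theta[n], 1e-3), 1 - 1e-3)
                vals[n] = rng.beta(mu * nu, (1 - mu) * nu)
            cum = np.cumsum(model.category_probabilities(vals), axis=1)
        u = rng.random((len(cells), m))
        codes[p_idx] = (u[:, :, None] > cum[:, None, :]).sum(axis=2).reshape(-1)

    n_trials = codes.size
    resp = np.asarray(CATEGORIES, dtype=object)[codes.reshape(-1)]
    trials = pd.DataFrame(
        {
            "participant": np.repeat(
                [f"p{i + 1:04d}" for i in range(design.n_participants)],
                len(cells) * m,
            ),
            "statement": np.tile(statement_ids, design.n_participants),
            "plausibility": np.tile(
                np.repeat([c[0] for c in cells], m), design.n_participants
            ),
            "condition": np.tile(
                np.repeat([c[1] for c in cells], m), design.n_participants
            ),
            "old_response": np.where(resp == "new", "new", "old"),
            "feedback_response": pd.array(
                np.where(resp == "new", None, resp), dtype="string"
            ),
        }
    )
    return trials, GroundTruth(dict(full_theta), design, seed)


def simulate_frequencies(
    model: MptModel, theta, design: DesignSpec = DesignSpec(), seed: int = 0
):
    """Simulate an aggregated frequency table directly.

    Under participant homogeneity the pooled counts in each design cell are
    multinomial with ``n = n_participants * items_per_cell``, so sampling at
    the aggregate level is distributionally identical to aggregating
    simulated trials — and much faster for simulation studies.
    """
    probs = _tree_probs(model, theta)
    rng = np.random.default_rng(seed)
    n_cell = design.n_participants * design.items_per_cell
    counts = [rng.multinomial(n_cell, p) for p in probs]
    labels = [(pl, it) for pl in PLAUSIBILITY for it in ITEM_TYPES]
    tab = FrequencyTable(counts, labels, [CATEGORIES] * len(labels))
    return tab, GroundTruth(dict(model.expand_theta(theta)), design, seed)


def aggregate(trials: pd.DataFrame) -> FrequencyTable:
    """Pool trial records into the canonical 8x4 frequency table."""
    tab = FrequencyTable.full_design_zeros()
    pos = {lab: i for i, lab in enumerate(tab.labels)}
    cpos = {c: j for j, c in enumerate(CATEGORIES)}
    if len(trials) == 0:
        return tab
    required = {"plausibility", "condition", "old_response"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial records lack columns {sorted(required - set(trials.columns))}")
    resp = np.where(
        trials["old_response"].to_numpy() == "new",
        "new",
        trials["feedback_response"].fillna("").to_numpy(),
    )
    if (resp == "").any():
        raise ValueError("old response without feedback attribution")
    grouped = (
        pd.DataFrame(
            {
                "plausibility": trials["plausibility"],
                "item_type": trials["condition"],
                "response": resp,
            }
        )
        .value_counts()
        .reset_index(name="count")
    )
    for _, row in grouped.iterrows():
        key = (row["plausibility"], row["item_type"])
        if key not in pos or row["response"] not in cpos:
            raise ValueError(f"malformed trial cell {key} / {row['response']!r}")
        tab.counts[pos[key]][cpos[row["response"]]] += row["count"]
    return tab


# ---------------------------------------------------------------------------
# Named generating scenarios
# ---------------------------------------------------------------------------


def _base_estimates() -> dict[str, float]:
    """Aggregate-fit point estimates from the study data (the
    "paper-estimates" scenario)."""
    return {
        # plausible
        "D_P_true": 0.75, "D_P_false": 0.70, "D_P_q": 0.70, "D_P_new": 0.70,
        "d_P_true": 0.73, "d_P_false": 0.76, "d_P_q": 0.23,
        "b_P": 0.43, "a_fb_P": 0.44, "a_true_P": 0.54,
        "g_fb_P": 0.73, "g_true_P": 0.65,
        # implausible
        "D_I_true": 0.75, "D_I_false": 0.79, "D_I_q": 0.72, "D_I_new": 0.72,
        "d_I_true": 0.77, "d_I_false": 0.62, "d_I_q": 0.43,
        "b_I": 0.37, "a_fb_I": 0.56, "a_true_I": 0.29,
        "g_fb_I": 0.64, "g_true_I": 0.36,
    }


def _null_theta() -> dict[str, float]:
    t = _base_estimates()
    # equate every tested pair at the mean of the point estimates
    for a, b in [
        ("D_P_true", "D_P_false"), ("D_I_true", "D_I_false"),
        ("d_P_true", "d_P_false"), ("d_I_true", "d_I_false"),
        ("a_true_P", "a_true_I"), ("g_true_P", "g_true_I"),
    ]:
        m = (t[a] + t[b]) / 2.0
        t[a] = t[b] = m
    return t


def _expectation_violation_theta() -> dict[str, float]:
    """Plant a feedback-memory expectation-violation effect of size 0.10.

    Within each plausibility condition the expectation-inconsistent d is
    0.75 and the consistent d is 0.65, i.e. equal shrinkage s = 13/15 in
    both conditions (an interior matched null for the equal-shrinkage test).
    """
    t = _null_theta()
    t["d_P_false"], t["d_P_true"] = 0.75, 0.65   # consistent for plausible: "true"
    t["d_I_true"], t["d_I_false"] = 0.75, 0.65   # consistent for implausible: "false"
    return t


def _guessing_only_theta() -> dict[str, float]:
    """Plausibility moves only the "true"-guessing parameters.

    All statement-memory and feedback-memory parameters are flat across
    conditions; a_true/g_true take the study's asymmetric values.  Under
    this vector any observable plausibility-by-feedback interaction in
    correct feedback attributions is produced by guessing alone.
    """
    t = {}
    for p in ("P", "I"):
        for fb in ("true", "false", "q", "new"):
            t[f"D_{p}_{fb}"] = 0.73
        for fb in ("true", "false", "q"):
            t[f"d_{p}_{fb}"] = 0.60
        t[f"b_{p}"] = 0.40
        t[f"a_fb_{p}"] = 0.50
        t[f"g_fb_{p}"] = 0.68
    t["a_true_P"], t["a_true_I"] = 0.54, 0.29
    t["g_true_P"], t["g_true_I"] = 0.65, 0.36
    return t


SCENARIOS = {
    "paper-estimates": _base_estimates,
    "null": _null_theta,
    "expectation-violation-d": _expectation_violation_theta,
    "guessing-only": _guessing_only_theta,
}


def make_effect_scenario(name: str) -> dict[str, float]:
    """Return the full generating parameter vector for a named scenario."""
    try:
        return SCENARIOS[name]()
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
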