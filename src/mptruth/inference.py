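"""Nested-model comparisons and the order-constrained shrinkage model.

Hypotheses about latent processes are tested by imposing equality
constraints on the baseline model and comparing fits with the
likelihood-ratio difference statistic ``delta G2 = G2_restricted -
G2_baseline``, referred to chi-square with ``delta df`` equal to the number
of independent constraints.

The asymmetry of the expectation-violation effect on feedback memory is
assessed in a reparametrised model with parametric order constraints: the
feedback-memory parameter for expectation-consistent feedback is written as
``d_consistent = s * d_inconsistent`` with a shrinkage parameter
``s in [0, 1]``.  Because ``1 - s*d = (1 - s) + s*(1 - d)``, the
reparametrised model is itself a proper MPT model obtained by branch
splitting, so the same fitting machinery applies and the free-parameter
count is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimation import FitResult, FrequencyTable, fit
from .model import Branch, MptModel, ParameterRef, SourceTree, build_feedback_model

__all__ = [
    "NestedTest",
    "ShrinkageSpec",
    "DEFAULT_SHRINKAGE",
    "nested_test",
    "reparametrise_shrinkage",
    "run_test_battery",
    "BatteryReport",
]


@dataclass
class NestedTest:
    """A likelihood-ratio comparison of a restricted against a base model."""

    label: str
    constraints: list
    delta_g_squared: float
    delta_df: int
    p_value: float
    base_fit: FitResult = field(repr=False)
    restricted_fit: FitResult = field(repr=False)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "constraints": [list(c) for c in self.constraints],
            "delta_g_squared": round(self.delta_g_squared, 4),
            "delta_df": self.delta_df,
            "p_value": self.p_value,
            "converged": self.base_fit.converged and self.restricted_fit.converged,
        }


def _project_onto_constraints(model: MptModel, restricted: MptModel, estimates: dict) -> dict:
    """Project base-model estimates onto the restricted parameter space.

    Equated classes take the mean of their members' base estimates; this is
    used only as a warm start for the restricted fit.
    """
    rep_of, fixed_of, free = restricted.resolve()
    members: dict[str, list[float]] = {}
    base_rep = model.resolve()[0]
    base_est_full = {n: estimates[base_rep[n]] for n in model.parameters if base_rep[n] in estimates}
    for n, v in base_est_full.items():
        if n in rep_of and rep_of[n] in free:
            members.setdefault(rep_of[n], []).append(v)
    init = {r: float(np.mean(vs)) for r, vs in members.items()}
    return {n: init[n] for n in free if n in init}


def nested_test(
    model: MptModel,
    freq: FrequencyTable,
    constraints,
    label: str = "",
    seed: int | None = None,
    n_starts: int = 20,
    base_fit: FitResult | None = None,
) -> NestedTest:
    """Fit base and restricted model; return the delta-G2 test.

    Both fits share ``seed`` and ``n_starts``; the restricted fit is
    additionally warm-started from the base MLE projected onto the
    constraint set, which guards against spurious negative ``delta G2``.
    Small negatives (within 1e-6) are clamped to zero; larger ones trigger
    one refit with doubled starts and a warning.
    """
    constraints = list(constraints)
    if base_fit is None:
        base_fit = fit(model, freq, n_starts=n_starts, seed=seed)
    restricted_model = model.with_constraints(constraints)
    init = _project_onto_constraints(model, restricted_model, base_fit.estimates) or None
    restricted_fit = fit(restricted_model, freq, n_starts=n_starts, seed=seed, init=init)

    delta = restricted_fit.g_squared - base_fit.g_squared
    if delta < -1e-6:
        warnings.warn(
            f"negative delta G2 ({delta:.3g}) in test {label!r}; refitting with doubled starts"
        )
        base_fit = fit(model, freq, n_starts=2 * n_starts, seed=seed,
                       init=base_fit.theta)
        restricted_fit = fit(restricted_model, freq, n_starts=2 * n_starts, seed=seed,
                             init=_project_onto_constraints(model, restricted_model,
                                                            base_fit.estimates) or None)
        delta = restricted_fit.g_squared - base_fit.g_squared
    delta = max(delta, 0.0)
    delta_df = model.n_free_parameters - restricted_model.n_free_parameters
    p = float(stats.chi2.sf(delta, delta_df)) if delta_df > 0 else 1.0
    if delta_df == 0:
        delta = 0.0
    return NestedTest(label, constraints, delta, delta_df, p, base_fit, restricted_fit)


# ---------------------------------------------------------------------------
# Shrinkage reparametrisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShrinkageSpec:
    """Order-constraint specification ``d_consistent = s * d_inconsistent``.

    ``pairs`` holds ``(consistent_d, inconsistent_d, s_name)`` triples, one
    per plausibility condition.  For any ``s in [0, 1]`` the implied order
    ``d_inconsistent >= d_consistent`` holds; smaller ``s`` means a larger
    expectation-violation effect.
    """

    pairs: tuple[tuple[str, str, str], ...]


#: Expectation-consistent feedback is "true" for plausible and "false" for
#: implausible statements; the consistent d is shrunk towards 0 relative to
#: the inconsistent one.
DEFAULT_SHRINKAGE = ShrinkageSpec(
    pairs=(
        ("d_P_true", "d_P_false", "s_P_d"),
        ("d_I_false", "d_I_true", "s_I_d"),
    )
)


def reparametrise_shrinkage(
    model: MptModel, spec: ShrinkageSpec = DEFAULT_SHRINKAGE
) -> MptModel:
    """Rewrite the model so each consistent d equals ``s * d_inconsistent``.

    Branch rewriting keeps the result a pure product-form MPT model:
    a factor ``d_c`` becomes ``s * d_i``, and a complement factor
    ``(1 - d_c)`` splits the branch into ``(1 - s)`` and ``s * (1 - d_i)``
    branches.  The consistent-d parameter disappears and the shrinkage
    parameter takes its place, so the free-parameter count is unchanged.
    """
    mapping = {}
    for cons, incons, s_name in spec.pairs:
        for n in (cons, incons):
            if n not in model.parameters:
                raise KeyError(f"shrinkage spec references unknown parameter {n!r}")
            if model.parameters[n].role != "feedback-memory":
                raise ValueError(f"shrinkage spec must reference d-parameters, got {n!r}")
        mapping[cons] = (s_name, incons)
    for c in model.equality_constraints:
        if any(n in mapping for n in c):
            raise ValueError("cannot reparametrise a parameter that is already constrained")
    if any(n in mapping for n in model.fixed_values):
        raise ValueError("cannot reparametrise a fixed parameter")

    def rewrite(branch: Branch) -> list[Branch]:
        out = [branch.factors]
        for pos, (name, comp) in enumerate(branch.factors):
            if name not in mapping:
                continue
            s_name, incons = mapping[name]
            new_out = []
            for factors in out:
                pre, post = factors[:pos], factors[pos + 1:]
                if not comp:
                    new_out.append(pre + ((s_name, False), (incons, False)) + post)
                else:
                    # 1 - s*d = (1-s) + s*(1-d)
                    new_out.append(pre + ((s_name, True),) + post)
                    new_out.append(pre + ((s_name, False), (incons, True)) + post)
            out = new_out
        return [Branch(f, branch.terminal) for f in out]

    trees = tuple(
        SourceTree(
            t.condition,
            tuple(nb for b in t.branches for nb in rewrite(b)),
            categories=t.categories,
        )
        for t in model.trees
    )
    params = {n: r for n, r in model.parameters.items() if n not in mapping}
    for cons, incons, s_name in spec.pairs:
        params[s_name] = ParameterRef(s_name, "shrinkage")
    return MptModel(
        trees=trees,
        parameters=params,
        equality_constraints=model.equality_constraints,
        fixed_values=dict(model.fixed_values),
        name=model.name + "+shrinkage",
    )


# ---------------------------------------------------------------------------
# The test battery
# ---------------------------------------------------------------------------

TEST_CONSTRAINTS = {
    "1": [("D_P_true", "D_P_false"), ("D_I_true", "D_I_false")],
    "2a": [("d_P_true", "d_P_false"), ("d_I_true", "d_I_false")],
    "2b": [("s_P_d", "s_I_d")],
    "3": [("a_true_P", "a_true_I"), ("g_true_P", "g_true_I")],
}


@dataclass
class BatteryReport:
    """Structured result of the full hypothesis-test battery."""

    baseline_fit: FitResult
    shrinkage_fit: FitResult
    tests: list[NestedTest]
    alpha: float
    fit_alpha: float

    @property
    def baseline_fit_ok(self) -> bool:
        """Goodness-of-fit decision for the baseline model (strict alpha)."""
        return self.baseline_fit.p_value >= self.fit_alpha

    def test(self, label: str) -> NestedTest:
        for t in self.tests:
            if t.label == label:
                return t
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "baseline": {
                "g_squared": round(self.baseline_fit.g_squared, 4),
                "df": self.baseline_fit.df,
                "p_value": self.baseline_fit.p_value,
                "fit_alpha": self.fit_alpha,
                "fit_ok": self.baseline_fit_ok,
            },
            "shrinkage": {
                "s_P_d": round(self.shrinkage_fit.estimates.get("s_P_d", float("nan")), 4),
                "s_I_d": round(self.shrinkage_fit.estimates.get("s_I_d", float("nan")), 4),
                "g_squared": round(self.shrinkage_fit.g_squared, 4),
            },
            "alpha": self.alpha,
            "tests": [t.to_dict() for t in self.tests],
        }


def run_test_battery(
    freq: FrequencyTable,
    seed: int | None = None,
    n_starts: int = 20,
    alpha: float = 0.05,
    fit_alpha: float = 0.001,
) -> BatteryReport:
    """Run the four preregistered parameter tests on a full-design table.

    Tests 1 (statement memory), 2a (feedback memory) and 3 (true-guessing)
    restrict the baseline model; test 2b (equal shrinkage) restricts the
    order-constrained reparametrisation.  The baseline goodness of fit is
    judged at the strict ``fit_alpha`` (high power makes the G2 test
    sensitive to tiny deviations); parameter tests use ``alpha``.
    """
    model = build_feedback_model()
    base_fit = fit(model, freq, n_starts=n_starts, seed=seed)
    tests = []
    for label in ("1", "2a"):
        tests.append(
            nested_test(model, freq, TEST_CONSTRAINTS[label], label=label,
                        seed=seed, n_starts=n_starts, base_fit=base_fit)
        )
    shrink_model = reparametrise_shrinkage(model)
    shrink_init = {k: v for k, v in base_fit.estimates.items()
                   if k in shrink_model.free_parameters}
    # start each s at the ratio of the unconstrained d estimates (clipped)
    for cons, incons, s_name in DEFAULT_SHRINKAGE.pairs:
        d_i = base_fit.estimates.get(incons, 0.5)
        d_c = base_fit.estimates.get(cons, 0.5)
        if d_i > 1e-6:
            shrink_init[s_name] = float(np.clip(d_c / d_i, 1e-3, 1 - 1e-6))
    shrink_fit = fit(shrink_model, freq, n_starts=n_starts, seed=seed,
                     init=shrink_init or None)
    tests.append(
        nested_test(shrink_model, freq, TEST_CONSTRAINTS["2b"], label="2b",
                    seed=seed, n_starts=n_starts, base_fit=shrink_fit)
    )
    tests.append(
        nested_test(model, freq, TEST_CONSTRAINTS["3"], label="3",
                    seed=seed, n_starts=n_starts, base_fit=base_fit)
    )
    return BatteryReport(base_fit, shrink_fit, tests, alpha, fit_alpha)
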