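"""Power and sample-size analysis for the model-based and ANOVA tests.

Three routes are provided:

* simulation-based power for nested delta-G2 tests (simulate aggregated
  frequencies under an alternative, fit base and restricted model, count
  rejections) and the matching required-N search;
* analytic power of the overall goodness-of-fit test against a misfit of
  effect size Cohen's ``w`` via the noncentral chi-square with
  noncentrality ``lambda = n * w**2``;
* analytic required N for a within-subject 2x2 ANOVA interaction from the
  noncentral F distribution, with an explicit, configurable noncentrality
  convention ``lambda = f**2 * N * m / (1 - rho)`` (m repeated
  measurements, numerator df 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimation import FrequencyTable, fit
from .inference import nested_test
from .model import MptModel
from .simulate import DesignSpec, simulate_frequencies

__all__ = [
    "PowerResult",
    "power_delta_g2",
    "required_n_delta_g2",
    "power_model_misfit",
    "required_n_rm_anova",
]


@dataclass
class PowerResult:
    """Estimated power (with Monte-Carlo CI) or required sample size."""

    power: float | None = None
    mc_ci: tuple[float, float] | None = None
    required_n: int | None = None
    n_reps: int | None = None
    n_failures: int = 0
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in {
            "power": self.power,
            "mc_ci": list(self.mc_ci) if self.mc_ci else None,
            "required_n": self.required_n,
            "n_reps": self.n_reps,
            "n_failures": self.n_failures,
        }.items() if v is not None}
        out["settings"] = self.settings
        return out


def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    # Wilson score interval
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def power_delta_g2(
    model: MptModel,
    theta_h1,
    constraints,
    n_participants: int,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int | None = None,
    n_starts: int = 2,
    items_per_cell: int = 6,
) -> PowerResult:
    """Monte-Carlo power of a delta-G2 test under a planted alternative.

    Each replicate simulates an aggregated frequency table at ``theta_h1``
    with ``n_participants``, runs the nested test, and counts ``p < alpha``.
    Replicates whose fits fail to converge are counted separately and do
    not enter the rejection rate.  Deterministic given ``seed``.
    """
    design = DesignSpec(n_participants=n_participants, items_per_cell=items_per_cell)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(2 * n_reps) % (2**31 - 1)
    rejections = 0
    failures = 0
    for r in range(n_reps):
        tab, _ = simulate_frequencies(model, theta_h1, design, seed=int(rep_seeds[2 * r]))
        test = nested_test(
            model, tab, constraints, label="power-rep",
            seed=int(rep_seeds[2 * r + 1]), n_starts=n_starts,
        )
        if not (test.base_fit.converged and test.restricted_fit.converged):
            failures += 1
            continue
        if test.p_value < alpha:
            rejections += 1
    n_eff = n_reps - failures
    power = rejections / n_eff if n_eff else float("nan")
    return PowerResult(
        power=power,
        mc_ci=_binomial_ci(rejections, n_eff) if n_eff else None,
        n_reps=n_reps,
        n_failures=failures,
        settings={
            "n_participants": n_participants, "alpha": alpha,
            "n_starts": n_starts, "seed": seed, "constraints": [list(c) for c in constraints],
        },
    )


def required_n_delta_g2(
    model: MptModel,
    theta_h1,
    constraints,
    alpha: float = 0.05,
    target_power: float = 0.90,
    n_reps: int = 200,
    seed: int | None = None,
    n_starts: int = 2,
    n_min: int = 8,
    n_cap: int = 4096,
) -> PowerResult:
    """Smallest N reaching ``target_power``, by doubling then bisection.

    Power at each candidate N is estimated by Monte Carlo with a seed
    derived deterministically from ``seed`` and N, so results are
    reproducible bit-exactly given the grid settings.
    """

    def power_at(n: int) -> float:
        sub_seed = int(np.random.SeedSequence([0 if seed is None else seed, n]).generate_state(1)[0] % (2**31 - 1))
        return power_delta_g2(
            model, theta_h1, constraints, n, alpha=alpha,
            n_reps=n_reps, seed=sub_seed, n_starts=n_starts,
        ).power

    evaluations: dict[int, float] = {}
    n = n_min
    while n <= n_cap:
        evaluations[n] = power_at(n)
        if evaluations[n] >= target_power:
            break
        n *= 2
    else:
        return PowerResult(
            required_n=None, n_reps=n_reps,
            settings={"alpha": alpha, "target_power": target_power,
                      "seed": seed, "unreachable_below": n_cap},
        )
    lo, hi = n // 2, n
    if lo < n_min:
        lo = n_min
    while hi - lo > 1:
        mid = (lo + hi) // 2
        evaluations[mid] = power_at(mid)
        if evaluations[mid] >= target_power:
            hi = mid
        else:
            lo = mid
    return PowerResult(
        required_n=hi,
        power=evaluations[hi],
        n_reps=n_reps,
        settings={"alpha": alpha, "target_power": target_power, "seed": seed,
                  "grid": {str(k): round(v, 4) for k, v in sorted(evaluations.items())}},
    )


def power_model_misfit(w: float, df: int, n_total: float, alpha: float = 0.001) -> float:
    """Analytic power of the G2 goodness-of-fit test against misfit ``w``.

    Under a model deviation of effect size Cohen's ``w`` the G2 statistic
    is asymptotically noncentral chi-square with noncentrality
    ``lambda = n_total * w**2``; power is the upper-tail mass beyond the
    central critical value.  ``w = 0`` returns ``alpha`` exactly.
    """
    if w < 0:
        raise ValueError("w must be non-negative")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    lam = n_total * w * w
    if lam == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, lam))


def required_n_rm_anova(
    f: float = 0.10,
    rho: float = 0.50,
    alpha: float = 0.05,
    target_power: float = 0.90,
    n_measurements: int = 4,
    n_cap: int = 100000,
) -> int:
    """Smallest N for the within-subject 2x2 interaction at effect size f.

    Uses the noncentral-F convention ``lambda = f**2 * N * m / (1 - rho)``
    with numerator df 1 and denominator df N - 1 (m = number of repeated
    measurements, rho = assumed correlation among them).  Conventions
    differ between external power programs; this one is stated explicitly
    and applied consistently.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    for n in range(2, n_cap + 1):
        lam = f * f * n * n_measurements / (1.0 - rho)
        crit = stats.f.ppf(1.0 - alpha, 1, n - 1)
        power = float(stats.ncf.sf(crit, 1, n - 1, lam))
        if power >= target_power:
            return n
    raise ValueError(f"target power not reachable below N = {n_cap}")
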