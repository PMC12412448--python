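"""Maximum-likelihood estimation of MPT models from category frequencies.

Fitting follows the complete-pooling convention of aggregate MPT analyses:
all participants' responses are summed into one frequency table per
condition and the product-multinomial likelihood is maximised over the free
parameters.  Goodness of fit is the likelihood-ratio statistic

    G2 = 2 * sum_ij n_ij * ln(n_ij / m_ij),

referred to a chi-square distribution with ``df = free response categories -
free parameters``.  Optimisation runs on logit-transformed parameters
(boundary-safe) with analytic gradients and seeded multi-start.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .model import CATEGORIES, ITEM_TYPES, PLAUSIBILITY, MptModel, build_feedback_model

__all__ = [
    "FrequencyTable",
    "FitResult",
    "expected_frequencies",
    "log_likelihood",
    "fit",
    "confidence_intervals",
    "identifiability_check",
    "RankReport",
]


@dataclass
class FrequencyTable:
    """Response counts per processing tree.

    ``counts`` holds one non-negative array per tree, aligned with that
    tree's category order; ``labels`` carries the tree conditions (e.g.
    ``("plausible", "true-feedback")``).
    """

    counts: list[np.ndarray]
    labels: list[tuple[str, str]]
    categories: list[tuple[str, ...]]

    def __post_init__(self):
        self.counts = [np.asarray(c, dtype=float) for c in self.counts]
        if not (len(self.counts) == len(self.labels) == len(self.categories)):
            raise ValueError("counts, labels and categories must have equal length")
        for c in self.counts:
            if (c < 0).any():
                raise ValueError("negative counts")

    @property
    def totals(self) -> np.ndarray:
        """Trial count per tree."""
        return np.array([c.sum() for c in self.counts])

    @property
    def grand_total(self) -> float:
        return float(self.totals.sum())

    @property
    def flat(self) -> np.ndarray:
        return np.concatenate(self.counts)

    @classmethod
    def from_array(cls, counts, labels=None, categories=None) -> "FrequencyTable":
        counts = [np.asarray(c, dtype=float) for c in counts]
        if labels is None:
            labels = [(f"tree{i + 1}", "") for i in range(len(counts))]
        if categories is None:
            categories = [
                CATEGORIES if len(c) == len(CATEGORIES)
                else tuple(f"c{j + 1}" for j in range(len(c)))
                for c in counts
            ]
        return cls(list(counts), list(labels), list(categories))

    @classmethod
    def full_design_zeros(cls) -> "FrequencyTable":
        labels = [(pl, it) for pl in PLAUSIBILITY for it in ITEM_TYPES]
        return cls(
            [np.zeros(4) for _ in labels], labels, [CATEGORIES for _ in labels]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab, cats, cnt in zip(self.labels, self.categories, self.counts):
            for c, n in zip(cats, cnt):
                rows.append(
                    {"plausibility": lab[0], "item_type": lab[1], "response": c,
                     "count": int(n) if float(n).is_integer() else float(n)}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrequencyTable":
        """Build a full-design table from long-format records.

        Expects columns ``plausibility, item_type, response, count``; cells
        are placed in the canonical tree/category order, missing cells are
        zero, unknown levels raise.
        """
        tab = cls.full_design_zeros()
        pos = {lab: i for i, lab in enumerate(tab.labels)}
        cpos = {c: j for j, c in enumerate(CATEGORIES)}
        for _, row in df.iterrows():
            key = (row["plausibility"], row["item_type"])
            if key not in pos:
                raise ValueError(f"unknown design cell {key!r}")
            if row["response"] not in cpos:
                raise ValueError(f"unknown response {row['response']!r}")
            tab.counts[pos[key]][cpos[row["response"]]] += float(row["count"])
        return tab

    @classmethod
    def from_csv(cls, path) -> "FrequencyTable":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


# ---------------------------------------------------------------------------
# Compiled likelihood machinery
# ---------------------------------------------------------------------------


class CompiledModel:
    """Array-compiled MPT model for fast repeated likelihood evaluation.

    Fixed parameters are folded into per-branch constants; each remaining
    factor references an index into the free-parameter vector.  Provides
    cell probabilities and their analytic gradient.
    """

    def __init__(self, model: MptModel):
        self.model = model
        rep_of, fixed_of, free = model.resolve()
        self.free = list(free)
        findex = {n: i for i, n in enumerate(free)}

        cell_slices = []
        cell_of = {}
        n_cells = 0
        for ti, tree in enumerate(model.trees):
            cell_slices.append(slice(n_cells, n_cells + len(tree.categories)))
            for j, c in enumerate(tree.categories):
                cell_of[(ti, c)] = n_cells + j
            n_cells += len(tree.categories)
        self.n_cells = n_cells
        self.cell_slices = cell_slices

        b_idx, b_comp, b_const, b_cell, b_nslots = [], [], [], [], []
        for ti, tree in enumerate(model.trees):
            for br in tree.branches:
                const = 1.0
                slots = []
                for name, comp in br.factors:
                    r = rep_of[name]
                    if r in fixed_of:
                        v = fixed_of[r]
                        const *= (1.0 - v) if comp else v
                    else:
                        slots.append((findex[r], comp))
                b_idx.append([s[0] for s in slots])
                b_comp.append([s[1] for s in slots])
                b_const.append(const)
                b_cell.append(cell_of[(ti, br.terminal)])
                b_nslots.append(len(slots))
        self.n_branches = len(b_idx)
        m = max(b_nslots) if b_nslots else 0
        self.max_slots = m
        self.idx = np.zeros((self.n_branches, m), dtype=np.intp)
        self.comp = np.zeros((self.n_branches, m), dtype=bool)
        self.mask = np.zeros((self.n_branches, m), dtype=bool)
        for i, (ix, cp) in enumerate(zip(b_idx, b_comp)):
            self.idx[i, : len(ix)] = ix
            self.comp[i, : len(ix)] = cp
            self.mask[i, : len(ix)] = True
        self.const = np.asarray(b_const)
        self.cell = np.asarray(b_cell, dtype=np.intp)
        # flat scatter indices for gradient accumulation
        bb, ss = np.nonzero(self.mask)
        self._gb, self._gs = bb, ss
        self._gf = self.idx[bb, ss]
        self._gc = self.cell[bb]
        self._gsign = np.where(self.comp[bb, ss], -1.0, 1.0)

    def _factor_values(self, theta: np.ndarray) -> np.ndarray:
        V = theta[self.idx]
        V = np.where(self.comp, 1.0 - V, V)
        V[~self.mask] = 1.0
        return V

    def cell_probs(self, theta: np.ndarray) -> np.ndarray:
        bp = self.const * self._factor_values(theta).prod(axis=1)
        P = np.zeros(self.n_cells)
        np.add.at(P, self.cell, bp)
        return P

    def cell_probs_and_grad(self, theta: np.ndarray):
        """Return ``(P, dP)`` with ``dP`` of shape ``(n_free, n_cells)``."""
        V = self._factor_values(theta)
        m = self.max_slots
        # leave-one-out products via prefix/suffix cumulative products
        left = np.ones_like(V)
        right = np.ones_like(V)
        if m > 1:
            left[:, 1:] = np.cumprod(V[:, :-1], axis=1)
            right[:, :-1] = np.cumprod(V[:, ::-1], axis=1)[:, -2::-1]
        loo = left * right  # product of all factors except slot s
        bp = self.const * V.prod(axis=1)
        P = np.zeros(self.n_cells)
        np.add.at(P, self.cell, bp)
        contrib = (self.const[self._gb] * loo[self._gb, self._gs]) * self._gsign
        dP = np.zeros((len(self.free), self.n_cells))
        np.add.at(dP, (self._gf, self._gc), contrib)
        return P, dP

    def ll_and_grad(self, theta: np.ndarray, counts: np.ndarray):
        """Multinomial log-likelihood kernel ``sum n*log p`` and its gradient.

        Cells with zero counts contribute nothing; a positive count on a
        zero-probability cell yields ``-inf`` (contract, not an exception).
        """
        P, dP = self.cell_probs_and_grad(theta)
        nz = counts > 0
        if np.any(P[nz] <= 0):
            return -np.inf, np.zeros(len(self.free))
        ll = float(np.dot(counts[nz], np.log(P[nz])))
        w = np.zeros_like(P)
        w[nz] = counts[nz] / P[nz]
        return ll, dP @ w


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    estimates: dict[str, float]
    log_likelihood: float
    g_squared: float
    df: int
    p_value: float
    n_starts: int
    converged: bool
    seed: int | None
    model: MptModel = field(repr=False)
    freq: FrequencyTable = field(repr=False)
    ci: dict[str, tuple[float, float]] | None = field(default=None, repr=False)
    ci_method: dict[str, str] | None = field(default=None, repr=False)

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.estimates[n] for n in self.model.free_parameters])

    def to_dict(self) -> dict:
        out = {
            "model": self.model.name,
            "estimates": {k: round(v, 6) for k, v in self.estimates.items()},
            "log_likelihood": self.log_likelihood,
            "g_squared": self.g_squared,
            "df": self.df,
            "p_value": self.p_value,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "seed": self.seed,
        }
        if self.ci is not None:
            out["ci"] = {k: [round(a, 6), round(b, 6)] for k, (a, b) in self.ci.items()}
            out["ci_method"] = self.ci_method
        return out


def _check_conformable(model: MptModel, freq: FrequencyTable) -> None:
    if len(freq.counts) != len(model.trees):
        raise ValueError(
            f"frequency table has {len(freq.counts)} trees, model has {len(model.trees)}"
        )
    for tree, cats, cnt in zip(model.trees, freq.categories, freq.counts):
        if len(cnt) != len(tree.categories):
            raise ValueError(f"category count mismatch in tree {tree.condition}")


def expected_frequencies(model: MptModel, theta, totals) -> FrequencyTable:
    """Multinomial expectations ``total_t * p_tc`` per tree and category."""
    full = model.expand_theta(theta)
    totals = np.asarray(totals, dtype=float)
    if totals.shape != (len(model.trees),):
        raise ValueError("one total per tree required")
    counts = [
        t.category_probabilities(full) * n for t, n in zip(model.trees, totals)
    ]
    return FrequencyTable(
        counts,
        [t.condition for t in model.trees],
        [t.categories for t in model.trees],
    )


def log_likelihood(model: MptModel, theta, freq: FrequencyTable) -> float:
    """Product-multinomial log-likelihood kernel ``sum_ij n_ij log p_ij``."""
    _check_conformable(model, freq)
    comp = CompiledModel(model)
    vec = np.array([model.expand_theta(theta)[n] for n in comp.free]) if comp.free else np.zeros(0)
    ll, _ = comp.ll_and_grad(vec, freq.flat)
    return ll


def _g_squared(counts: np.ndarray, expected: np.ndarray) -> float:
    nz = counts > 0
    if np.any(expected[nz] <= 0):
        return float("inf")
    return float(2.0 * np.dot(counts[nz], np.log(counts[nz] / expected[nz])))


def fit(
    model: MptModel,
    freq: FrequencyTable,
    n_starts: int = 20,
    tol: float = 1e-13,
    seed: int | None = None,
    init=None,
) -> FitResult:
    """Fit an MPT model by maximum likelihood.

    Runs ``n_starts`` quasi-Newton optimisations from seeded uniform random
    starting points on the logit scale (plus an optional warm start
    ``init``) and keeps the best.  Returns estimates, ``G2`` with its
    chi-square p-value, and convergence diagnostics.  Deterministic given
    ``seed``.
    """
    _check_conformable(model, freq)
    comp = CompiledModel(model)
    counts = freq.flat
    totals_per_cell = np.empty(comp.n_cells)
    for sl, n in zip(comp.cell_slices, freq.totals):
        totals_per_cell[sl] = n

    k = len(comp.free)
    df = model.n_free_categories - k

    if k == 0:
        P = comp.cell_probs(np.zeros(0))
        expected = P * totals_per_cell
        g2 = _g_squared(counts, expected)
        nz = counts > 0
        ll = float(np.dot(counts[nz], np.log(P[nz]))) if np.all(P[nz] > 0) else -np.inf
        return FitResult({}, ll, g2, df, float(stats.chi2.sf(g2, df)) if df > 0 else float("nan"),
                         0, True, seed, model, freq)

    def objective(x):
        theta = special.expit(x)
        ll, g = comp.ll_and_grad(theta, counts)
        if not np.isfinite(ll):
            return 1e30, np.zeros(k)
        return -ll, -(g * theta * (1.0 - theta))

    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        if isinstance(init, dict):
            # partial warm starts allowed: unmentioned free parameters start at 0.5
            rep_of = model.resolve()[0]
            by_rep = {rep_of[k_]: float(v) for k_, v in init.items() if k_ in rep_of}
            init_vec = np.array([by_rep.get(n, 0.5) for n in comp.free])
        else:
            init_vec = np.asarray(init, dtype=float)
        starts.append(np.clip(init_vec, 1e-4, 1 - 1e-4))
    starts.extend(rng.uniform(0.02, 0.98, size=(n_starts, k)))

    best = None
    any_success = False
    for s in starts:
        x0 = special.logit(np.asarray(s))
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-9, "maxiter": 2000, "maxfun": 10000},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res

    theta_hat = special.expit(best.x)
    estimates = dict(zip(comp.free, theta_hat))
    P = comp.cell_probs(theta_hat)
    expected = P * totals_per_cell
    g2 = _g_squared(counts, expected)
    nz = counts > 0
    ll = float(np.dot(counts[nz], np.log(P[nz]))) if np.all(P[nz] > 0) else -np.inf
    p = float(stats.chi2.sf(g2, df)) if df > 0 else float("nan")
    return FitResult(
        estimates, ll, g2, df, p, len(starts), bool(any_success), seed, model, freq
    )


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------


def _observed_information(fitres: FitResult) -> np.ndarray:
    """Numerical Hessian of -log L at the MLE (central differences of the
    analytic gradient on the probability scale)."""
    comp = CompiledModel(fitres.model)
    counts = fitres.freq.flat
    theta = fitres.theta
    k = len(theta)
    H = np.zeros((k, k))
    h = 1e-5
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] = min(tp[j] + h, 1 - 1e-9)
        tm[j] = max(tm[j] - h, 1e-9)
        _, gp = comp.ll_and_grad(tp, counts)
        _, gm = comp.ll_and_grad(tm, counts)
        H[j] = -(gp - gm) / (tp[j] - tm[j])
    return 0.5 * (H + H.T)


def _profile_ci_one(fitres: FitResult, name: str, level: float) -> tuple[float, float]:
    """Profile-likelihood interval for one parameter by bisection on the
    likelihood-ratio threshold, refitting the remaining parameters."""
    model = fitres.model
    target = stats.chi2.ppf(level, 1) / 2.0
    ll_max = fitres.log_likelihood
    est = fitres.estimates[name]
    others_init = dict(fitres.estimates)

    def profile_ll(v: float) -> float:
        m = model.with_constraints([(name, float(v))])
        init = {k_: x for k_, x in others_init.items() if k_ in m.free_parameters}
        r = fit(m, fitres.freq, n_starts=0 if init else 1, seed=0, init=init if init else None)
        return r.log_likelihood

    def deficit(v):
        return ll_max - profile_ll(v) - target

    def search(lo, hi, increasing):
        # deficit < 0 inside the interval, > 0 outside; bisect the crossing
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if deficit(mid) > 0:
                lo, hi = (mid, hi) if increasing else (lo, mid)
            else:
                lo, hi = (lo, mid) if increasing else (mid, hi)
            if abs(hi - lo) < 1e-4:
                break
        return 0.5 * (lo + hi)

    lower = 0.0 if deficit(1e-6) <= 0 else search(1e-6, est, increasing=True)
    upper = 1.0 if deficit(1 - 1e-6) <= 0 else search(est, 1 - 1e-6, increasing=False)
    return float(lower), float(upper)


def confidence_intervals(
    fitres: FitResult, level: float = 0.95, boundary_tol: float = 0.01
) -> FitResult:
    """Attach per-parameter confidence intervals to a fit.

    Default is Wald intervals ``estimate +/- z * SE`` from the inverse
    observed information on the probability scale, clipped to ``[0, 1]``.
    Parameters within ``boundary_tol`` of a boundary, or whole fits with a
    singular information matrix, fall back to profile-likelihood intervals
    (flagged per parameter in ``ci_method``).
    """
    names = fitres.model.free_parameters
    if not names:
        fitres.ci, fitres.ci_method = {}, {}
        return fitres
    z = stats.norm.ppf(0.5 + level / 2.0)
    H = _observed_information(fitres)
    se = None
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            se = np.sqrt(d)
    except np.linalg.LinAlgError:
        pass
    ci, method = {}, {}
    for j, n in enumerate(names):
        est = fitres.estimates[n]
        near_boundary = est < boundary_tol or est > 1 - boundary_tol
        if se is not None and not near_boundary:
            ci[n] = (max(0.0, est - z * se[j]), min(1.0, est + z * se[j]))
            method[n] = "wald"
        else:
            try:
                ci[n] = _profile_ci_one(fitres, n, level)
                method[n] = "profile"
            except Exception:  # pragma: no cover - defensive
                ci[n] = (0.0, 1.0)
                method[n] = "degenerate"
        lo, hi = ci[n]
        if not lo - 1e-9 <= est <= hi + 1e-9:
            method[n] = "degenerate"
    fitres.ci, fitres.ci_method = ci, method
    return fitres


# ---------------------------------------------------------------------------
# Identifiability
# ---------------------------------------------------------------------------


@dataclass
class RankReport:
    """Numerical local-identifiability diagnostic."""

    n_free: int
    ranks: list[int]
    full_rank: bool
    deficient_directions: np.ndarray  # null-space basis at the worst point

    def __str__(self) -> str:
        status = "locally identifiable" if self.full_rank else "RANK DEFICIENT"
        return (
            f"{status}: {min(self.ranks)}/{self.n_free} "
            f"(Jacobian column rank at {len(self.ranks)} random interior points)"
        )


def identifiability_check(
    model: MptModel, n_points: int = 10, seed: int = 0
) -> RankReport:
    """Check local identifiability via the Jacobian of cell probabilities.

    Computes the analytic Jacobian of all category probabilities with
    respect to the free parameters at random interior points; full column
    rank at every point indicates local identifiability.
    """
    comp = CompiledModel(model)
    k = len(comp.free)
    rng = np.random.default_rng(seed)
    ranks = []
    worst_null = np.zeros((k, 0))
    worst_rank = k
    for _ in range(n_points):
        theta = rng.uniform(0.15, 0.85, k)
        _, dP = comp.cell_probs_and_grad(theta)
        r = int(np.linalg.matrix_rank(dP.T, tol=1e-8))
        ranks.append(r)
        if r < worst_rank:
            worst_rank = r
            _, s, vt = np.linalg.svd(dP.T)
            worst_null = vt[r:].T
    return RankReport(k, ranks, all(r == k for r in ranks), worst_null)
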