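"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from mptruth import (
    DesignSpec,
    FrequencyTable,
    build_feedback_model,
    make_effect_scenario,
    simulate_frequencies,
    simulate_trials,
)
from mptruth.model import Branch, MptModel, SourceTree


@pytest.fixture(scope="session")
def baseline_model():
    return build_feedback_model()


@pytest.fixture(scope="session")
def paper_theta():
    return make_effect_scenario("paper-estimates")


@pytest.fixture(scope="session")
def sim_freq(baseline_model, paper_theta):
    """One aggregated table simulated at the study's estimates, N=328."""
    tab, _ = simulate_frequencies(baseline_model, paper_theta, DesignSpec(), seed=101)
    return tab


@pytest.fixture(scope="session")
def sim_trials(baseline_model, paper_theta):
    """Trial-level dataset at the study's estimates, N=328."""
    trials, _ = simulate_trials(baseline_model, paper_theta, DesignSpec(), seed=202)
    return trials


# ---------------------------------------------------------------------------
# Toy models with hand-written likelihoods (grid-search oracles)
# ---------------------------------------------------------------------------


def _chain_tree(n_params: int, prefix: str = "t") -> SourceTree:
    """Sequential-threshold tree: t1 -> c1, (1-t1)t2 -> c2, ..."""
    cats = tuple(f"c{i + 1}" for i in range(n_params + 1))
    branches = []
    for i in range(n_params):
        factors = tuple((f"{prefix}{j + 1}", True) for j in range(i)) + (
            (f"{prefix}{i + 1}", False),
        )
        branches.append(Branch(factors, cats[i]))
    branches.append(
        Branch(tuple((f"{prefix}{j + 1}", True) for j in range(n_params)), cats[-1])
    )
    return SourceTree(("chain", ""), tuple(branches), categories=cats)


class ToyModel:
    """An MPT model bundled with an independent vectorised log-likelihood."""

    def __init__(self, model, counts, ll_fn, n_params):
        self.model = model
        self.freq = FrequencyTable.from_array(counts)
        self.ll_fn = ll_fn  # ll_fn(*theta_arrays) -> broadcast log-likelihood
        self.n_params = n_params


def toy_one_param():
    # single high-threshold: t -> c1, (1-t) -> c2
    model = MptModel(trees=(_chain_tree(1),), name="toy1")
    counts = [np.array([37.0, 63.0])]

    def ll(t):
        return 37 * np.log(t) + 63 * np.log(1 - t)

    return ToyModel(model, counts, ll, 1)


def toy_two_param():
    model = MptModel(trees=(_chain_tree(2),), name="toy2")
    counts = [np.array([20.0, 30.0, 50.0])]

    def ll(t1, t2):
        return (
            20 * np.log(t1)
            + 80 * np.log(1 - t1)
            + 30 * np.log(t2)
            + 50 * np.log(1 - t2)
        )

    return ToyModel(model, counts, ll, 2)


def toy_two_tree():
    # one-high-threshold recognition: studied tree D -> hit, (1-D)b -> hit,
    # (1-D)(1-b) -> miss; new tree b -> fa, (1-b) -> cr; shared guessing b
    t_old = SourceTree(
        ("old", ""),
        (
            Branch((("D", False),), "hit"),
            Branch((("D", True), ("b", False)), "hit"),
            Branch((("D", True), ("b", True)), "miss"),
        ),
        categories=("hit", "miss"),
    )
    t_new = SourceTree(
        ("new", ""),
        (Branch((("b", False),), "fa"), Branch((("b", True),), "cr")),
        categories=("fa", "cr"),
    )
    model = MptModel(trees=(t_old, t_new), name="toy-1ht")
    counts = [np.array([60.0, 40.0]), np.array([30.0, 70.0])]

    def ll(D, b):
        p_hit = D + (1 - D) * b
        return (
            60 * np.log(p_hit)
            + 40 * np.log((1 - D) * (1 - b))
            + 30 * np.log(b)
            + 70 * np.log(1 - b)
        )

    return ToyModel(model, counts, ll, 2)


def toy_three_param():
    model = MptModel(trees=(_chain_tree(3),), name="toy3")
    counts = [np.array([10.0, 20.0, 30.0, 40.0])]

    def ll(t1, t2, t3):
        return (
            10 * np.log(t1)
            + 90 * np.log(1 - t1)
            + 20 * np.log(t2)
            + 70 * np.log(1 - t2)
            + 30 * np.log(t3)
            + 40 * np.log(1 - t3)
        )

    return ToyModel(model, counts, ll, 3)


ALL_TOYS = {
    "one-param": toy_one_param,
    "two-param": toy_two_param,
    "two-tree": toy_two_tree,
    "three-param": toy_three_param,
}


def grid_search_max(toy: ToyModel, step: float = 1e-3):
    """Exhaustive (or coarse-to-fine for 3 params) grid maximisation.

    Returns ``(best_ll, best_theta)`` at resolution ``step``.  For one or
    two parameters the full grid is scanned; for three a 0.01 grid is
    refined locally to 0.001 (valid here: the toy likelihoods are smooth
    and unimodal in each coordinate).
    """
    k = toy.n_params

    def scan(axes):
        grids = np.meshgrid(*axes, indexing="ij")
        vals = toy.ll_fn(*grids)
        flat = np.argmax(vals)
        idx = np.unravel_index(flat, vals.shape)
        return vals[idx], np.array([g[idx] for g in grids])

    if k <= 2:
        axes = [np.arange(step, 1.0, step)] * k
        return scan(axes)
    coarse_axes = [np.arange(0.01, 1.0, 0.01)] * k
    _, centre = scan(coarse_axes)
    fine_axes = [
        np.arange(max(step, c - 0.01), min(1.0 - step, c + 0.01) + step / 2, step)
        for c in centre
    ]
    return scan(fine_axes)
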