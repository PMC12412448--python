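"""Symbolic multinomial-processing-tree (MPT) models.

An MPT model expresses the probability of each observable response category
as a sum of branch probabilities, where every branch is a product of latent
process probabilities ``theta`` or their complements ``1 - theta``.  This
module provides the generic containers (:class:`ParameterRef`,
:class:`Branch`, :class:`SourceTree`, :class:`MptModel`), construction of
the three-source two-high-threshold feedback-memory model used throughout
the package, equality/fixing constraint handling, degrees-of-freedom
accounting, and EQN-format I/O for interoperability with standard MPT
tools (multiTree, MPTinR).

The feedback-memory model describes a recognition test in which every
studied statement was paired with "true", "false" or uninformative "?"
feedback, and test responses are one of four categories:
``("true", "false", "?", "new")``.  Latent processes are statement memory
``D``, feedback memory ``d``, the old-guessing probability ``b``, and
separate feedback-guessing probabilities for recognised (``a_fb``,
``a_true``) versus unrecognised (``g_fb``, ``g_true``) statements.  All
parameters are estimated separately for plausible (``P``) and implausible
(``I``) statements.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CATEGORIES",
    "ITEM_TYPES",
    "PLAUSIBILITY",
    "ParameterRef",
    "Branch",
    "SourceTree",
    "MptModel",
    "build_feedback_model",
    "category_probabilities",
    "apply_constraints",
    "count_df",
    "read_eqn",
    "write_eqn",
    "EqnFormatError",
]

#: Canonical response-category order used everywhere in the package.
CATEGORIES: tuple[str, ...] = ("true", "false", "?", "new")

#: Canonical item-type (study condition) order.
ITEM_TYPES: tuple[str, ...] = ("true-feedback", "false-feedback", "?-feedback", "new")

#: Canonical plausibility-condition order.
PLAUSIBILITY: tuple[str, ...] = ("plausible", "implausible")

_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")


def _infer_role(name: str) -> str:
    """Infer the cognitive role of a parameter from its name prefix."""
    if name.startswith("D"):
        return "item-memory"
    if name.startswith("d"):
        return "feedback-memory"
    if name.startswith("b"):
        return "old-guess"
    if name.startswith(("a_fb", "g_fb")):
        return "feedback-guess"
    if name.startswith(("a_true", "g_true")):
        return "true-guess"
    if name.startswith("s"):
        return "shrinkage"
    return "generic"


@dataclass(frozen=True)
class ParameterRef:
    """A named latent process probability in ``[0, 1]``."""

    name: str
    role: str = ""

    def __post_init__(self):
        if not _NAME_RE.match(self.name):
            raise ValueError(f"illegal parameter name: {self.name!r}")
        if not self.role:
            object.__setattr__(self, "role", _infer_role(self.name))


@dataclass(frozen=True)
class Branch:
    """One processing path: an ordered product of factors ending in a response.

    ``factors`` is a tuple of ``(parameter_name, complemented)`` pairs; the
    branch probability is the product of ``theta`` (or ``1 - theta`` when
    complemented) over the factors.
    """

    factors: tuple[tuple[str, bool], ...]
    terminal: str

    def probability(self, theta: dict[str, float]) -> float:
        p = 1.0
        for name, comp in self.factors:
            v = theta[name]
            p *= (1.0 - v) if comp else v
        return p

    def __str__(self) -> str:
        toks = [f"(1-{n})" if c else n for n, c in self.factors]
        return " ".join(toks) + f" -> {self.terminal}"


@dataclass(frozen=True)
class SourceTree:
    """One processing tree: all branches for a single statement condition.

    ``condition`` identifies the cell, e.g. ``("plausible", "true-feedback")``;
    ``categories`` fixes the order in which response probabilities are
    reported.  Branch probabilities must sum to one for any parameter
    vector, which holds by construction for well-formed trees.
    """

    condition: tuple[str, str]
    branches: tuple[Branch, ...]
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self):
        for b in self.branches:
            if b.terminal not in self.categories:
                raise ValueError(
                    f"branch terminal {b.terminal!r} not among categories "
                    f"{self.categories} in tree {self.condition}"
                )

    @property
    def parameter_names(self) -> set[str]:
        return {n for b in self.branches for n, _ in b.factors}

    @property
    def emitted_categories(self) -> tuple[str, ...]:
        emitted = {b.terminal for b in self.branches}
        return tuple(c for c in self.categories if c in emitted)

    def category_probabilities(self, theta: dict[str, float]) -> np.ndarray:
        """Probability of each category (in ``self.categories`` order)."""
        out = np.zeros(len(self.categories))
        pos = {c: i for i, c in enumerate(self.categories)}
        for b in self.branches:
            out[pos[b.terminal]] += b.probability(theta)
        return out


class _UnionFind:
    def __init__(self, names):
        self.parent = {n: n for n in names}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic representative: lexicographically smallest
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


@dataclass
class MptModel:
    """A collection of processing trees sharing a parameter space.

    ``equality_constraints`` lists parameter-name pairs that are collapsed to
    a single free parameter; ``fixed_values`` pins parameters (or whole
    equivalence classes) to constants.  Constraints are stored, not baked
    into the tree structure, so restrictions remain testable and removable.
    """

    trees: tuple[SourceTree, ...]
    parameters: dict[str, ParameterRef] = field(default_factory=dict)
    equality_constraints: tuple[tuple[str, str], ...] = ()
    fixed_values: dict[str, float] = field(default_factory=dict)
    name: str = "mpt"

    def __post_init__(self):
        self.trees = tuple(self.trees)
        self.equality_constraints = tuple(tuple(c) for c in self.equality_constraints)
        used = {n for t in self.trees for n in t.parameter_names}
        for n in used:
            self.parameters.setdefault(n, ParameterRef(n))
        for a, b in self.equality_constraints:
            for n in (a, b):
                if n not in self.parameters:
                    raise KeyError(f"constraint references unknown parameter {n!r}")
        for n, v in self.fixed_values.items():
            if n not in self.parameters:
                raise KeyError(f"fixing references unknown parameter {n!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fixed value for {n!r} outside [0, 1]: {v}")
        self._resolution = None

    # -- constraint resolution -------------------------------------------------

    def resolve(self):
        """Collapse constraints; return ``(rep_of, fixed_of, free_names)``.

        ``rep_of`` maps every parameter to its equivalence-class
        representative, ``fixed_of`` maps representatives to constants, and
        ``free_names`` is the sorted list of free representatives.
        Contradictory fixings (one class, two constants) raise ``ValueError``.
        """
        if self._resolution is not None:
            return self._resolution
        uf = _UnionFind(self.parameters)
        for a, b in self.equality_constraints:
            uf.union(a, b)
        rep_of = {n: uf.find(n) for n in self.parameters}
        fixed_of: dict[str, float] = {}
        for n, v in self.fixed_values.items():
            r = rep_of[n]
            if r in fixed_of and abs(fixed_of[r] - v) > 1e-12:
                raise ValueError(
                    f"contradictory constraints: class of {r!r} fixed to both "
                    f"{fixed_of[r]} and {v}"
                )
            fixed_of[r] = v
        free = sorted(set(rep_of.values()) - set(fixed_of))
        self._resolution = (rep_of, fixed_of, free)
        return self._resolution

    @property
    def free_parameters(self) -> list[str]:
        """Sorted names of the free parameters after constraint collapse."""
        return list(self.resolve()[2])

    @property
    def n_free_parameters(self) -> int:
        return len(self.resolve()[2])

    @property
    def n_free_categories(self) -> int:
        """Sum over trees of (distinct emitted categories - 1)."""
        return sum(len(t.emitted_categories) - 1 for t in self.trees)

    # -- evaluation ------------------------------------------------------------

    def expand_theta(self, theta) -> dict[str, float]:
        """Expand a parameter assignment to a full per-parameter dict.

        ``theta`` may be a mapping keyed by any parameter name (an alias of
        a class works) or a sequence aligned with :attr:`free_parameters`.
        """
        rep_of, fixed_of, free = self.resolve()
        if not isinstance(theta, dict):
            vec = np.asarray(theta, dtype=float)
            if vec.shape != (len(free),):
                raise ValueError(
                    f"expected {len(free)} free-parameter values, got {vec.shape}"
                )
            theta = dict(zip(free, vec))
        by_rep: dict[str, float] = {}
        for k, v in theta.items():
            if k not in rep_of:
                raise KeyError(f"unknown parameter {k!r}")
            r = rep_of[k]
            if r in by_rep and abs(by_rep[r] - float(v)) > 1e-12:
                raise ValueError(f"conflicting values supplied for class of {r!r}")
            by_rep[r] = float(v)
        by_rep.update(fixed_of)
        full = {}
        for n in self.parameters:
            r = rep_of[n]
            if r not in by_rep:
                raise KeyError(f"no value supplied for parameter {n!r} (class {r!r})")
            v = by_rep[r]
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"value for {n!r} outside [0, 1]: {v}")
            full[n] = v
        return full

    def category_probabilities(self, theta) -> np.ndarray:
        return category_probabilities(self, theta)

    # -- manipulation ----------------------------------------------------------

    def with_constraints(self, constraints) -> "MptModel":
        """Return a copy with additional equality/fixing constraints.

        Each constraint is ``(name_a, name_b)`` to equate two parameters, or
        ``(name, value)`` with a numeric value to fix one.
        """
        eqs = list(self.equality_constraints)
        fixed = dict(self.fixed_values)
        for c in constraints:
            a, b = c
            if isinstance(b, str):
                eqs.append((a, b))
            else:
                fixed[a] = float(b)
        m = MptModel(
            trees=self.trees,
            parameters=dict(self.parameters),
            equality_constraints=tuple(eqs),
            fixed_values=fixed,
            name=self.name,
        )
        m.resolve()  # validate now: contradictory fixings raise here
        return m

    def summary(self) -> str:
        """Plain-text model report."""
        rep_of, fixed_of, free = self.resolve()
        lines = [
            f"MPT model {self.name!r}",
            f"  trees: {len(self.trees)}",
            f"  parameters: {len(self.parameters)} "
            f"({self.n_free_parameters} free after constraints)",
            f"  free response categories: {self.n_free_categories}",
            f"  goodness-of-fit df: {count_df(self)}",
        ]
        if self.equality_constraints:
            lines.append("  equality constraints:")
            for a, b in self.equality_constraints:
                lines.append(f"    {a} = {b}")
        if fixed_of:
            lines.append("  fixed values:")
            for r, v in sorted(fixed_of.items()):
                lines.append(f"    {r} = {v:g}")
        for t in self.trees:
            lines.append(f"  tree {t.condition}:")
            for b in t.branches:
                lines.append(f"    {b}")
        return "\n".join(lines)


def category_probabilities(model: MptModel, theta) -> np.ndarray:
    """Per-tree response-category distributions.

    Returns an array of shape ``(n_trees, n_categories)`` (trees must share a
    category set); each row is non-negative and sums to one within 1e-12 for
    any valid parameter vector.
    """
    full = model.expand_theta(theta)
    cats = model.trees[0].categories
    out = np.empty((len(model.trees), len(cats)))
    for i, t in enumerate(model.trees):
        if t.categories != cats:
            raise ValueError("trees do not share a common category set")
        out[i] = t.category_probabilities(full)
    return out


def apply_constraints(model: MptModel, constraints) -> MptModel:
    """Functional alias of :meth:`MptModel.with_constraints`."""
    return model.with_constraints(constraints)


def count_df(model: MptModel) -> int:
    """Goodness-of-fit degrees of freedom.

    ``df = free response categories - free parameters``.  A negative value
    signals more parameters than identifiable cells (not identifiable).
    """
    return model.n_free_categories - model.n_free_parameters


# ---------------------------------------------------------------------------
# The three-source two-high-threshold feedback-memory model
# ---------------------------------------------------------------------------


def _suffix(plausibility: str) -> str:
    return {"plausible": "P", "implausible": "I"}[plausibility]


_FB_SUFFIX = {"true-feedback": "true", "false-feedback": "false", "?-feedback": "q"}
_FB_TERMINAL = {"true-feedback": "true", "false-feedback": "false", "?-feedback": "?"}


def _studied_tree(plausibility: str, item_type: str) -> SourceTree:
    p = _suffix(plausibility)
    fb = _FB_SUFFIX[item_type]
    D, d = f"D_{p}_{fb}", f"d_{p}_{fb}"
    b, a_fb, a_true = f"b_{p}", f"a_fb_{p}", f"a_true_{p}"
    g_fb, g_true = f"g_fb_{p}", f"g_true_{p}"
    branches = (
        # statement recognised, feedback remembered
        Branch(((D, False), (d, False)), _FB_TERMINAL[item_type]),
        # recognised, feedback forgotten -> guess among feedback options
        Branch(((D, False), (d, True), (a_fb, False), (a_true, False)), "true"),
        Branch(((D, False), (d, True), (a_fb, False), (a_true, True)), "false"),
        Branch(((D, False), (d, True), (a_fb, True)), "?"),
        # not recognised, guessed old -> guess among feedback options
        Branch(((D, True), (b, False), (g_fb, False), (g_true, False)), "true"),
        Branch(((D, True), (b, False), (g_fb, False), (g_true, True)), "false"),
        Branch(((D, True), (b, False), (g_fb, True)), "?"),
        # not recognised, guessed new
        Branch(((D, True), (b, True)), "new"),
    )
    return SourceTree((plausibility, item_type), branches)


def _new_tree(plausibility: str) -> SourceTree:
    p = _suffix(plausibility)
    D = f"D_{p}_new"
    b, g_fb, g_true = f"b_{p}", f"g_fb_{p}", f"g_true_{p}"
    branches = (
        Branch(((D, False),), "new"),  # new statement detected as new
        Branch(((D, True), (b, False), (g_fb, False), (g_true, False)), "true"),
        Branch(((D, True), (b, False), (g_fb, False), (g_true, True)), "false"),
        Branch(((D, True), (b, False), (g_fb, True)), "?"),
        Branch(((D, True), (b, True)), "new"),
    )
    return SourceTree((plausibility, "new"), branches)


def build_feedback_model(baseline_constraints: bool = True) -> MptModel:
    """Construct the 8-tree three-source two-high-threshold model.

    One tree per plausibility (plausible/implausible) x item type
    ("true"/"false"/"?" feedback, new).  With the identifiability baseline
    (``baseline_constraints=True``) the statement-memory parameters for "?"
    feedback and new statements are equated within each plausibility
    condition (``D_*_q = D_*_new``), leaving 22 free parameters against 24
    free response categories (goodness-of-fit df = 2).
    """
    trees = tuple(
        _studied_tree(pl, it) if it != "new" else _new_tree(pl)
        for pl in PLAUSIBILITY
        for it in ITEM_TYPES
    )
    constraints = ()
    if baseline_constraints:
        constraints = (("D_P_new", "D_P_q"), ("D_I_new", "D_I_q"))
    return MptModel(trees=trees, equality_constraints=constraints, name="feedback-3source-2htsm")


# ---------------------------------------------------------------------------
# EQN I/O
# ---------------------------------------------------------------------------


class EqnFormatError(ValueError):
    """Raised for malformed or invalid EQN files."""


_COMPLEMENT_RE = re.compile(r"^\(1\s*-\s*([A-Za-z][A-Za-z0-9_]*)\)$")


def write_eqn(model: MptModel, path) -> None:
    """Write the tree structure in EQN format.

    Dialect (multiTree/MPTinR-compatible): a header line with the number of
    branch lines, then one line per branch with the 1-based tree index, the
    1-based category index within the tree's category order, and the product
    of parameter names with complements written ``(1-name)``.  Equality and
    fixing constraints are not part of the EQN format and are not written.
    """
    lines = []
    for ti, tree in enumerate(model.trees, start=1):
        pos = {c: i + 1 for i, c in enumerate(tree.categories)}
        for b in tree.branches:
            toks = [f"(1-{n})" if c else n for n, c in b.factors]
            lines.append(f"{ti} {pos[b.terminal]} {' '.join(toks)}")
    with open(path, "w") as fh:
        fh.write(f"{len(lines)}\n")
        fh.write("\n".join(lines) + "\n")


def read_eqn(path, categories: tuple[str, ...] | None = None, validate: bool = True) -> MptModel:
    """Read an EQN model file.

    ``categories`` supplies response-category labels per within-tree index;
    when omitted and a tree uses exactly the canonical four indices the
    canonical labels are used, otherwise generic ``c1, c2, ...`` labels.
    Tokens may be separated by whitespace or ``*``; complements are
    ``(1-name)``.  With ``validate=True`` each tree's branch probabilities
    are checked to sum to 1 at random interior parameter values.
    """
    with open(path) as fh:
        raw = [ln.strip() for ln in fh]
    raw = [ln for ln in raw if ln and not ln.startswith("#")]
    if not raw:
        raise EqnFormatError("empty EQN file")
    header = raw[0].split()
    body = raw[1:] if len(header) == 1 and header[0].isdigit() else raw
    per_tree: dict[int, list[tuple[int, tuple[tuple[str, bool], ...]]]] = {}
    for ln in body:
        parts = ln.replace("*", " ").split()
        if len(parts) < 3:
            raise EqnFormatError(f"malformed EQN line: {ln!r}")
        try:
            ti, ci = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise EqnFormatError(f"malformed tree/category index in line: {ln!r}") from exc
        if ci < 1:
            raise EqnFormatError(f"category index must be >= 1 in line: {ln!r}")
        factors = []
        for tok in parts[2:]:
            m = _COMPLEMENT_RE.match(tok)
            if m:
                factors.append((m.group(1), True))
            elif _NAME_RE.match(tok):
                factors.append((tok, False))
            else:
                raise EqnFormatError(f"illegal parameter token {tok!r} in line: {ln!r}")
        per_tree.setdefault(ti, []).append((ci, tuple(factors)))
    trees = []
    for ti in sorted(per_tree):
        n_cats = max(ci for ci, _ in per_tree[ti])
        if categories is not None:
            if n_cats > len(categories):
                raise EqnFormatError(
                    f"tree {ti} uses category index {n_cats} beyond supplied labels"
                )
            cats = tuple(categories)
        elif n_cats == len(CATEGORIES):
            cats = CATEGORIES
        else:
            cats = tuple(f"c{i + 1}" for i in range(n_cats))
        branches = tuple(
            Branch(factors, cats[ci - 1]) for ci, factors in per_tree[ti]
        )
        trees.append(SourceTree((f"tree{ti}", ""), branches, categories=cats))
    model = MptModel(trees=tuple(trees), name="eqn")
    if validate:
        rng = np.random.default_rng(0)
        for _ in range(3):
            theta = {n: v for n, v in zip(
                sorted(model.parameters), rng.uniform(0.1, 0.9, len(model.parameters))
            )}
            for t in model.trees:
                s = t.category_probabilities(model.expand_theta(theta)).sum()
                if abs(s - 1.0) > 1e-8:
                    raise EqnFormatError(
                        f"tree {t.condition} probabilities sum to {s:.6f} != 1; "
                        "EQN file does not describe a normalised MPT"
                    )
    return model
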