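"""Stratigraphic congruence indices and their building blocks.

Given a rooted binary cladogram and per-tip first-occurrence (FO) ages, a
clade's implied origin is the oldest FO among its members, and every branch
whose child is younger than that origin subtends a ghost range.  The sum of
ghost ranges is the minimum implied gap (MIG); MIG is bounded below by
Gmin = FOoldest - FOyoungest (attained by a perfectly laddered topology)
and above by Gmax = sum(FOoldest - FO_i) (every taxon hung directly off the
oldest).  The five indices computed here are:

* SCI  — fraction of non-root internal nodes whose oldest supported terminal
  is no older than that of its sister (ties count as consistent).
* GER  — 1 - (MIG - Gmin)/(Gmax - Gmin).
* MSM* — Gmin/MIG, equivalently the minimum over observed length of an
  irreversible (Sankoff) character coding FO ages.
* GERt — the GER form with Gmin/Gmax replaced by the permutation bounds
  Gtmin/Gtmax attainable on the *observed* topology.
* GER* — the fraction of permuted MIG values exceeding the observed MIG.

A vectorized kernel (:class:`TopologyArrays`) evaluates MIG and SCI for
many FO-to-tip assignments on a fixed topology at once; the permutation
machinery for GERt/GER* and the simulation study are built on it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .stratigraphy import FOTable, FOTableError
from .trees import Cladogram, Node, PolytomyError, TreeError, resolve_polytomies

__all__ = [
    "UndefinedIndexError",
    "TopologyArrays",
    "GhostRangeResult",
    "PermutationNull",
    "IndexReport",
    "node_ages",
    "mig",
    "sankoff_irreversible_length",
    "g_min",
    "g_max",
    "sci",
    "ger",
    "msm_star",
    "permutation_null",
    "ger_t",
    "ger_star",
    "index_report",
]


class UndefinedIndexError(ValueError):
    """An index is undefined for this input (e.g. all FO dates equal).

    Carries a machine-readable ``reason`` code; callers that assemble
    reports record the reason instead of a fabricated value.
    """

    def __init__(self, reason: str, message: str) -> None:
        super().__init__(message)
        self.reason = reason


def _require_binary(tree: Cladogram) -> None:
    if not tree.is_binary:
        raise PolytomyError(
            "index requires a binary tree; use resolve_polytomies first"
        )


# -- vectorized topology kernel ---------------------------------------------


class TopologyArrays:
    """Postorder index arrays for fast repeated MIG/SCI evaluation.

    Tips are numbered 0..n-1 in the tree's traversal order (``tip_labels``);
    internal nodes n..2n-2 in postorder, so every child index precedes its
    parent and the root is last.  Age inputs are arrays whose final axis has
    length n, ordered like ``tip_labels``; MIG and SCI broadcast over any
    leading axes (one row per FO-to-tip assignment).
    """

    def __init__(self, tree: Cladogram) -> None:
        _require_binary(tree)
        tips = tree.tips()
        self.tip_labels: list[str] = [t.label for t in tips]  # type: ignore[misc]
        self.n = len(tips)
        index: dict[Node, int] = {t: i for i, t in enumerate(tips)}
        left, right = [], []
        for node in tree.postorder():
            if node.is_leaf:
                continue
            a, b = node.children
            left.append(index[a])
            right.append(index[b])
            index[node] = self.n + len(left) - 1
        self.left = np.asarray(left, dtype=np.intp)
        self.right = np.asarray(right, dtype=np.intp)

    def node_max_ages(self, tip_ages: np.ndarray) -> np.ndarray:
        """Oldest descendant FO per node; shape (..., 2n-1), root last."""
        tip_ages = np.asarray(tip_ages, dtype=float)
        n = self.n
        out = np.empty(tip_ages.shape[:-1] + (2 * n - 1,), dtype=float)
        out[..., :n] = tip_ages
        for k in range(n - 1):
            out[..., n + k] = np.maximum(
                out[..., self.left[k]], out[..., self.right[k]]
            )
        return out

    def mig(self, tip_ages: np.ndarray) -> np.ndarray | float:
        """Sum of ghost ranges for each assignment row.

        For a binary node the two child clades share an origin at the older
        of their oldest FOs, so the node contributes |ageL - ageR|.
        """
        ages = self.node_max_ages(tip_ages)
        total = np.zeros(ages.shape[:-1], dtype=float)
        for k in range(self.n - 1):
            total += np.abs(ages[..., self.left[k]] - ages[..., self.right[k]])
        return total if total.ndim else float(total)

    def sci(self, tip_ages: np.ndarray) -> np.ndarray | float:
        """Stratigraphic consistency index for each assignment row."""
        if self.n < 3:
            raise TreeError("SCI undefined for fewer than 3 tips")
        ages = self.node_max_ages(tip_ages)
        n = self.n
        consistent = np.zeros(ages.shape[:-1], dtype=float)
        for k in range(n - 1):
            l, r = self.left[k], self.right[k]
            if l >= n:  # left child is an internal (non-root) node
                consistent += ages[..., l] <= ages[..., r]
            if r >= n:
                consistent += ages[..., r] <= ages[..., l]
        result = consistent / (n - 2)
        return result if result.ndim else float(result)


# -- node ages and ghost ranges ---------------------------------------------


def node_ages(tree: Cladogram, fo: FOTable) -> dict[Node, float]:
    """Implied origin age per node: the oldest FO among its descendant tips."""
    ages: dict[Node, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            ages[node] = float(fo.age_of(node.label))
        else:
            ages[node] = max(ages[c] for c in node.children)
    return ages


@dataclass
class GhostRangeResult:
    """Per-branch ghost ranges, their sum (MIG), and the topology-free bounds."""

    ghost_ranges: list[tuple[tuple[str, ...], float]]
    mig: float
    g_min: float
    g_max: float
    units: str = "interval"

    def __post_init__(self) -> None:
        eps = 1e-9 * max(1.0, abs(self.g_max))
        if not (self.g_min - eps <= self.mig <= self.g_max + eps):
            raise ValueError("MIG outside [Gmin, Gmax]; inconsistent inputs")


def mig(tree: Cladogram, fo: FOTable) -> GhostRangeResult:
    """Ghost ranges and their sum on a binary tree.

    Each branch's ghost range is age(parent) - age(child); branches at or
    below the root's children contribute (the root has no subtending branch).
    Ghost ranges are keyed by the sorted tip set of the child clade.
    """
    _require_binary(tree)
    ages = node_ages(tree, fo)
    ghosts: list[tuple[tuple[str, ...], float]] = []
    total = 0.0

    def clade_tips(node: Node) -> tuple[str, ...]:
        if node.is_leaf:
            return (node.label,)  # type: ignore[return-value]
        return tuple(sorted(t for c in node.children for t in clade_tips(c)))

    for node in tree.postorder():
        if node.parent is None:
            continue
        g = ages[node.parent] - ages[node]
        ghosts.append((clade_tips(node), g))
        total += g
    table = fo.subset(tree.tip_labels)
    return GhostRangeResult(
        ghost_ranges=ghosts,
        mig=total,
        g_min=g_min(table),
        g_max=g_max(table),
        units=fo.scale.unit,
    )


def sankoff_irreversible_length(tree: Cladogram, fo: FOTable) -> float:
    """Optimal length of the irreversible age character on the tree.

    Independent dynamic-programming check on the ghost-range sum: FO ages are
    coded as ordered states, a parent in state s may give a child in state t
    only if s is no younger (cost s - t, the stratigraphic step distance);
    younger-to-older change is forbidden.  The minimum total cost over all
    internal state assignments equals the MIG.
    """
    _require_binary(tree)
    states = np.unique(fo.ages_for(tree.tip_labels))  # ascending ages
    m = len(states)
    state_of = {a: i for i, a in enumerate(states)}

    cost: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.full(m, np.inf)
            vec[state_of[float(fo.age_of(node.label))]] = 0.0
            cost[node] = vec
        else:
            total = np.zeros(m)
            for child in node.children:
                c = cost[child]
                # min over child states t <= s of c[t] + (states[s] - states[t])
                best = np.minimum.accumulate(c - states)
                total += best + states
            cost[node] = total
    return float(np.min(cost[tree.root]))


# -- topology-free bounds ---------------------------------------------------


def g_min(fo: FOTable) -> float:
    """Smallest possible MIG on any topology: FOoldest - FOyoungest."""
    if len(fo) < 2:
        raise TreeError("Gmin needs at least two taxa")
    return fo.fo_oldest - fo.fo_youngest


def g_max(fo: FOTable) -> float:
    """Largest possible MIG on any topology: sum(FOoldest - FO_i)."""
    if len(fo) < 2:
        raise TreeError("Gmax needs at least two taxa")
    return float(np.sum(fo.fo_oldest - fo.fo_ages))


# -- scalar indices ---------------------------------------------------------


def sci(tree: Cladogram, fo: FOTable) -> float:
    """Stratigraphic consistency index.

    A non-root internal node is consistent if the oldest terminal it supports
    is no older than the oldest terminal supported by its sister; equal
    oldest ages count as consistent for both sisters.  SCI is the consistent
    fraction of the n-2 non-root internal nodes of a binary tree.
    """
    arrays = TopologyArrays(tree)
    return float(arrays.sci(fo.ages_for(arrays.tip_labels)))


def ger(tree: Cladogram, fo: FOTable) -> float:
    """Gap excess ratio: 1 - (MIG - Gmin)/(Gmax - Gmin)."""
    table = fo.subset(tree.tip_labels)
    lo, hi = g_min(table), g_max(table)
    if hi == lo:
        raise UndefinedIndexError(
            "all_fo_equal", "GER undefined: Gmax equals Gmin (all FO dates equal)"
        )
    observed = mig(tree, fo).mig
    return 1.0 - (observed - lo) / (hi - lo)


def msm_star(tree: Cladogram, fo: FOTable) -> float:
    """Modified Manhattan stratigraphic measure: Gmin/MIG (= Lm/Lo)."""
    table = fo.subset(tree.tip_labels)
    observed = mig(tree, fo).mig
    if observed == 0:
        raise UndefinedIndexError(
            "zero_mig", "MSM* undefined: MIG = 0 (all FO dates equal)"
        )
    return g_min(table) / observed


# -- permutation machinery ---------------------------------------------------


@dataclass
class PermutationNull:
    """The null distribution of MIG from shuffling FO dates over fixed tips.

    The observed MIG is pooled with the replicates when taking ``gt_min`` and
    ``gt_max`` so the bounds always bracket the observation.
    """

    observed_mig: float
    permuted_mig: np.ndarray
    gt_min: float
    gt_max: float
    reps: int
    seed: int | None = None
    exhaustive: bool = False


def permutation_null(
    tree: Cladogram,
    fo: FOTable,
    reps: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    rng: np.random.Generator | None = None,
) -> PermutationNull:
    """Estimate Gtmin/Gtmax by permuting FO dates across the tips.

    Each replicate shuffles the observed multiset of FO ages over the fixed
    topology (permutation without replacement) and recomputes MIG.  With
    ``exhaustive=True`` all n! orderings are evaluated instead (n <= 8).
    Deterministic for a given ``seed``.
    """
    arrays = TopologyArrays(tree)
    ages = fo.ages_for(arrays.tip_labels)
    observed = float(arrays.mig(ages))

    if exhaustive:
        if arrays.n > 8:
            raise TreeError("exhaustive permutation limited to 8 tips")
        perms = np.array(list(itertools.permutations(ages)), dtype=float)
        migs = np.asarray(arrays.mig(perms), dtype=float)
        reps = len(migs)
    else:
        if reps < 1:
            raise ValueError("reps must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        shuffled = rng.permuted(np.tile(ages, (reps, 1)), axis=1)
        migs = np.asarray(arrays.mig(shuffled), dtype=float)

    return PermutationNull(
        observed_mig=observed,
        permuted_mig=migs,
        gt_min=float(min(migs.min(), observed)),
        gt_max=float(max(migs.max(), observed)),
        reps=int(reps),
        seed=seed,
        exhaustive=exhaustive,
    )


def ger_t(null: PermutationNull) -> float:
    """Topological GER: 1 - (MIG - Gtmin)/(Gtmax - Gtmin)."""
    if null.gt_max == null.gt_min:
        raise UndefinedIndexError(
            "degenerate_null", "GERt undefined: Gtmax equals Gtmin"
        )
    return 1.0 - (null.observed_mig - null.gt_min) / (null.gt_max - null.gt_min)


# relative tolerance for treating a permuted MIG as tied with the observed
# value: sums of identical age multisets taken in different orders can
# differ in the last few ulps
_TIE_RTOL = 1e-12
_TIE_ATOL = 1e-9


def ger_star(null: PermutationNull, ties: str = "half") -> float:
    """Modified GER: fraction of permuted MIG values exceeding the observed.

    ``ties='half'`` (default) gives permuted values equal to the observed MIG
    half weight (midpoint rule); ``ties='strict'`` counts only strictly
    greater values.
    """
    if ties not in ("half", "strict"):
        raise ValueError("ties must be 'half' or 'strict'")
    migs = null.permuted_mig
    tied = np.isclose(migs, null.observed_mig, rtol=_TIE_RTOL, atol=_TIE_ATOL)
    greater = (migs > null.observed_mig) & ~tied
    if ties == "half":
        return float((greater.sum() + 0.5 * tied.sum()) / len(migs))
    return float(greater.sum() / len(migs))


# -- full report ------------------------------------------------------------


@dataclass
class IndexReport:
    """All five congruence indices plus bounds for one tree + FO table pair.

    Undefined indices are carried as ``None`` with a reason code in
    ``undefined`` — never fabricated sentinel numbers.
    """

    sci: float | None
    ger: float | None
    msm_star: float | None
    ger_t: float | None
    ger_star: float | None
    mig: float
    g_min: float
    g_max: float
    gt_min: float
    gt_max: float
    reps: int
    polytomy_mode: str
    seed: int | None
    units: str = "interval"
    n_taxa: int = 0
    undefined: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sci": self.sci,
            "ger": self.ger,
            "msm_star": self.msm_star,
            "ger_t": self.ger_t,
            "ger_star": self.ger_star,
            "mig": self.mig,
            "g_min": self.g_min,
            "g_max": self.g_max,
            "gt_min": self.gt_min,
            "gt_max": self.gt_max,
            "reps": self.reps,
            "polytomy_mode": self.polytomy_mode,
            "seed": self.seed,
            "units": self.units,
            "n_taxa": self.n_taxa,
            "undefined": dict(self.undefined),
        }


def index_report(
    tree: Cladogram,
    fo: FOTable,
    polytomy_mode: str = "hard",
    reps: int = 1000,
    seed: int | None = None,
    ties: str = "half",
) -> IndexReport:
    """Compute every congruence index for one tree + FO table pair.

    Polytomies are resolved against (``hard``, default) or with (``soft``)
    stratigraphic ordering before computing indices; the seed, replicate
    count and mode are echoed for reproducibility.
    """
    missing = [t for t in tree.tip_labels if t not in fo]
    if missing:
        raise FOTableError(f"tree tips missing from FO table: {missing}")
    work = tree if tree.is_binary else resolve_polytomies(tree, fo, mode=polytomy_mode)
    table = fo.subset(work.tip_labels)

    undefined: dict[str, str] = {}
    values: dict[str, float | None] = {}

    ghost = mig(work, table)

    try:
        values["sci"] = sci(work, table)
    except TreeError:
        values["sci"] = None
        undefined["sci"] = "too_few_tips"
    for name, fn in (("ger", ger), ("msm_star", msm_star)):
        try:
            values[name] = fn(work, table)
        except UndefinedIndexError as exc:
            values[name] = None
            undefined[name] = exc.reason

    null = permutation_null(work, table, reps=reps, seed=seed)
    try:
        values["ger_t"] = ger_t(null)
    except UndefinedIndexError as exc:
        values["ger_t"] = None
        undefined["ger_t"] = exc.reason
    values["ger_star"] = ger_star(null, ties=ties)

    return IndexReport(
        sci=values["sci"],
        ger=values["ger"],
        msm_star=values["msm_star"],
        ger_t=values["ger_t"],
        ger_star=values["ger_star"],
        mig=ghost.mig,
        g_min=ghost.g_min,
        g_max=ghost.g_max,
        gt_min=null.gt_min,
        gt_max=null.gt_max,
        reps=null.reps,
        polytomy_mode=polytomy_mode,
        seed=seed,
        units=table.scale.unit,
        n_taxa=work.n_tips,
        undefined=undefined,
    )
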