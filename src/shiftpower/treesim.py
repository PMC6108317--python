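"""Birth-death tree simulation and single-shift composite construction.

Constant-rate trees are simulated forward from two lineages at the crown
(age-conditioned, as in TESS's ``tess.sim.age``), rejecting outcomes in
which either crown lineage dies out, so every returned tree has exactly
the requested crown age.  Composite trees carry one speciation-rate
shift: a clade of the basetree whose crown age matches the subtree's
crown age to within ±2.5% is pruned, and an independently simulated
faster-speciating subtree is grafted in its place.  The grafted crown
node is labelled ``SHIFT`` and subtree descent defines the binary tip
character used downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .likelihoods import BDRates
from .trees import DatedTree, Node

__all__ = [
    "ShiftTree",
    "GridSpec",
    "InfeasibleSimulationError",
    "simulate_bd_tree",
    "find_graft_candidates",
    "graft_subtree",
    "simulate_composite",
    "simulate_set2_composite",
    "generate_grid",
    "set1_grid",
    "set2_grid",
]

logger = logging.getLogger(__name__)

GRAFT_LABEL = "SHIFT"
#: crown-age matching window for prunable clades (relative)
GRAFT_AGE_RTOL = 0.025
#: rejection budgets
MAX_SIM_ATTEMPTS = 10_000
MAX_CELL_ATTEMPTS = 50_000

SET2_ASYMMETRY = 2.0
SET2_LAM0_CHOICES = (0.2, 0.26, 0.28)
SET2_REL_AGE_RANGE = (30.0, 70.0)
SET2_BAGE_RANGE = (5.0, 35.0)
SET1_BAGE_RANGE = (5.0, 35.0)
#: per-part tolerance on the ratio-implied basetree/subtree tip targets
SET2_PART_RTOL = 0.25


class InfeasibleSimulationError(RuntimeError):
    """Rejection budget exhausted for a (rates, age, target) combination."""


@dataclass
class ShiftTree:
    """A composite dated tree plus the ground truth of its simulated shift."""

    tree: DatedTree
    graft_node: int
    base_rates: BDRates
    sub_rates: BDRates
    tip_states: dict[str, int]
    meta: dict = field(default_factory=dict)

    @property
    def asymmetry(self) -> float:
        return self.sub_rates.lam / self.base_rates.lam

    @property
    def subtree_age(self) -> float:
        return float(self.tree.age[self.graft_node])

    @property
    def n_subtree_tips(self) -> int:
        return sum(self.tip_states.values())

    @property
    def n_basetree_tips(self) -> int:
        return len(self.tip_states) - self.n_subtree_tips


# ----------------------------------------------------------------------
# constant-rate simulation


def _simulate_crown_once(
    age: float, lam: float, mu: float, rng: np.random.Generator,
    max_tips: int,
) -> Node | None:
    """One forward pass from two crown lineages; None on rejection.

    Rejection: either crown lineage leaves no extant descendant (which
    would shorten the reconstructed crown age), or the extant lineage
    count exceeds ``max_tips`` (runaway growth guard).
    """
    total = lam + mu
    root = Node()
    # stack entries: (node, birth time); time runs 0 (crown) -> age (present)
    crown_children = [Node(), Node()]
    root.children = crown_children
    stack = [(crown_children[0], 0.0), (crown_children[1], 0.0)]
    n_alive = 0
    while stack:
        node, t = stack.pop()
        if total == 0.0:
            node.length = age - t
            node.label = "x"  # extant marker
            n_alive += 1
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= age:
            node.length = age - t
            node.label = "x"
            n_alive += 1
            if n_alive > max_tips:
                return None
            continue
        if rng.random() < lam / total:
            node.length = dt
            node.children = [Node(), Node()]
            stack.append((node.children[0], t + dt))
            stack.append((node.children[1], t + dt))
        else:  # extinction
            node.length = dt
            node.label = None
        if len(stack) + n_alive > max_tips:
            return None
    # prune extinct lineages; both crown children must survive
    kept = [_prune_extinct(c) for c in crown_children]
    if kept[0] is None or kept[1] is None:
        return None
    root.children = kept
    return root


def _prune_extinct(node: Node) -> Node | None:
    """Drop extinct lineages; merge unary nodes into their child's stem."""
    if node.is_tip():
        return node if node.label == "x" else None
    kept = [c for c in (_prune_extinct(c) for c in node.children)
            if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.length += node.length
        return child
    node.children = kept
    return node


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_bd_tree(
    age: float,
    rates: BDRates,
    seed,
    max_tips: int = 100_000,
    max_attempts: int = MAX_SIM_ATTEMPTS,
    tip_prefix: str = "t",
) -> DatedTree:
    """Simulate a reconstructed birth-death tree of exact crown age.

    Forward simulation from two lineages at the crown for duration
    ``age``, conditioned (by rejection) on both crown lineages surviving;
    extinct lineages are pruned.  Tips are labelled ``t1..tn`` left to
    right (override with ``tip_prefix``).
    """
    if not age > 0:
        raise ValueError("age must be positive")
    rng = _as_rng(seed)
    for _ in range(max_attempts):
        root = _simulate_crown_once(age, rates.lam, rates.mu, rng, max_tips)
        if root is not None:
            _label_tips(root, tip_prefix)
            return DatedTree.from_node(root)
    raise InfeasibleSimulationError(
        f"no surviving crown tree in {max_attempts} attempts "
        f"(lam={rates.lam}, mu={rates.mu}, age={age})"
    )


def _label_tips(root: Node, prefix: str) -> None:
    i = 0
    for node in root.walk_postorder():
        if node.is_tip():
            i += 1
            node.label = f"{prefix}{i}"
        else:
            node.label = None


# ----------------------------------------------------------------------
# pruning & grafting


def find_graft_candidates(
    basetree: DatedTree, target_age: float, rel_tol: float = GRAFT_AGE_RTOL
) -> list[int]:
    """Internal non-root nodes whose crown age is within ±rel_tol of target.

    Crown-age matching: grafting equates the subtree's crown with the
    pruned clade's crown, so the candidate node's own age is compared.
    """
    if not target_age < basetree.crown_age:
        raise ValueError("target age must be below the basetree crown age")
    lo = target_age * (1.0 - rel_tol)
    hi = target_age * (1.0 + rel_tol)
    out = []
    for i in basetree.internal_ids(include_root=False):
        if lo <= basetree.age[int(i)] <= hi:
            out.append(int(i))
    return out


def graft_subtree(
    basetree: DatedTree, subtree: DatedTree, at_node: int
) -> ShiftTree:
    """Replace the clade below ``at_node`` with ``subtree``.

    The subtree keeps its own crown age: its stem length is set to
    ``age(parent of at_node) - subtree crown age``, so the composite is
    exactly ultrametric with the basetree's crown age.  Basetree tips are
    relabelled ``b1..bn``, subtree tips ``s1..sm``; the grafted crown node
    is labelled ``SHIFT``.  Rates in the returned ShiftTree are left for
    the caller to fill (this function only edits topology); use the
    ``simulate_composite`` drivers for fully annotated output.
    """
    if basetree.is_tip[at_node] or at_node == basetree.root:
        raise ValueError("graft point must be an internal non-root node")
    parent_age = float(basetree.age[basetree.parent[at_node]])
    s_age = subtree.crown_age
    if parent_age <= s_age:
        raise ValueError(
            f"subtree crown age {s_age:g} does not fit below the graft "
            f"point's parent (age {parent_age:g})"
        )
    base_root, base_map = basetree.to_node()
    sub_root, _ = subtree.to_node()
    old = base_map[at_node]
    old.children = sub_root.children
    old.label = GRAFT_LABEL
    # stem adjusted so the grafted crown sits at its simulated age
    old.length = parent_age - s_age
    # rescale: children stems unchanged (subtree already internally dated)
    bi = si = 0
    for node in base_root.walk_postorder():
        if node.is_tip():
            node.label = None
    # relabel after structure is final: subtree descent first
    for node in old.walk_postorder():
        if node.is_tip():
            si += 1
            node.label = f"s{si}"
    for node in base_root.walk_postorder():
        if node.is_tip() and node.label is None:
            bi += 1
            node.label = f"b{bi}"
    tree = DatedTree.from_node(base_root)
    graft_id = tree.find_by_label(GRAFT_LABEL)
    tip_states = {lab: (1 if lab.startswith("s") else 0)
                  for lab in tree.tip_labels()}
    return ShiftTree(
        tree=tree,
        graft_node=graft_id,
        base_rates=BDRates(1.0, 0.0),  # placeholder, overwritten by drivers
        sub_rates=BDRates(2.0, 0.0),
        tip_states=tip_states,
    )


# ----------------------------------------------------------------------
# composite drivers


def _expected_crown_tips(rates: BDRates, age: float) -> float:
    return 2.0 * math.exp(rates.r * age)


def simulate_composite(
    size_class: tuple[int, int],
    base_rates: BDRates,
    sub_rates: BDRates,
    rel_subtree_age: float,
    seed,
    max_attempts: int = MAX_SIM_ATTEMPTS,
) -> ShiftTree:
    """Simulate one single-shift composite tree (rate-asymmetry design).

    Rejection loop: draw the basetree age uniformly in [5, 35], simulate
    the basetree, look for a prunable clade matching the target subtree
    age (rel_subtree_age percent of the basetree age), simulate the
    subtree, and accept iff the composite tip count falls in
    ``center ± halfwidth``.
    """
    center, halfwidth = size_class
    if center - halfwidth < 4:
        raise ValueError("size class lower bound must be >= 4 tips")
    if not sub_rates.lam > base_rates.lam:
        raise ValueError("subtree speciation rate must exceed the basetree's")
    rng = _as_rng(seed)
    lo, hi = center - halfwidth, center + halfwidth
    cap = max(8 * hi, 200)
    for attempt in range(1, max_attempts + 1):
        b_age = rng.uniform(*SET1_BAGE_RANGE)
        s_age = rel_subtree_age * b_age / 100.0
        # cheap feasibility screen on expected sizes
        exp_total = (_expected_crown_tips(base_rates, b_age)
                     + _expected_crown_tips(sub_rates, s_age))
        if not (center / 4.0 <= exp_total <= center * 4.0):
            continue
        shift = _attempt_graft(
            b_age, s_age, base_rates, sub_rates, rng, lo, hi, cap,
            part_windows=None,
        )
        if shift is None:
            continue
        shift.meta.update(
            set=1,
            size_class=list(size_class),
            asymmetry=sub_rates.lam / base_rates.lam,
            rel_subtree_age=rel_subtree_age,
            tip_ratio=None,
            b_age=b_age,
            s_age=s_age,
            attempts=attempt,
        )
        return shift
    raise InfeasibleSimulationError(
        f"no composite tree in {max_attempts} attempts for size {size_class}, "
        f"asymmetry {sub_rates.lam / base_rates.lam:g}, "
        f"relative age {rel_subtree_age:g}%"
    )


def _attempt_graft(
    b_age, s_age, base_rates, sub_rates, rng, lo, hi, cap, part_windows
):
    """One simulate-prune-graft attempt; None if any acceptance gate fails."""
    base = _simulate_crown_once(b_age, base_rates.lam, base_rates.mu, rng, cap)
    if base is None:
        return None
    _label_tips(base, "t")
    basetree = DatedTree.from_node(base)
    candidates = [
        c for c in find_graft_candidates(basetree, s_age)
        if basetree.age[basetree.parent[c]] > s_age
    ]
    if not candidates:
        return None
    at_node = int(candidates[rng.integers(len(candidates))])
    n_base = basetree.n_tips
    n_pruned = len(basetree.clade_tips(at_node))
    n_base_part = n_base - n_pruned
    if n_base_part < 1:
        return None
    # required subtree size window implied by the composite window
    ns_lo, ns_hi = lo - n_base_part, hi - n_base_part
    if part_windows is not None:
        (pb_lo, pb_hi), (ps_lo, ps_hi) = part_windows
        if not pb_lo <= n_base_part <= pb_hi:
            return None
        ns_lo, ns_hi = max(ns_lo, ps_lo), min(ns_hi, ps_hi)
    if ns_hi < 2:
        return None
    sub = _simulate_crown_once(s_age, sub_rates.lam, sub_rates.mu, rng, cap)
    if sub is None:
        return None
    _label_tips(sub, "u")
    subtree = DatedTree.from_node(sub)
    if not ns_lo <= subtree.n_tips <= ns_hi:
        return None
    shift = graft_subtree(basetree, subtree, at_node)
    shift.base_rates = base_rates
    shift.sub_rates = sub_rates
    return shift


def _ratio_targets(center: int, tip_ratio: tuple[int, int]) -> tuple[float, float]:
    b, s = tip_ratio
    return center * b / (b + s), center * s / (b + s)


def simulate_set2_composite(
    size_class: tuple[int, int],
    tip_ratio: tuple[int, int],
    seed,
    mu: float = 0.05,
    max_attempts: int = MAX_CELL_ATTEMPTS,
) -> ShiftTree:
    """Simulate one composite tree hitting a basetree:subtree tip-ratio.

    Fixed 2x speciation asymmetry; the basetree rate is drawn from
    {0.2, 0.26, 0.28}, the basetree age from [5, 35] and the relative
    subtree age from [30, 70]% each attempt (automated stand-in for
    pilot-run calibration).  Acceptance additionally requires the
    basetree and subtree tip counts to sit within ±25% of the
    ratio-implied targets.  The (100 ± 10, 1:9) cell is remapped to 1:8.
    """
    center, halfwidth = size_class
    ratio = tuple(tip_ratio)
    if ratio not in ((9, 1), (1, 9), (1, 19), (1, 8)):
        raise ValueError(f"unsupported tip ratio {ratio}")
    if ratio == (1, 9) and center == 100:
        logger.info("size class 100±10 at 1:9 remapped to 1:8 "
                    "(1:9 not attainable at this size)")
        ratio = (1, 8)
    rng = _as_rng(seed)
    lo, hi = center - halfwidth, center + halfwidth
    nb_t, ns_t = _ratio_targets(center, ratio)
    pb = (nb_t * (1 - SET2_PART_RTOL), nb_t * (1 + SET2_PART_RTOL))
    ps = (ns_t * (1 - SET2_PART_RTOL), ns_t * (1 + SET2_PART_RTOL))
    cap = max(8 * hi, 200)
    for attempt in range(1, max_attempts + 1):
        lam0 = SET2_LAM0_CHOICES[rng.integers(len(SET2_LAM0_CHOICES))]
        base_rates = BDRates(lam0, mu)
        sub_rates = BDRates(SET2_ASYMMETRY * lam0, mu)
        b_age = rng.uniform(*SET2_BAGE_RANGE)
        rel_age = rng.uniform(*SET2_REL_AGE_RANGE)
        s_age = rel_age * b_age / 100.0
        exp_sub = _expected_crown_tips(sub_rates, s_age)
        if not (ns_t / 3.0 <= exp_sub <= ns_t * 3.0):
            continue
        exp_base = _expected_crown_tips(base_rates, b_age)
        if exp_base > 6.0 * center or exp_base < 0.4 * nb_t:
            continue
        shift = _attempt_graft(
            b_age, s_age, base_rates, sub_rates, rng, lo, hi, cap,
            part_windows=(pb, ps),
        )
        if shift is None:
            continue
        shift.meta.update(
            set=2,
            size_class=list(size_class),
            asymmetry=SET2_ASYMMETRY,
            rel_subtree_age=rel_age,
            tip_ratio=f"{ratio[0]}:{ratio[1]}",
            lam0=lam0,
            b_age=b_age,
            s_age=s_age,
            attempts=attempt,
        )
        return shift
    raise InfeasibleSimulationError(
        f"no composite tree in {max_attempts} attempts for size {size_class}, "
        f"tip ratio {ratio[0]}:{ratio[1]}"
    )


# ----------------------------------------------------------------------
# factorial grids


@dataclass
class GridSpec:
    """Factorial simulation design (defaults mirror the two study grids)."""

    set_id: int
    size_classes: list[tuple[int, int]]
    replicates: int
    base_seed: int
    # set 1 axes
    asymmetries: list[float] = field(default_factory=list)
    rel_ages: list[float] = field(default_factory=list)
    lam0: float = 0.2
    mu: float = 0.05
    # set 2 axis
    tip_ratios: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.set_id not in (1, 2):
            raise ValueError("set_id must be 1 or 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cells(self) -> list[dict]:
        out = []
        if self.set_id == 1:
            for size in self.size_classes:
                for age in self.rel_ages:
                    for asym in self.asymmetries:
                        out.append(dict(set=1, size_class=tuple(size),
                                        rel_age=age, asymmetry=asym))
        else:
            for size in self.size_classes:
                for ratio in self.tip_ratios:
                    out.append(dict(set=2, size_class=tuple(size),
                                    tip_ratio=tuple(ratio)))
        return out


def set1_grid(replicates: int = 50, base_seed: int = 1) -> GridSpec:
    """The full rate-asymmetry design (6 sizes x 3 ages x 5 asymmetries)."""
    return GridSpec(
        set_id=1,
        size_classes=[(50, 10), (100, 10), (150, 10), (200, 10),
                      (300, 10), (500, 10)],
        asymmetries=[1.5, 2.5, 3.5, 4.5, 5.5],
        rel_ages=[20.0, 40.0, 60.0],
        replicates=replicates,
        base_seed=base_seed,
    )


def set2_grid(replicates: int = 100, base_seed: int = 1) -> GridSpec:
    """The full tip-ratio design (5 sizes x 3 ratios)."""
    return GridSpec(
        set_id=2,
        size_classes=[(50, 10), (100, 10), (200, 10), (400, 10), (800, 10)],
        tip_ratios=[(9, 1), (1, 9), (1, 19)],
        replicates=replicates,
        base_seed=base_seed,
    )


def replicate_seed(base_seed: int, cell_idx: int, rep: int) -> int:
    """Deterministic per-replicate seed (independent of worker layout)."""
    ss = np.random.SeedSequence(entropy=base_seed,
                                spawn_key=(cell_idx, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_grid(spec: GridSpec) -> Iterator[tuple[dict, ShiftTree]]:
    """Yield (manifest row, ShiftTree) per replicate, cell by cell.

    Seeds are derived per (cell, replicate) from the base seed, so a
    reduced-replicate run reproduces a prefix of the full run.  Infeasible
    cells are logged and skipped without aborting other cells.
    """
    for cell_idx, cell in enumerate(spec.cells()):
        for rep in range(spec.replicates):
            seed = replicate_seed(spec.base_seed, cell_idx, rep)
            try:
                if spec.set_id == 1:
                    lam0 = spec.lam0
                    shift = simulate_composite(
                        cell["size_class"],
                        BDRates(lam0, spec.mu),
                        BDRates(cell["asymmetry"] * lam0, spec.mu),
                        cell["rel_age"],
                        seed,
                    )
                else:
                    shift = simulate_set2_composite(
                        cell["size_class"], cell["tip_ratio"], seed,
                        mu=spec.mu,
                    )
            except InfeasibleSimulationError as err:
                logger.warning("cell %s replicate %d infeasible: %s",
                               cell, rep, err)
                continue
            row = {
                "cell_index": cell_idx,
                "replicate": rep,
                "seed": seed,
                "set": spec.set_id,
                "size_center": cell["size_class"][0],
                "size_halfwidth": cell["size_class"][1],
                "asymmetry": shift.meta.get("asymmetry"),
                "rel_subtree_age": shift.meta.get("rel_subtree_age"),
                "tip_ratio": shift.meta.get("tip_ratio"),
                "lam0": shift.base_rates.lam,
                "mu0": shift.base_rates.mu,
                "lam1": shift.sub_rates.lam,
                "mu1": shift.sub_rates.mu,
                "n_tips": shift.tree.n_tips,
                "n_basetree_tips": shift.n_basetree_tips,
                "n_subtree_tips": shift.n_subtree_tips,
                "b_age": shift.meta.get("b_age"),
                "s_age": shift.meta.get("s_age"),
            }
            shift.meta["seed"] = seed
            yield row, shift
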