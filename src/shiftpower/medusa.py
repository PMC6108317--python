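"""Character-independent stepwise-AIC search for birth-death rate shifts.

The tree is partitioned into *pieces*, each evolving under its own
constant birth-death rates.  A shift placed at a node applies from that
node's stem edge downward (clade + stem).  The total log-likelihood is a
sum of per-piece reconstructed-process likelihoods in propagator form
(see :mod:`shiftpower.likelihoods`): every internal node contributes
``log lam`` of its piece, every branch segment contributes
``log phi_p(t_top) - log phi_p(t_bottom)`` with the piece's own survival
propagator, and survival conditioning is applied once at the root.  With
identical rates in all pieces the sum telescopes exactly to the
single-piece likelihood, so adding a null shift never changes the value.

Search: start from one piece; at each step try a shift on every eligible
stem edge, refit only the two affected pieces (the decomposition is
separable), keep the best candidate, and accept it iff the
small-sample-corrected AIC improves by more than a threshold.  The
default threshold grows with tree size — it is the AICc drop at which a
Bonferroni-corrected likelihood-ratio test over all candidate edges
(2 df, family-wise 0.05) would reject — mirroring stepwise-AIC
conventions in which the required improvement scales with the number of
branches tried.  A fixed threshold can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .detection import DetectionResult
from .likelihoods import _extinction_prob, _log_phi
from .trees import DatedTree

__all__ = [
    "MedusaModel",
    "medusa_search",
    "detect_shift_medusa",
    "default_aicc_threshold",
]

logger = logging.getLogger(__name__)

ROOT_PIECE = "root"
_EPS_MAX = 0.999  # upper bound on mu/lam during optimization
_LAM_MIN, _LAM_MAX = 1e-6, 50.0


@dataclass
class MedusaModel:
    """A piecewise constant-rate birth-death model on a dated tree.

    ``pieces`` is ordered; piece 0 starts at the root, later pieces at
    their shift node's stem edge.  ``assignment`` maps every node id to
    the piece governing its stem edge (and, for internal nodes, its
    branching event).  k counts two rates per piece plus one location per
    shift; AICc uses the number of internal nodes as the sample size.
    """

    shift_nodes: list  # [ROOT_PIECE, node_id, ...]
    rates: list[tuple[float, float]]  # (lam, mu) per piece
    logliks: list[float]  # per-piece log-likelihood contributions
    assignment: np.ndarray
    n_internal: int

    @property
    def n_pieces(self) -> int:
        return len(self.shift_nodes)

    @property
    def loglik(self) -> float:
        return float(sum(self.logliks))

    @property
    def k(self) -> int:
        return 2 * self.n_pieces + (self.n_pieces - 1)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def aicc(self) -> float:
        n, k = self.n_internal, self.k
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)


def default_aicc_threshold(n_candidates: int) -> float:
    """Required AICc improvement per accepted shift.

    Chosen so acceptance is equivalent to a 2-df likelihood-ratio test at
    family-wise level 0.05 over ``n_candidates`` candidate edges: the
    chi-square quantile minus the 6-point AIC penalty the three extra
    parameters already pay.
    """
    if n_candidates < 1:
        return np.inf
    q = float(stats.chi2.isf(0.05 / n_candidates, df=2))
    return max(q - 6.0, 0.0)


def _piece_loglik_terms(tree, assignment, piece):
    """Static bookkeeping for one piece: node counts and edge age arrays."""
    ids = np.flatnonzero(assignment == piece)
    internal = ids[~tree.is_tip[ids]]
    edges = ids[ids != tree.root]
    top = tree.age[tree.parent[edges]]
    bot = tree.age[edges]
    return internal.size, top, bot


def _fit_piece(tree, assignment, piece, start, conditioned):
    """ML rates for one piece; returns ((lam, mu), loglik).

    Extinction is parameterized as eps = mu/lam in [0, 0.999) for
    stability; the optimizer starts at ``start`` (the rates of the piece
    this one was split from) so a split can never lose likelihood.
    """
    n_int, top, bot = _piece_loglik_terms(tree, assignment, piece)
    crown = tree.crown_age

    def negll(x):
        lam = np.exp(np.clip(x[0], np.log(_LAM_MIN), np.log(_LAM_MAX)))
        eps = _EPS_MAX * expit(x[1])
        mu = lam * eps
        ll = n_int * np.log(lam)
        ll += float(np.sum(_log_phi(top, lam, mu)) - np.sum(_log_phi(bot, lam, mu)))
        if conditioned:
            e = _extinction_prob(crown, lam, mu)
            ll -= np.log(lam) + 2.0 * np.log1p(-e)
        return -ll if np.isfinite(ll) else 1e12

    lam0, mu0 = start
    eps0 = min(max(mu0 / lam0, 1e-4), 0.99)
    x0 = np.array([np.log(lam0), np.log(eps0 / (_EPS_MAX - eps0))])
    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"maxfev": 400, "xatol": 1e-6,
                                     "fatol": 1e-9})
    best_x, best_f = res.x, res.fun
    if negll(x0) < best_f:  # never regress below the inherited rates
        best_x, best_f = x0, negll(x0)
    lam = float(np.exp(np.clip(best_x[0], np.log(_LAM_MIN), np.log(_LAM_MAX))))
    eps = float(_EPS_MAX * expit(best_x[1]))
    return (lam, lam * eps), -best_f


def medusa_search(
    tree: DatedTree,
    max_shifts: int | None = None,
    threshold_rule: str = "size",
    seed: int = 0,
    fixed_threshold: float | None = None,
) -> tuple[list[MedusaModel], MedusaModel]:
    """Stepwise search for birth-death rate shifts.

    Returns ``(trace, selected)``: the best model at each shift count
    (0, 1, ... shifts) and the model at which the search stopped.
    Candidate shift points are internal non-root nodes (a shift on a
    terminal edge carries no branching information under this
    parameterization and is not tried).
    """
    if tree.n_tips < 4:
        raise ValueError("stepwise search needs at least 4 tips")
    if threshold_rule not in ("size", "fixed"):
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    n_internal = tree.n_tips - 1
    all_candidates = [int(i) for i in tree.internal_ids(include_root=False)]
    if fixed_threshold is not None or threshold_rule == "fixed":
        threshold = float(fixed_threshold if fixed_threshold is not None else 0.0)
    else:
        threshold = default_aicc_threshold(len(all_candidates))
    if max_shifts is None:
        max_shifts = max((n_internal - 1) // 3, 1)

    assignment = np.zeros(tree.n_nodes, dtype=np.int64)
    start = (max(np.log(tree.n_tips / 2.0) / tree.crown_age, 1e-3), 0.0)
    rates0, ll0 = _fit_piece(tree, assignment, 0, start, conditioned=True)
    current = MedusaModel(
        shift_nodes=[ROOT_PIECE],
        rates=[rates0],
        logliks=[ll0],
        assignment=assignment.copy(),
        n_internal=n_internal,
    )
    trace = [current]
    clade_masks = {v: tree.clade_mask(v) for v in all_candidates}

    while current.n_pieces - 1 < max_shifts:
        best = None
        used = set(current.shift_nodes[1:])
        for v in all_candidates:
            if v in used:
                continue
            p = int(current.assignment[v])
            split_mask = clade_masks[v] & (current.assignment == p)
            remain_mask = (current.assignment == p) & ~split_mask
            # both halves must retain likelihood information
            if not remain_mask.any() or not split_mask.any():
                continue
            new_assign = current.assignment.copy()
            new_piece = current.n_pieces
            new_assign[split_mask] = new_piece
            parent_rates = current.rates[p]
            cond_p = p == 0
            rates_a, ll_a = _fit_piece(tree, new_assign, p, parent_rates,
                                       conditioned=cond_p)
            rates_b, ll_b = _fit_piece(tree, new_assign, new_piece,
                                       parent_rates, conditioned=False)
            cand = MedusaModel(
                shift_nodes=current.shift_nodes + [v],
                rates=[*current.rates, rates_b],
                logliks=[*current.logliks, ll_b],
                assignment=new_assign,
                n_internal=n_internal,
            )
            cand.rates[p] = rates_a
            cand.logliks[p] = ll_a
            if best is None or cand.aicc < best.aicc:
                best = cand
        if best is None:
            break
        trace.append(best)
        if best.aicc < current.aicc - threshold:
            current = best
        else:
            break
    if current.n_pieces - 1 >= max_shifts:
        logger.info("stepwise search stopped at max_shifts=%d", max_shifts)
    return trace, current


def detect_shift_medusa(
    tree: DatedTree,
    graft_node: int,
    search: tuple[list[MedusaModel], MedusaModel],
) -> DetectionResult:
    """Detection = multi-rate model selected AND a shift at the graft node.

    Stem-edge placement counts as the node itself (the search places
    shifts on stem edges).  When detected, the subtree piece's rates are
    reported as the (lam1, mu1) estimates.
    """
    _, selected = search
    shift_nodes = selected.shift_nodes[1:]
    detected = selected.n_pieces > 1 and graft_node in shift_nodes
    extra = {
        "n_pieces": selected.n_pieces,
        "shift_nodes": list(shift_nodes),
        "lam0_hat": selected.rates[0][0],
        "mu0_hat": selected.rates[0][1],
    }
    if detected:
        idx = selected.shift_nodes.index(graft_node)
        extra["lam1_hat"] = selected.rates[idx][0]
        extra["mu1_hat"] = selected.rates[idx][1]
    elif selected.n_pieces > 1:
        # a shift was claimed somewhere else; record the first one
        extra["lam1_hat"] = selected.rates[1][0]
        extra["mu1_hat"] = selected.rates[1][1]
    return DetectionResult(method="medusa", detected=bool(detected),
                           extra=extra)
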