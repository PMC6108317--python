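"""Core likelihood engines on dated trees.

Three likelihoods share one set of conventions so that they compose:

* :func:`bd_loglik` — reconstructed constant-rate birth–death process,
  written in propagator form: each branch contributes
  ``log phi(t_parent) - log phi(t_child)`` with
  ``phi(t) = exp(-rt) * (r / (lam - mu * exp(-rt)))**2`` (r = lam - mu),
  and each internal node (crown included) contributes ``log lam``.
* :func:`mk2_loglik` — two-state Markov character model via Felsenstein
  pruning with closed-form 2x2 transition probabilities.
* :func:`bisse_loglik` — state-dependent speciation/extinction via
  per-branch integration of the (E0, E1, D0, D1) system.

With equal speciation and extinction rates in both states the BiSSE
likelihood factorizes exactly into ``bd_loglik + mk2_loglik`` (same root
rule, same survival conditioning); the test suite enforces this.

Root treatment follows the "observed" weighting: root state s receives
weight ``D_s / (D0 + D1)``.  Survival conditioning divides by
``sum_s w_s * lam_s * (1 - E_s(T))**2``, i.e. both crown lineages must
survive to the present.  Both conventions can be switched off through
:class:`LikelihoodOptions` (oracle tests do).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._bisse_ode import STATUS_OK, bisse_postorder
from .trees import DatedTree

__all__ = [
    "BDRates",
    "BisseParams",
    "LikelihoodOptions",
    "BisseError",
    "NEG_LL",
    "bd_loglik",
    "mk2_loglik",
    "bisse_loglik",
]

#: finite stand-in for log-likelihood -inf; model selection treats it as
#: "always worse" while keeping optimizers away from NaN arithmetic.
NEG_LL = -1e10


class BisseError(RuntimeError):
    """ODE failure or non-finite state during a BiSSE evaluation."""


@dataclass(frozen=True)
class BDRates:
    """Constant birth-death rates (events / lineage / time unit)."""

    lam: float
    mu: float

    def __post_init__(self):
        # lam = 0 is allowed so the simulator can express the degenerate
        # "no events" process; the likelihoods reject it.
        if self.lam < 0:
            raise ValueError(f"speciation rate must be >= 0, got {self.lam}")
        if self.mu < 0:
            raise ValueError(f"extinction rate must be non-negative, got {self.mu}")

    @property
    def r(self) -> float:
        """Net diversification rate lam - mu."""
        return self.lam - self.mu


@dataclass(frozen=True)
class BisseParams:
    """Six-parameter binary-state speciation/extinction model."""

    lam0: float
    lam1: float
    mu0: float
    mu1: float
    q01: float
    q10: float

    def __post_init__(self):
        if not (self.lam0 > 0 and self.lam1 > 0):
            raise ValueError("speciation rates must be positive")
        if min(self.mu0, self.mu1, self.q01, self.q10) < 0:
            raise ValueError("extinction and transition rates must be >= 0")

    def as_array(self) -> np.ndarray:
        """Kernel ordering: (lam0, mu0, q01, lam1, mu1, q10)."""
        return np.array(
            [self.lam0, self.mu0, self.q01, self.lam1, self.mu1, self.q10]
        )

    def swapped(self) -> "BisseParams":
        return BisseParams(self.lam1, self.lam0, self.mu1, self.mu0,
                           self.q10, self.q01)


@dataclass(frozen=True)
class LikelihoodOptions:
    root_rule: str = "obs"  # "obs" (weights prop. to D) or "equal"
    condition_on_survival: bool = True
    rtol: float = 1e-8
    atol: float = 1e-10
    sampling_fraction: float = 1.0

    def __post_init__(self):
        if self.root_rule not in ("obs", "equal"):
            raise ValueError(f"unknown root rule {self.root_rule!r}")
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("ODE tolerances must be positive")
        if self.sampling_fraction != 1.0:
            raise ValueError("only complete sampling is supported")


DEFAULT_OPTIONS = LikelihoodOptions()


# ----------------------------------------------------------------------
# birth-death


def _log_phi(t: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """log of the branch survival propagator phi(t); phi(0) = 1."""
    t = np.asarray(t, dtype=float)
    r = lam - mu
    if abs(r) < 1e-12 * lam:
        # critical process lam ~= mu: phi -> (1 + lam t)^-2
        return -r * t - 2.0 * np.log1p(lam * t)
    denom = r - mu * np.expm1(-r * t)  # = lam - mu e^{-rt}
    return -r * t + 2.0 * (np.log(abs(r)) - np.log(np.abs(denom)))


def _extinction_prob(t: float, lam: float, mu: float) -> float:
    """P(single lineage at age t leaves no extant descendant)."""
    if mu == 0.0:
        return 0.0
    r = lam - mu
    if abs(r) < 1e-12 * lam:
        return lam * t / (1.0 + lam * t)
    em = np.expm1(-r * t)
    return float(-mu * em / (r - mu * em))


def bd_loglik(tree: DatedTree, rates: BDRates, conditioned: bool = True) -> float:
    """Log-likelihood of the reconstructed birth-death process.

    Depends on the tree only through its branching times.  With
    ``conditioned`` the likelihood is conditioned on both crown lineages
    surviving to the present (dividing by ``lam * (1 - E(T))**2``), which
    matches the survival conditioning used by :func:`bisse_loglik`.
    """
    lam, mu = rates.lam, rates.mu
    if not lam > 0:
        raise ValueError("bd_loglik requires a positive speciation rate")
    n = tree.n_tips
    non_root = np.arange(tree.n_nodes) != tree.root
    child_ages = tree.age[non_root]
    parent_ages = tree.age[tree.parent[non_root]]
    ll = (n - 1) * np.log(lam)
    ll += float(np.sum(_log_phi(parent_ages, lam, mu))
                - np.sum(_log_phi(child_ages, lam, mu)))
    if conditioned:
        e_root = _extinction_prob(tree.crown_age, lam, mu)
        ll -= np.log(lam) + 2.0 * np.log1p(-e_root)
    return float(ll)


# ----------------------------------------------------------------------
# two-state Markov character (Mk2)


def _mk2_pmatrix(t: float, q01: float, q10: float) -> np.ndarray:
    q = q01 + q10
    if q == 0.0:
        return np.eye(2)
    pi0, pi1 = q10 / q, q01 / q
    e = np.exp(-q * t)
    return np.array([
        [pi0 + pi1 * e, pi1 * (1.0 - e)],
        [pi0 * (1.0 - e), pi1 + pi0 * e],
    ])


def _root_combine(partials: np.ndarray, root_rule: str) -> float:
    """log of the root-rule-weighted likelihood of the two root partials."""
    total = partials.sum()
    if total <= 0:
        return -np.inf
    if root_rule == "obs":
        weights = partials / total
    else:
        weights = np.array([0.5, 0.5])
    val = float(weights @ partials)
    return np.log(val) if val > 0 else -np.inf


def mk2_loglik(
    tree: DatedTree,
    states: dict[str, int],
    q01: float,
    q10: float,
    root_rule: str = "obs",
) -> float:
    """Felsenstein-pruning log-likelihood of a binary tip character.

    Impossible data (e.g. both states observed under zero transition
    rates) yield the finite sentinel :data:`NEG_LL`.
    """
    if min(q01, q10) < 0:
        raise ValueError("transition rates must be >= 0")
    partials = np.zeros((tree.n_nodes, 2))
    for i in tree.tip_ids():
        label = tree.labels[int(i)]
        if label not in states:
            raise KeyError(f"tip {label!r} has no character state")
        partials[int(i), states[label]] = 1.0
    logscale = 0.0
    for v in tree.postorder_internal:
        prod = np.ones(2)
        for c in (int(tree.left[v]), int(tree.right[v])):
            p = _mk2_pmatrix(tree.age[v] - tree.age[c], q01, q10)
            prod *= p @ partials[c]
        s = prod.sum()
        if s <= 0.0:
            return NEG_LL
        partials[int(v)] = prod / s
        logscale += np.log(s)
    ll = _root_combine(partials[tree.root], root_rule) + logscale
    return float(ll) if np.isfinite(ll) else NEG_LL


# ----------------------------------------------------------------------
# BiSSE


def _tip_state_array(tree: DatedTree, states: dict[str, int]) -> np.ndarray:
    arr = np.full(tree.n_nodes, -1, dtype=np.int64)
    for i in tree.tip_ids():
        label = tree.labels[int(i)]
        if label not in states:
            raise KeyError(f"tip {label!r} has no character state")
        s = states[label]
        if s not in (0, 1):
            raise ValueError(f"tip {label!r}: state must be 0 or 1")
        arr[int(i)] = s
    return arr


def bisse_loglik(
    tree: DatedTree,
    states: dict[str, int],
    params: BisseParams,
    opts: LikelihoodOptions = DEFAULT_OPTIONS,
    return_diagnostics: bool = False,
):
    """Joint log-likelihood of tree and binary tip states under BiSSE.

    Post-order traversal integrating the (E0, E1, D0, D1) equations up
    every branch, multiplying ``lam_s D_left D_right`` at nodes, then
    applying the root rule and (optionally) survival conditioning.

    Raises :class:`BisseError` (carrying the failing node id and the
    parameters) if the integrator loses the solution.
    """
    tip_state = _tip_state_array(tree, states)
    pars = params.as_array()
    root_y, logscale, status, failed, diag = bisse_postorder(
        tree.parent, tree.left, tree.right, tree.age,
        tree.postorder_internal, tip_state, pars, opts.rtol, opts.atol,
    )
    if status != STATUS_OK:
        raise BisseError(
            f"BiSSE integration failed (status {status}) on branch of node "
            f"{failed} with params {params}"
        )
    e_root = root_y[:2]
    d_root = root_y[2:]
    total = d_root.sum()
    if not (total > 0 and np.isfinite(total)):
        result = NEG_LL
    else:
        if opts.root_rule == "obs":
            weights = d_root / total
        else:
            weights = np.array([0.5, 0.5])
        val = float(weights @ d_root)
        if opts.condition_on_survival:
            lam = np.array([params.lam0, params.lam1])
            denom = float(weights @ (lam * (1.0 - e_root) ** 2))
            val = val / denom if denom > 0 else 0.0
        result = float(np.log(val) + logscale) if val > 0 else NEG_LL
    if return_diagnostics:
        return result, {"min_E": diag[0], "max_E": diag[1], "min_D": diag[2],
                        "E_root": e_root.copy(), "D_root": d_root.copy()}
    return result
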