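"""Constrained BiSSE model fitting and shift detection by likelihood ratio.

Eight nested constraint patterns of the six-parameter model are fitted by
maximum likelihood (derivative-free simplex from jittered moment-based
starts, quasi-Newton polish, log-scale parameters):

    I    all rates free                        k = 6
    II   lam1 = lam0                           k = 5
    III  mu1 = mu0                             k = 5
    IV   q01 = q10                             k = 5
    V    lam1 = lam0, mu1 = mu0                k = 4
    VI   mu1 = mu0,  q01 = q10                 k = 4
    VII  lam1 = lam0, q01 = q10                k = 4
    VIII all pairs tied (null)                 k = 3

A speciation-rate shift is declared by a likelihood-ratio test at
P < 0.05 between an unequal-lambda and an equal-lambda model, chosen one
of three ways: (1) minimum-AIC member of {I, III, IV, VI} against the
minimum-AIC member of {II, V, VII, VIII}; (2) III against V;
(3) VI against VIII.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .detection import DetectionResult
from .likelihoods import (
    NEG_LL,
    BisseError,
    BisseParams,
    DEFAULT_OPTIONS,
    LikelihoodOptions,
    bisse_loglik,
)
from .trees import DatedTree

__all__ = [
    "ModelSpec",
    "FitResult",
    "MODELS",
    "UNEQUAL_LAMBDA_MODELS",
    "EQUAL_LAMBDA_MODELS",
    "fit_bisse_model",
    "fit_all_models",
    "detect_shift_bisse",
    "select_best",
]

logger = logging.getLogger(__name__)

RATE_MIN, RATE_MAX = 1e-6, 20.0
_LOG_MIN, _LOG_MAX = np.log(RATE_MIN), np.log(RATE_MAX)


@dataclass(frozen=True)
class ModelSpec:
    """One constraint pattern: which rate pairs are tied equal."""

    model_id: str
    tie_lam: bool
    tie_mu: bool
    tie_q: bool

    @property
    def k(self) -> int:
        return 6 - int(self.tie_lam) - int(self.tie_mu) - int(self.tie_q)

    def free_names(self) -> list[str]:
        names = ["lam0"] + ([] if self.tie_lam else ["lam1"])
        names += ["mu0"] + ([] if self.tie_mu else ["mu1"])
        names += ["q01"] + ([] if self.tie_q else ["q10"])
        return names

    def expand(self, theta: np.ndarray) -> BisseParams:
        """Map a free-parameter vector (natural scale) to full parameters."""
        it = iter(theta)
        lam0 = next(it)
        lam1 = lam0 if self.tie_lam else next(it)
        mu0 = next(it)
        mu1 = mu0 if self.tie_mu else next(it)
        q01 = next(it)
        q10 = q01 if self.tie_q else next(it)
        return BisseParams(lam0, lam1, mu0, mu1, q01, q10)

    def reduce(self, params: BisseParams) -> np.ndarray:
        out = [params.lam0] + ([] if self.tie_lam else [params.lam1])
        out += [params.mu0] + ([] if self.tie_mu else [params.mu1])
        out += [params.q01] + ([] if self.tie_q else [params.q10])
        return np.array(out)


MODELS: dict[str, ModelSpec] = {
    "I": ModelSpec("I", False, False, False),
    "II": ModelSpec("II", True, False, False),
    "III": ModelSpec("III", False, True, False),
    "IV": ModelSpec("IV", False, False, True),
    "V": ModelSpec("V", True, True, False),
    "VI": ModelSpec("VI", False, True, True),
    "VII": ModelSpec("VII", True, False, True),
    "VIII": ModelSpec("VIII", True, True, True),
}

MODEL_ORDER = list(MODELS)
UNEQUAL_LAMBDA_MODELS = ("I", "III", "IV", "VI")
EQUAL_LAMBDA_MODELS = ("II", "V", "VII", "VIII")


@dataclass
class FitResult:
    model_id: str
    params: BisseParams
    loglik: float
    k: int
    converged: bool
    n_restarts: int

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


def _start_point(tree: DatedTree, spec: ModelSpec) -> np.ndarray:
    """Moment-based start: crown-Yule speciation rate, small mu and q."""
    lam = max(np.log(max(tree.n_tips, 3) / 2.0) / tree.crown_age, 1e-3)
    base = {"lam0": lam, "lam1": lam, "mu0": 0.1 * lam, "mu1": 0.1 * lam,
            "q01": 0.01, "q10": 0.01}
    return np.array([base[name] for name in spec.free_names()])


def fit_bisse_model(
    tree: DatedTree,
    states: dict[str, int],
    spec: ModelSpec,
    n_restarts: int = 3,
    seed: int = 0,
    opts: LikelihoodOptions = DEFAULT_OPTIONS,
) -> FitResult:
    """Maximize the BiSSE log-likelihood under one constraint pattern.

    Parameters are optimized on the log scale within [1e-6, 20]; each
    restart jitters the moment-based start multiplicatively.  The best
    restart wins; a fit that never produced a finite likelihood is
    flagged non-converged (selection skips it).
    """
    rng = np.random.default_rng(seed)
    ndim = spec.k

    def objective(log_theta: np.ndarray) -> float:
        theta = np.exp(np.clip(log_theta, _LOG_MIN, _LOG_MAX))
        try:
            ll = bisse_loglik(tree, states, spec.expand(theta), opts)
        except BisseError:
            return -NEG_LL
        return -ll

    start = _start_point(tree, spec)
    best_val = np.inf
    best_theta = np.log(start)
    converged = False
    for restart in range(n_restarts):
        x0 = np.log(start)
        if restart > 0:
            x0 = x0 + rng.normal(0.0, 0.5, size=ndim)
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxfev": 300 * ndim, "xatol": 1e-4, "fatol": 1e-7},
        )
        x1, v1 = res.x, res.fun
        polish = optimize.minimize(
            objective, x1, method="L-BFGS-B",
            bounds=[(_LOG_MIN, _LOG_MAX)] * ndim,
            options={"maxiter": 200},
        )
        if polish.fun < v1:
            x1, v1 = polish.x, polish.fun
        if v1 < best_val:
            best_val, best_theta = v1, x1
        if v1 < -NEG_LL / 2:
            converged = True
    params = spec.expand(np.exp(np.clip(best_theta, _LOG_MIN, _LOG_MAX)))
    if not converged:
        logger.warning("model %s failed to converge on %s", spec.model_id, tree)
    return FitResult(
        model_id=spec.model_id,
        params=params,
        loglik=-best_val,
        k=spec.k,
        converged=converged,
        n_restarts=n_restarts,
    )


def fit_all_models(
    tree: DatedTree,
    states: dict[str, int],
    n_restarts: int = 3,
    seed: int = 0,
    model_ids: tuple[str, ...] = tuple(MODEL_ORDER),
    opts: LikelihoodOptions = DEFAULT_OPTIONS,
) -> dict[str, FitResult]:
    fits = {}
    for i, mid in enumerate(model_ids):
        fits[mid] = fit_bisse_model(
            tree, states, MODELS[mid], n_restarts=n_restarts,
            seed=seed * 1009 + i, opts=opts,
        )
    return fits


def select_best(fits: dict[str, FitResult], group: tuple[str, ...]) -> FitResult:
    """Minimum-AIC converged fit; ties go to fewer parameters, then to the
    lower model number."""
    candidates = [fits[m] for m in group if m in fits and fits[m].converged]
    if not candidates:
        raise RuntimeError(f"no converged fits among models {group}")
    return min(
        candidates,
        key=lambda f: (f.aic, f.k, MODEL_ORDER.index(f.model_id)),
    )


def detect_shift_bisse(
    tree: DatedTree,
    states: dict[str, int],
    approach: int = 1,
    seed: int = 0,
    n_restarts: int = 3,
    fits: dict[str, FitResult] | None = None,
    opts: LikelihoodOptions = DEFAULT_OPTIONS,
) -> DetectionResult:
    """Declare a speciation-rate shift via a likelihood-ratio test.

    The degrees of freedom are the difference in free-parameter counts
    between the chosen models (at least 1; the AIC-chosen pair of
    approach 1 need not be nested).
    """
    if approach not in (1, 2, 3):
        raise ValueError("approach must be 1, 2 or 3")
    if approach == 1:
        needed = tuple(MODEL_ORDER)
        groups = (UNEQUAL_LAMBDA_MODELS, EQUAL_LAMBDA_MODELS)
    elif approach == 2:
        needed, groups = ("III", "V"), (("III",), ("V",))
    else:
        needed, groups = ("VI", "VIII"), (("VI",), ("VIII",))
    if fits is None:
        fits = fit_all_models(tree, states, n_restarts=n_restarts,
                              seed=seed, model_ids=needed, opts=opts)
    unequal = select_best(fits, groups[0])
    equal = select_best(fits, groups[1])
    stat = 2.0 * (unequal.loglik - equal.loglik)
    df = max(unequal.k - equal.k, 1)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return DetectionResult(
        method=f"bisse_approach{approach}",
        detected=bool(p < 0.05),
        stat=float(stat),
        df=df,
        p_value=p,
        model_unequal=unequal.model_id,
        model_equal=equal.model_id,
        extra={
            "lam0_hat": unequal.params.lam0,
            "lam1_hat": unequal.params.lam1,
        },
    )
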