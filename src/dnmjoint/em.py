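"""EM estimation of the mixture parameters.

The E-step computes class posteriors by Bayes' rule in log space.  The
M-step has an analytic update for the class prior ``pi`` and, per trait,
either an analytic intercept update (no-annotation model) or a safeguarded
Newton-Raphson maximization of the expected complete-data log-likelihood
``Q`` over the effect vector ``beta`` (annotation model).  ``Q`` is concave
in ``beta``, so step-halving Newton converges globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import (
    AnnotationDesign,
    CohortInfo,
    GeneTable,
    MixtureParams,
    PosteriorMatrix,
    class_loglik_matrix,
    marginal_loglik,
    risk_indicators,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitOptions",
    "FitResult",
    "e_step",
    "m_step_pi",
    "m_step_beta_closed",
    "newton_update_beta",
    "fit_multi",
    "fit_single",
]

#: Floor applied to class proportions whose posterior mass collapses,
#: keeping log(pi) finite on degenerate data.
_PI_FLOOR = 1e-12


@dataclass
class FitOptions:
    """Knobs for the EM loop and the inner Newton solver.

    Defaults favour deterministic, tightly converged fits: EM stops when the
    relative change of the observed-data log-likelihood drops below
    ``loglik_rel_tol``; the Newton solver stops at gradient infinity-norm
    ``newton_grad_tol``.
    """

    max_em_iter: int = 5000
    loglik_rel_tol: float = 1e-8
    newton_max_iter: int = 100
    newton_grad_tol: float = 1e-8
    ridge: float = 1e-8
    init_pi: np.ndarray | str = "default"
    init_beta_intercept: float | str = "moment"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_em_iter < 1 or self.newton_max_iter < 1:
            raise ValueError("iteration limits must be >= 1")
        if self.loglik_rel_tol <= 0 or self.newton_grad_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FitResult:
    params: MixtureParams
    posterior: PosteriorMatrix
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def to_dict(self) -> dict:
        out = {
            "pi": self.params.pi.tolist(),
            "beta1": self.params.beta1.tolist(),
            "loglik_trace": self.loglik_trace,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        if self.params.beta2 is not None:
            out["beta2"] = self.params.beta2.tolist()
        return out


def e_step(
    table: GeneTable,
    cohorts: CohortInfo,
    designs: list[AnnotationDesign],
    params: MixtureParams,
) -> PosteriorMatrix:
    """Class posteriors Z_il = pi_l Pr(Y_i|l) / sum_l' pi_l' Pr(Y_i|l').

    Normalized in log space; rows sum to one exactly up to rounding.
    """
    ll = class_loglik_matrix(table, cohorts, designs, params)
    with np.errstate(divide="ignore"):
        log_num = ll + np.log(params.pi)[None, :]
    log_den = logsumexp(log_num, axis=1)
    if not np.isfinite(log_den).all():
        bad = table.gene_id[~np.isfinite(log_den)][:5]
        raise FloatingPointError(
            f"zero total likelihood in E-step for genes: {', '.join(map(str, bad))}"
        )
    return np.exp(log_num - log_den[:, None])


def m_step_pi(posterior: PosteriorMatrix) -> np.ndarray:
    """Analytic M-step for the class prior: column means of the posterior."""
    posterior = np.asarray(posterior, dtype=float)
    if posterior.ndim != 2 or posterior.shape[0] == 0:
        raise ValueError("posterior must be a non-empty 2-D matrix")
    pi = posterior.mean(axis=0)
    return pi / pi.sum()


def _trait_weights(posterior: PosteriorMatrix, n_traits: int, trait: int) -> np.ndarray:
    """Posterior probability that each gene carries risk for ``trait``."""
    risks = risk_indicators(n_traits)
    return posterior @ risks[:, trait - 1]


def m_step_beta_closed(
    posterior: PosteriorMatrix,
    table: GeneTable,
    cohorts: CohortInfo,
    trait: int,
) -> float:
    """Analytic intercept update for the no-annotation model.

    beta = log( sum_i w_i Y_i / sum_i w_i 2 N mu_i ) with w_i the posterior
    risk weight for the trait; the exponential of this is the weighted
    moment estimate of the common relative risk.
    """
    w = _trait_weights(posterior, table.n_traits, trait)
    y = table.counts[:, trait - 1]
    base = 2.0 * cohorts.sizes[trait - 1] * table.mu
    num = float(w @ y)
    den = float(w @ base)
    if den <= 0:
        raise ZeroDivisionError("total weighted null expectation is zero")
    if num <= 0:
        raise FloatingPointError(
            "weighted count sum is zero: relative-risk estimate degenerates to 0"
        )
    return float(np.log(num / den))


def _q_beta(w, y, base, design, beta):
    """Expected complete-data log-likelihood in beta, up to a beta-free constant."""
    eta = design.matrix @ beta
    lam = base * np.exp(eta)
    return float(w @ (y * eta - lam))


def _grad_hess(w, y, base, design, beta):
    eta = design.matrix @ beta
    lam = base * np.exp(eta)
    if not np.isfinite(lam).all():
        raise FloatingPointError("relative-risk overflow in Newton step")
    x = design.matrix
    grad = x.T @ (w * (y - lam))
    hess = -(x.T * (w * lam)) @ x
    return grad, hess


def newton_update_beta(
    posterior: PosteriorMatrix,
    table: GeneTable,
    cohorts: CohortInfo,
    design: AnnotationDesign,
    beta_current: np.ndarray,
    trait: int,
    ridge: float = 1e-8,
    max_halvings: int = 30,
) -> np.ndarray:
    """One damped Newton-Raphson step on beta for one trait.

    The step is ``beta - H^{-1} g`` with the gradient and Hessian of ``Q``;
    the Hessian is ridge-regularized if numerically singular and the step is
    halved until ``Q`` does not decrease.
    """
    w = _trait_weights(posterior, table.n_traits, trait)
    y = table.counts[:, trait - 1].astype(float)
    base = 2.0 * cohorts.sizes[trait - 1] * table.mu
    beta = np.asarray(beta_current, dtype=float)
    grad, hess = _grad_hess(w, y, base, design, beta)
    if np.max(np.abs(grad)) == 0.0:
        return beta.copy()
    try:
        step = np.linalg.solve(hess, grad)
    except np.linalg.LinAlgError:
        reg = ridge * np.trace(-hess) / hess.shape[0] + ridge
        step = np.linalg.solve(hess - reg * np.eye(hess.shape[0]), grad)
    q0 = _q_beta(w, y, base, design, beta)
    scale = 1.0
    for _ in range(max_halvings):
        candidate = beta - scale * step
        try:
            q1 = _q_beta(w, y, base, design, candidate)
        except FloatingPointError:
            q1 = -np.inf
        if np.isfinite(q1) and q1 >= q0:
            return candidate
        scale *= 0.5
    return beta.copy()


def _maximize_beta(posterior, table, cohorts, design, beta_start, trait, opts):
    """Run Newton to convergence for one trait's beta (inner M-step loop)."""
    w = _trait_weights(posterior, table.n_traits, trait)
    y = table.counts[:, trait - 1].astype(float)
    base = 2.0 * cohorts.sizes[trait - 1] * table.mu
    beta = np.asarray(beta_start, dtype=float)
    for _ in range(opts.newton_max_iter):
        grad, _ = _grad_hess(w, y, base, design, beta)
        if np.max(np.abs(grad)) < opts.newton_grad_tol:
            break
        new = newton_update_beta(
            posterior, table, cohorts, design, beta, trait, ridge=opts.ridge
        )
        if np.allclose(new, beta, rtol=0.0, atol=1e-14):
            break
        beta = new
    return beta


def _moment_intercept(table: GeneTable, cohorts: CohortInfo, trait: int) -> float:
    """log of the overall count inflation, floored at log(1.5)."""
    y = table.counts[:, trait - 1]
    base = 2.0 * cohorts.sizes[trait - 1] * table.mu
    ratio = float(y.sum() / base.sum())
    return float(np.log(max(1.5, ratio)))


def _initial_params(table, cohorts, designs, opts) -> MixtureParams:
    n_traits = table.n_traits
    if isinstance(opts.init_pi, str):
        pi0 = np.array([0.9, 0.1]) if n_traits == 1 else np.array([0.90, 0.04, 0.04, 0.02])
    else:
        pi0 = np.asarray(opts.init_pi, dtype=float)
    betas = []
    for t in range(1, n_traits + 1):
        p = designs[t - 1].matrix.shape[1]
        beta = np.zeros(p)
        if opts.init_beta_intercept == "moment":
            beta[0] = _moment_intercept(table, cohorts, t)
        else:
            beta[0] = float(opts.init_beta_intercept)
        betas.append(beta)
    if n_traits == 1:
        return MixtureParams(pi=pi0, beta1=betas[0])
    return MixtureParams(pi=pi0, beta1=betas[0], beta2=betas[1])


def _floor_pi(pi: np.ndarray, m: int) -> np.ndarray:
    collapsed = pi < _PI_FLOOR
    if collapsed.any():
        pi = np.where(collapsed, _PI_FLOOR, pi)
        pi = pi / pi.sum()
    return pi


def _fit(table, cohorts, designs, opts) -> FitResult:
    params = _initial_params(table, cohorts, designs, opts)
    trace: list[float] = [marginal_loglik(table, cohorts, designs, params)]
    posterior = e_step(table, cohorts, designs, params)
    converged = False
    n_iter = 0
    for n_iter in range(1, opts.max_em_iter + 1):
        pi = _floor_pi(m_step_pi(posterior), table.n_genes)
        betas = []
        for t in range(1, table.n_traits + 1):
            design = designs[t - 1]
            if design.n_features == 0:
                try:
                    beta = np.array([m_step_beta_closed(posterior, table, cohorts, t)])
                except FloatingPointError:
                    # all posterior count mass in the null: freeze the intercept
                    beta = params.betas[t - 1].copy()
            else:
                beta = _maximize_beta(
                    posterior, table, cohorts, design, params.betas[t - 1], t, opts
                )
            betas.append(beta)
        if table.n_traits == 1:
            params = MixtureParams(pi=pi, beta1=betas[0])
        else:
            params = MixtureParams(pi=pi, beta1=betas[0], beta2=betas[1])
        ll = marginal_loglik(table, cohorts, designs, params)
        trace.append(ll)
        prev = trace[-2]
        if ll < prev - 1e-8 * max(1.0, abs(prev)):
            logger.warning("log-likelihood decreased at EM iteration %d", n_iter)
        if abs(ll - prev) < opts.loglik_rel_tol * max(1.0, abs(prev)):
            converged = True
        posterior = e_step(table, cohorts, designs, params)
        if converged:
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", opts.max_em_iter)
    if any(b[0] <= 0 for b in params.betas):
        logger.warning(
            "a fitted intercept is <= 0 (relative risk <= 1), contrary to the "
            "model's assumption of enriched risk genes"
        )
    return FitResult(
        params=params,
        posterior=posterior,
        loglik_trace=trace,
        converged=converged,
        n_iter=n_iter,
    )


def fit_multi(
    table: GeneTable,
    cohorts: CohortInfo,
    design1: AnnotationDesign | None = None,
    design2: AnnotationDesign | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the two-trait four-class mixture by EM.

    ``design1``/``design2`` default to intercept-only (the no-annotation
    model); supplying annotation columns switches the per-trait M-step to
    the Newton solver.
    """
    if table.n_traits != 2:
        raise ValueError("fit_multi requires a two-trait GeneTable (y2 present)")
    if cohorts.n2 is None:
        raise ValueError("fit_multi requires both cohort sizes (n2 missing)")
    opts = options or FitOptions()
    d1 = design1 or AnnotationDesign.intercept_only(table.n_genes, 1)
    d2 = design2 or AnnotationDesign.intercept_only(table.n_genes, 2)
    if d1.matrix.shape[0] != table.n_genes or d2.matrix.shape[0] != table.n_genes:
        raise ValueError("designs must be row-aligned with the gene table")
    return _fit(table, cohorts, [d1, d2], opts)


def fit_single(
    table: GeneTable,
    cohorts: CohortInfo,
    design: AnnotationDesign | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the single-trait two-class mixture by EM on ``y1``.

    A two-trait table may be passed; only its first trait is used.
    """
    opts = options or FitOptions()
    if table.n_traits == 2:
        table = GeneTable(gene_id=table.gene_id, mu=table.mu, y1=table.y1)
    cohorts = CohortInfo(n1=cohorts.n1)
    d = design or AnnotationDesign.intercept_only(table.n_genes, 1)
    if d.matrix.shape[0] != table.n_genes:
        raise ValueError("design must be row-aligned with the gene table")
    return _fit(table, cohorts, [d], opts)
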