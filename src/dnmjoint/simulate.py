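"""Synthetic-data generation and replicate scoring.

Two generators are provided.  The "true" generator draws data from the
fitted model itself: a four-class multinomial latent state with prior
``pi``, i.i.d. Bernoulli(0.5) annotations per trait, relative risk
``exp(x' beta)`` through the exponential link, and Poisson counts with mean
``2*N*mu`` (null) or ``2*N*mu*gamma`` (risk).  The "misspecified" generator
instead lets annotations act on the latent class through a multinomial
logistic link and fixes the relative risk at a constant, probing robustness
when the assumed risk model is wrong.

Gene mutabilities are drawn from a truncated log10-normal law that matches
the scale of damaging-class mutabilities of real exome genes (medians near
1e-5, range roughly 1e-8 to 3e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .em import FitOptions, FitResult, fit_multi, fit_single
from .inference import jlfdr as _jlfdr_fn
from .inference import run_inference
from .model import AnnotationDesign, CohortInfo, GeneTable

__all__ = [
    "SimulationConfig",
    "ReplicateMetrics",
    "pi_from_margins",
    "sample_mutabilities",
    "simulate_true_model",
    "simulate_misspecified",
    "evaluate_replicate",
    "run_grid",
    "METHODS",
]

#: The four analysis routes compared in the simulation study.
METHODS = ("single_noanno", "single_anno", "multi_noanno", "multi_anno")


def pi_from_margins(margin1: float, margin2: float, pi11: float) -> np.ndarray:
    """Class prior (00, 10, 01, 11) from marginal risk proportions and pi_11.

    ``pi11 = margin1 * margin2`` corresponds to independent association
    status across the two traits; larger values indicate pleiotropy.
    """
    pi10 = margin1 - pi11
    pi01 = margin2 - pi11
    pi00 = 1.0 - pi10 - pi01 - pi11
    pi = np.array([pi00, pi10, pi01, pi11])
    if (pi < 0).any():
        raise ValueError(
            f"inconsistent margins: pi would be {pi.tolist()} for "
            f"margins ({margin1}, {margin2}) and pi11={pi11}"
        )
    return pi


@dataclass
class SimulationConfig:
    """Generative settings for one simulation scenario.

    ``beta1``/``beta2`` are (intercept, effect_1, ..., effect_p) on the
    exponential-link scale for the true model and on the logistic
    latent-class scale for the misspecified model.  ``n_observed`` limits
    how many of the p annotations the analyst sees (the rest influence the
    data but are hidden); ``None`` exposes all of them.
    """

    n_genes: int = 10_000
    n1: int = 5_000
    n2: int = 5_000
    pi: np.ndarray = field(default_factory=lambda: pi_from_margins(0.1, 0.1, 0.05))
    beta1: np.ndarray = field(default_factory=lambda: np.array([3.0, 0.1, 0.1]))
    beta2: np.ndarray = field(default_factory=lambda: np.array([3.0, 0.1, 0.1]))
    bernoulli_p: float = 0.5
    n_observed: int | None = None
    model: str = "true"
    fixed_gamma: float = 25.0
    mutability_log10_mean: float = -5.0
    mutability_log10_sd: float = 0.7
    mutability_log10_range: tuple[float, float] = (-8.0, -3.5)
    n_replicates: int = 50
    base_seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        if self.model not in ("true", "misspecified"):
            raise ValueError("model must be 'true' or 'misspecified'")
        if self.model == "misspecified" and self.fixed_gamma <= 1:
            raise ValueError("fixed_gamma must exceed 1 for the misspecified model")
        if self.beta1.shape != self.beta2.shape:
            raise ValueError("beta1 and beta2 must have equal length")
        n_anno = self.beta1.shape[0] - 1
        if self.n_observed is not None and not 0 <= self.n_observed <= n_anno:
            raise ValueError(
                f"n_observed must be in [0, {n_anno}], got {self.n_observed}"
            )

    @property
    def n_annotations(self) -> int:
        return self.beta1.shape[0] - 1

    @property
    def observed_slice(self) -> slice:
        k = self.n_annotations if self.n_observed is None else self.n_observed
        return slice(0, k)


@dataclass
class ReplicateMetrics:
    """Power/FDR/type-I/AUC scoreboard for one analysis of one replicate."""

    power: float | None
    empirical_fdr: float
    type1: float
    auc: float | None
    n_rejected: int
    estimates: dict = field(default_factory=dict)


def sample_mutabilities(
    m: int,
    rng: np.random.Generator,
    log10_mean: float = -5.0,
    log10_sd: float = 0.7,
    log10_range: tuple[float, float] = (-8.0, -3.5),
) -> np.ndarray:
    """Draw ``m`` positive mutabilities: log10(mu) ~ truncated Normal."""
    lo, hi = log10_range
    if not (lo < hi and log10_sd > 0):
        raise ValueError("invalid mutability law parameters")
    a, b = (lo - log10_mean) / log10_sd, (hi - log10_mean) / log10_sd
    draws = stats.truncnorm.rvs(
        a, b, loc=log10_mean, scale=log10_sd, size=m, random_state=rng
    )
    return 10.0 ** draws


def _replicate_rng(config: SimulationConfig, rep_index: int) -> np.random.Generator:
    return np.random.default_rng(config.base_seed + rep_index)


def _draw_common(config: SimulationConfig, rng: np.random.Generator):
    m = config.n_genes
    mu = sample_mutabilities(
        m,
        rng,
        config.mutability_log10_mean,
        config.mutability_log10_sd,
        config.mutability_log10_range,
    )
    x1 = rng.binomial(1, config.bernoulli_p, size=(m, config.n_annotations)).astype(float)
    x2 = rng.binomial(1, config.bernoulli_p, size=(m, config.n_annotations)).astype(float)
    return mu, x1, x2


def _assemble(config, rng, mu, x1, x2, z_class, gamma1, gamma2):
    m = config.n_genes
    risk1 = np.isin(z_class, (1, 3))
    risk2 = np.isin(z_class, (2, 3))
    lam1 = 2.0 * config.n1 * mu * np.where(risk1, gamma1, 1.0)
    lam2 = 2.0 * config.n2 * mu * np.where(risk2, gamma2, 1.0)
    y1 = rng.poisson(lam1)
    y2 = rng.poisson(lam2)
    gene_id = np.array([f"g{i:05d}" for i in range(m)], dtype=object)
    table = GeneTable(gene_id=gene_id, mu=mu, y1=y1, y2=y2)
    obs = config.observed_slice
    names = [f"a{j + 1}" for j in range(config.n_annotations)][obs]
    designs = [
        AnnotationDesign.from_features(x1[:, obs], names, trait_index=1),
        AnnotationDesign.from_features(x2[:, obs], names, trait_index=2),
    ]
    truth = pd.DataFrame(
        {"gene_id": gene_id.astype(str), "class": z_class, "risk1": risk1, "risk2": risk2}
    )
    return table, designs, truth


def simulate_true_model(config: SimulationConfig, rep_index: int = 0):
    """One replicate from the exponential-link mixture model.

    Returns ``(GeneTable, [design1, design2], truth)`` where the designs
    contain only the observed annotation subset and ``truth`` records each
    gene's latent class and per-trait risk status.
    """
    if config.model != "true":
        raise ValueError("config.model must be 'true'")
    rng = _replicate_rng(config, rep_index)
    mu, x1, x2 = _draw_common(config, rng)
    z_class = rng.choice(4, size=config.n_genes, p=config.pi)
    ones = np.ones((config.n_genes, 1))
    gamma1 = np.exp(np.column_stack([ones, x1]) @ config.beta1)
    gamma2 = np.exp(np.column_stack([ones, x2]) @ config.beta2)
    return _assemble(config, rng, mu, x1, x2, z_class, gamma1, gamma2)


def simulate_misspecified(config: SimulationConfig, rep_index: int = 0):
    """One replicate with annotations acting on the latent class.

    Per-gene class probabilities follow the multinomial-logistic form
    P(Z_10) proportional to exp(x1' b1), P(Z_01) to exp(x2' b2), P(Z_11) to
    exp(x1' b1 + x2' b2) — equivalently two independent per-trait logistic
    Bernoulli draws — and the relative risk is the fixed constant
    ``fixed_gamma`` for every risk gene.
    """
    if config.model != "misspecified":
        raise ValueError("config.model must be 'misspecified'")
    rng = _replicate_rng(config, rep_index)
    mu, x1, x2 = _draw_common(config, rng)
    ones = np.ones((config.n_genes, 1))
    eta1 = np.column_stack([ones, x1]) @ config.beta1
    eta2 = np.column_stack([ones, x2]) @ config.beta2
    # factorized form of the 4-class multinomial logistic model
    p_risk1 = 1.0 / (1.0 + np.exp(-eta1))
    p_risk2 = 1.0 / (1.0 + np.exp(-eta2))
    risk1 = rng.random(config.n_genes) < p_risk1
    risk2 = rng.random(config.n_genes) < p_risk2
    z_class = np.select(
        [risk1 & risk2, risk1, risk2], [3, 1, 2], default=0
    )
    g = config.fixed_gamma
    return _assemble(config, rng, mu, x1, x2, z_class, np.full(config.n_genes, g), np.full(config.n_genes, g))


def simulate(config: SimulationConfig, rep_index: int = 0):
    """Dispatch on ``config.model``."""
    if config.model == "true":
        return simulate_true_model(config, rep_index)
    return simulate_misspecified(config, rep_index)


def evaluate_replicate(
    test: pd.DataFrame, truth: pd.DataFrame, trait: int = 1
) -> ReplicateMetrics:
    """Score one analysis against the generating truth for one trait.

    power = rejected risk genes / risk genes; empirical FDR = false
    rejections / max(1, rejections); type-I = false rejections / null
    genes; AUC ranks risk status by 1 - Jlfdr with ties counted 1/2.
    """
    merged = test.merge(truth[["gene_id", f"risk{trait}"]], on="gene_id", validate="1:1")
    risk = merged[f"risk{trait}"].to_numpy(dtype=bool)
    sig = merged[f"sig_t{trait}"].to_numpy(dtype=bool)
    score = 1.0 - merged[f"jlfdr_t{trait}"].to_numpy(dtype=float)
    n_risk = int(risk.sum())
    n_null = int((~risk).sum())
    n_rej = int(sig.sum())
    false_rej = int((sig & ~risk).sum())
    power = None if n_risk == 0 else float((sig & risk).sum() / n_risk)
    fdr = float(false_rej / max(1, n_rej))
    type1 = 0.0 if n_null == 0 else float(false_rej / n_null)
    auc = None
    if 0 < n_risk < len(risk):
        auc = float(roc_auc_score(risk, score))
    return ReplicateMetrics(
        power=power, empirical_fdr=fdr, type1=type1, auc=auc, n_rejected=n_rej
    )


def _analyze(method: str, table, cohorts, designs, options) -> FitResult:
    d1, d2 = designs
    m = table.n_genes
    if method == "single_noanno":
        return fit_single(table, cohorts, None, options)
    if method == "single_anno":
        return fit_single(table, cohorts, replace(d1, trait_index=1), options)
    if method == "multi_noanno":
        return fit_multi(table, cohorts, None, None, options)
    if method == "multi_anno":
        return fit_multi(table, cohorts, d1, d2, options)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_replicate(
    config: SimulationConfig,
    rep_index: int,
    method: str = "multi_anno",
    q: float = 0.05,
    options: FitOptions | None = None,
):
    """Simulate, fit, test and score one replicate for one method.

    Returns ``(metrics_by_trait, fit, test_table, truth)``; single-trait
    methods report trait 1 only.
    """
    table, designs, truth = simulate(config, rep_index)
    cohorts = CohortInfo(n1=config.n1, n2=config.n2)
    fit = _analyze(method, table, cohorts, designs, options)
    test = run_inference(fit, table if method.startswith("multi") else GeneTable(
        gene_id=table.gene_id, mu=table.mu, y1=table.y1
    ), q=q)
    traits = (1, 2) if method.startswith("multi") else (1,)
    metrics = {t: evaluate_replicate(test, truth, t) for t in traits}
    est = {"loglik": fit.loglik, "converged": fit.converged, "n_iter": fit.n_iter}
    if method.startswith("multi"):
        est.update(
            pi00_hat=fit.params.pi[0],
            pi10_hat=fit.params.pi[1],
            pi01_hat=fit.params.pi[2],
            pi11_hat=fit.params.pi[3],
        )
    else:
        est.update(pi1_hat=fit.params.pi[1])
    for t in metrics:
        metrics[t].estimates = est
    return metrics, fit, test, truth


def run_grid(
    configs: list[SimulationConfig],
    methods: tuple[str, ...] = METHODS,
    q: float = 0.05,
    options: FitOptions | None = None,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Replicate grid: every config x replicate x method, scored per trait.

    Per-replicate randomness is seeded as ``base_seed + replicate`` so the
    grid is reproducible and all methods see identical data within a
    replicate.  Individual replicate failures are recorded as missing rows
    rather than aborting the grid.
    """
    rows = []
    for config in configs:
        reps = n_replicates if n_replicates is not None else config.n_replicates
        for rep in range(reps):
            for method in methods:
                try:
                    metrics, *_ = run_replicate(config, rep, method, q, options)
                except Exception as exc:  # pragma: no cover - defensive
                    rows.append(
                        {
                            "setting": config.label,
                            "replicate": rep,
                            "method": method,
                            "trait": 1,
                            "error": str(exc),
                        }
                    )
                    continue
                for trait, met in metrics.items():
                    rows.append(
                        {
                            "setting": config.label,
                            "replicate": rep,
                            "method": method,
                            "trait": trait,
                            "power": met.power,
                            "fdr": met.empirical_fdr,
                            "type1": met.type1,
                            "auc": met.auc,
                            "n_rejected": met.n_rejected,
                            **met.estimates,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_grid(grid: pd.DataFrame) -> pd.DataFrame:
    """Means and Monte-Carlo standard errors over replicates."""
    metrics = [c for c in ("power", "fdr", "type1", "auc", "pi11_hat") if c in grid]
    grouped = grid.groupby(["setting", "method", "trait"], dropna=False)[metrics]
    mean = grouped.mean()
    se = grouped.sem()
    out = mean.join(se, lsuffix="_mean", rsuffix="_se").reset_index()
    return out
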