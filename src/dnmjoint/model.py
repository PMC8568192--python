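"""Core data model and likelihood primitives.

The observed data are per-gene de novo mutation (DNM) counts from one or two
case cohorts of parent-offspring trios.  Under the null, the count for gene
``i`` in a cohort of ``N`` trios is Poisson with mean ``2*N*mu_i`` where
``mu_i`` is the gene's mutability for the analyzed mutation class; in a risk
gene the mean is inflated by a relative risk ``gamma_i``, linked to the
gene's annotation vector through ``gamma_i = exp(x_i' beta)``.

With two traits each gene carries a four-way latent class ``(00, 10, 01,
11)`` indicating which traits it is associated with; the class prior ``pi``
measures global pleiotropy through the excess of ``pi_11`` over the
independence product.  All likelihoods here are computed and mixed in log
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "CLASS_LABELS_TWO_TRAIT",
    "CLASS_LABELS_SINGLE_TRAIT",
    "risk_indicators",
    "GeneTable",
    "CohortInfo",
    "AnnotationDesign",
    "MixtureParams",
    "PosteriorMatrix",
    "expected_count",
    "gene_relative_risk",
    "class_loglik",
    "class_loglik_matrix",
    "marginal_loglik",
]

#: Fixed class order for the two-trait mixture: neither / first only /
#: second only / both.  This is also the on-disk column order.
CLASS_LABELS_TWO_TRAIT = ("00", "10", "01", "11")

#: Class order for the single-trait two-component mixture.
CLASS_LABELS_SINGLE_TRAIT = ("0", "1")


def risk_indicators(n_traits: int) -> np.ndarray:
    """Return the (n_classes, n_traits) 0/1 matrix saying which latent class
    carries risk for which trait.

    Row order matches :data:`CLASS_LABELS_TWO_TRAIT` /
    :data:`CLASS_LABELS_SINGLE_TRAIT`.
    """
    if n_traits == 1:
        return np.array([[0], [1]], dtype=float)
    if n_traits == 2:
        return np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
    raise ValueError(f"only 1 or 2 traits supported, got {n_traits}")


@dataclass
class GeneTable:
    """Per-gene DNM counts and mutabilities.

    Parameters
    ----------
    gene_id
        Unique gene identifiers, length ``M``.
    mu
        Per-gene mutability of the analyzed mutation class (probability per
        haploid genome per generation); strictly positive.
    y1
        DNM count in cohort 1, non-negative integers.
    y2
        DNM count in cohort 2; ``None`` in single-trait mode.
    """

    gene_id: np.ndarray
    mu: np.ndarray
    y1: np.ndarray
    y2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.mu = np.asarray(self.mu, dtype=float)
        self.y1 = _validate_counts(np.asarray(self.y1), "y1")
        if self.y2 is not None:
            self.y2 = _validate_counts(np.asarray(self.y2), "y2")
            if self.y2.shape != self.y1.shape:
                raise ValueError("y1 and y2 must have equal length")
        m = self.gene_id.shape[0]
        if not (self.mu.shape[0] == self.y1.shape[0] == m):
            raise ValueError("gene_id, mu and counts must have equal length")
        bad = ~np.isfinite(self.mu) | (self.mu <= 0)
        if bad.any():
            offenders = ", ".join(map(str, self.gene_id[bad][:10]))
            raise ValueError(
                f"mutability must be positive and finite; offending genes: {offenders}"
            )
        ids, counts = np.unique(self.gene_id.astype(str), return_counts=True)
        if (counts > 1).any():
            dupes = ", ".join(ids[counts > 1][:10])
            raise ValueError(f"duplicate gene_id values: {dupes}")

    @property
    def n_genes(self) -> int:
        return self.gene_id.shape[0]

    @property
    def n_traits(self) -> int:
        return 1 if self.y2 is None else 2

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (M, n_traits) integer matrix."""
        if self.y2 is None:
            return self.y1[:, None]
        return np.column_stack([self.y1, self.y2])


def _validate_counts(y: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(y)
    if not np.all(np.isfinite(arr.astype(float))):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(arr.astype(float) != np.round(arr.astype(float))):
        raise ValueError(f"{name} must contain integers")
    out = arr.astype(np.int64)
    if (out < 0).any():
        raise ValueError(f"{name} must be non-negative")
    return out


@dataclass
class CohortInfo:
    """Trio counts of the case cohorts (``n2`` absent in single-trait mode)."""

    n1: int
    n2: int | None = None

    def __post_init__(self) -> None:
        for name, value in (("n1", self.n1), ("n2", self.n2)):
            if value is None:
                continue
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        self.n1 = int(self.n1)
        if self.n2 is not None:
            self.n2 = int(self.n2)

    @property
    def sizes(self) -> tuple[int, ...]:
        return (self.n1,) if self.n2 is None else (self.n1, self.n2)


@dataclass
class AnnotationDesign:
    """Gene x feature design matrix for one trait, including the intercept.

    The first column is identically 1; with no annotations the design
    degenerates to the intercept column alone.
    """

    trait_index: int
    feature_names: list[str]
    matrix: np.ndarray
    standardized: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.trait_index not in (1, 2):
            raise ValueError("trait_index must be 1 or 2")
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("design matrix must be 2-D with >= 1 column")
        if not np.isfinite(self.matrix).all():
            raise ValueError("design matrix contains non-finite entries")
        if not np.allclose(self.matrix[:, 0], 1.0):
            raise ValueError("first design column must be the constant 1 (intercept)")
        if len(self.feature_names) != self.matrix.shape[1]:
            raise ValueError("feature_names length must match column count")
        if not self.standardized:
            self.standardized = [False] * self.matrix.shape[1]

    @classmethod
    def intercept_only(cls, n_genes: int, trait_index: int = 1) -> "AnnotationDesign":
        return cls(
            trait_index=trait_index,
            feature_names=["intercept"],
            matrix=np.ones((n_genes, 1)),
        )

    @classmethod
    def from_features(
        cls,
        features: np.ndarray,
        feature_names: list[str],
        trait_index: int = 1,
    ) -> "AnnotationDesign":
        """Prepend an intercept column to a plain feature matrix."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        m = features.shape[0]
        matrix = np.column_stack([np.ones(m), features])
        return cls(
            trait_index=trait_index,
            feature_names=["intercept", *feature_names],
            matrix=matrix,
        )

    @property
    def n_features(self) -> int:
        """Number of non-intercept columns."""
        return self.matrix.shape[1] - 1


@dataclass
class MixtureParams:
    """Model parameters: class prior ``pi`` and per-trait effect vectors.

    ``pi`` is ordered (00, 10, 01, 11) in two-trait mode and (0, 1) in
    single-trait mode.  ``beta1``/``beta2`` include the intercept as their
    first element; ``beta2`` is absent in single-trait mode.
    """

    pi: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta1 = np.atleast_1d(np.asarray(self.beta1, dtype=float))
        if self.beta2 is not None:
            self.beta2 = np.atleast_1d(np.asarray(self.beta2, dtype=float))
        if self.pi.shape[0] not in (2, 4):
            raise ValueError("pi must have length 2 (single-trait) or 4 (two-trait)")
        if (self.pi < 0).any():
            raise ValueError("pi entries must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError(f"pi must sum to 1, got {self.pi.sum()!r}")
        if not np.isfinite(self.beta1).all():
            raise ValueError("beta1 must be finite")
        if self.beta2 is not None and not np.isfinite(self.beta2).all():
            raise ValueError("beta2 must be finite")
        if self.pi.shape[0] == 4 and self.beta2 is None:
            raise ValueError("two-trait parameters require beta2")

    @property
    def n_traits(self) -> int:
        return 1 if self.pi.shape[0] == 2 else 2

    @property
    def betas(self) -> list[np.ndarray]:
        return [self.beta1] if self.beta2 is None else [self.beta1, self.beta2]


#: Alias used in signatures: an (M, n_classes) matrix of class posteriors,
#: rows summing to 1, column order matching ``pi``.
PosteriorMatrix = np.ndarray


def expected_count(n: int, mu: float, gamma: float = 1.0) -> float:
    """Poisson mean ``2*n*mu*gamma`` of the DNM count in ``n`` trios.

    Each trio contributes two haploid genomes, hence the factor 2;
    ``gamma=1`` gives the null mean.
    """
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    return 2.0 * n * mu * gamma


def gene_relative_risk(x_row: np.ndarray, beta: np.ndarray) -> float:
    """Relative risk ``exp(x' beta)`` under the exponential link."""
    x_row = np.asarray(x_row, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x_row.shape != beta.shape:
        raise ValueError(
            f"annotation row and effect vector lengths differ: "
            f"{x_row.shape} vs {beta.shape}"
        )
    return float(np.exp(x_row @ beta))


def _poisson_logpmf(y: np.ndarray, log_lam: np.ndarray, lam: np.ndarray) -> np.ndarray:
    # y*log(lam) - lam - log(y!); log-space form avoids pmf underflow.
    return y * log_lam - lam - gammaln(y + 1.0)


def class_loglik(
    y1: int,
    y2: int | None,
    n1: int,
    n2: int | None,
    mu: float,
    gamma1: float,
    gamma2: float | None,
    class_label: str,
) -> float:
    """Log Pr(Y_i1[, Y_i2] | Z_il = 1) for one gene and one latent class.

    The two traits are conditionally independent given the class, so the
    value is the sum of one Poisson log-pmf per trait, with mean
    ``2*N*mu*gamma`` when the class carries risk for that trait and
    ``2*N*mu`` otherwise.
    """
    if y2 is None:
        labels, risks = CLASS_LABELS_SINGLE_TRAIT, risk_indicators(1)
        ys, ns, gammas = [y1], [n1], [gamma1]
    else:
        labels, risks = CLASS_LABELS_TWO_TRAIT, risk_indicators(2)
        ys, ns, gammas = [y1, y2], [n1, n2], [gamma1, gamma2]
    if class_label not in labels:
        raise ValueError(f"invalid class label {class_label!r}; expected one of {labels}")
    row = risks[labels.index(class_label)]
    total = 0.0
    for t, (y, n, g) in enumerate(zip(ys, ns, gammas)):
        lam = expected_count(n, mu, g if row[t] else 1.0)
        total += float(_poisson_logpmf(np.float64(y), np.log(lam), lam))
    return total


def class_loglik_matrix(
    table: GeneTable,
    cohorts: CohortInfo,
    designs: list[AnnotationDesign],
    params: MixtureParams,
) -> np.ndarray:
    """(M, n_classes) matrix of per-gene, per-class log-likelihoods.

    Vectorized over genes; the workhorse behind the E-step and the marginal
    log-likelihood.
    """
    counts = table.counts.astype(float)
    n_traits = table.n_traits
    if params.n_traits != n_traits or len(designs) != n_traits:
        raise ValueError("table, designs and params disagree on the number of traits")
    risks = risk_indicators(n_traits)
    n_classes = risks.shape[0]
    out = np.zeros((table.n_genes, n_classes))
    lgamma_y = gammaln(counts + 1.0)
    for t in range(n_traits):
        n_t = cohorts.sizes[t]
        log_lam0 = np.log(2.0 * n_t * table.mu)
        eta = designs[t].matrix @ params.betas[t]
        y = counts[:, t]
        # null and risk log-pmfs for this trait, each length M
        ll_null = y * log_lam0 - np.exp(log_lam0) - lgamma_y[:, t]
        log_lam1 = log_lam0 + eta
        ll_risk = y * log_lam1 - np.exp(log_lam1) - lgamma_y[:, t]
        for l in range(n_classes):
            out[:, l] += ll_risk if risks[l, t] else ll_null
    if not np.isfinite(out).all():
        bad = np.where(~np.isfinite(out).all(axis=1))[0]
        offenders = ", ".join(map(str, table.gene_id[bad][:5]))
        raise FloatingPointError(
            f"non-finite class log-likelihood (relative-risk overflow?) for genes: {offenders}"
        )
    return out


def marginal_loglik(
    table: GeneTable,
    cohorts: CohortInfo,
    designs: list[AnnotationDesign],
    params: MixtureParams,
) -> float:
    """Observed-data log-likelihood: sum_i log sum_l pi_l Pr(Y_i | class l).

    The inner mixture is accumulated with log-sum-exp; classes with
    ``pi_l = 0`` contribute nothing.
    """
    ll = class_loglik_matrix(table, cohorts, designs, params)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
    return float(logsumexp(ll + log_pi[None, :], axis=1).sum())
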