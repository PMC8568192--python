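"""Variant-to-gene annotation collapsing and two-stage feature selection.

Variant-level annotation scores of the observed DNMs are aggregated to a
gene-level score by summing the (optionally mean-centered) values over the
gene's mutations; a first-order expansion of the per-gene likelihood ratio
shows that this sum is the sufficient gene-level feature when per-variant
effects are small.  Gene-level features are then normalized, pruned for
pairwise Pearson correlation above 0.7 (first-in-order wins), and finally
filtered by fitted effect size |beta| > 0.01 with a refit on the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .em import FitOptions, FitResult, fit_single
from .model import AnnotationDesign, CohortInfo, GeneTable

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSelectionReport",
    "collapse_to_gene",
    "standardize_features",
    "prune_correlated",
    "select_by_effect_size",
    "build_design",
]


@dataclass
class FeatureSelectionReport:
    """Record of which features survived each selection stage."""

    kept_after_correlation: list[str] = field(default_factory=list)
    dropped_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    kept_after_effect_size: list[str] = field(default_factory=list)
    effect_sizes: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kept_after_correlation": self.kept_after_correlation,
            "dropped_pairs": [
                {"kept": k, "dropped": d, "r": r} for k, d, r in self.dropped_pairs
            ],
            "kept_after_effect_size": self.kept_after_effect_size,
            "effect_sizes": self.effect_sizes,
        }


def collapse_to_gene(
    variants: pd.DataFrame,
    genes: np.ndarray | list[str],
    annotation_cols: list[str] | None = None,
    center: bool | dict[str, bool] = True,
) -> pd.DataFrame:
    """Sum variant-level annotation values of observed DNMs per gene.

    ``variants`` lists one row per observed DNM with a ``gene_id`` column
    and numeric annotation columns.  Every gene in ``genes`` appears in the
    output; genes with no DNMs score 0 on every feature.  When centering is
    on for a column, its DNM-wide mean is subtracted before summing (binary
    flags are conventionally collapsed as plain counts with centering off).
    Missing values are imputed by the column's DNM-wide mean, with a logged
    tally.
    """
    genes = np.asarray(genes, dtype=object).astype(str)
    if annotation_cols is None:
        annotation_cols = [
            c for c in variants.columns if c not in ("gene_id", "variant_id")
        ]
    known = set(genes)
    unknown = set(variants["gene_id"].astype(str)) - known
    if unknown:
        raise ValueError(
            f"variant rows reference unknown genes: {sorted(unknown)[:10]}"
        )
    work = variants[["gene_id", *annotation_cols]].copy()
    work["gene_id"] = work["gene_id"].astype(str)
    for col in annotation_cols:
        values = pd.to_numeric(work[col], errors="raise")
        n_missing = int(values.isna().sum())
        if n_missing:
            logger.info("imputed %d missing values in %s with the DNM-wide mean", n_missing, col)
            values = values.fillna(values.mean())
        do_center = center[col] if isinstance(center, dict) else center
        if do_center and len(values):
            values = values - values.mean()
        work[col] = values
    sums = work.groupby("gene_id")[annotation_cols].sum()
    out = sums.reindex(genes, fill_value=0.0)
    out.index.name = "gene_id"
    return out.astype(float)


def standardize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Scale every column to mean 0, standard deviation 1 across genes.

    Uses the population (1/n) standard deviation.  Constant columns carry
    no information and are dropped with a warning; if everything is
    constant the result is empty (an intercept-only design downstream).
    """
    if len(features) < 2:
        raise ValueError("standardization requires at least 2 genes")
    out = {}
    for col in features.columns:
        values = features[col].to_numpy(dtype=float)
        sd = values.std()  # population scaling
        if sd == 0:
            logger.warning("dropping constant feature %s", col)
            continue
        out[col] = (values - values.mean()) / sd
    return pd.DataFrame(out, index=features.index)


def prune_correlated(
    features: pd.DataFrame,
    threshold: float = 0.7,
    absolute: bool = False,
) -> FeatureSelectionReport:
    """Greedy correlation pruning in input column order.

    A feature is dropped if its Pearson correlation with any already-kept
    feature exceeds ``threshold``; by default the signed correlation is
    compared (set ``absolute=True`` to compare |r|).
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if len(features) < 2:
        raise ValueError("correlation is undefined with fewer than 2 genes")
    report = FeatureSelectionReport()
    for col in features.columns:
        values = features[col].to_numpy(dtype=float)
        drop_against = None
        for kept in report.kept_after_correlation:
            r = _pearson(features[kept].to_numpy(dtype=float), values)
            stat = abs(r) if absolute else r
            if stat > threshold:
                drop_against = (kept, float(r))
                break
        if drop_against is None:
            report.kept_after_correlation.append(col)
        else:
            report.dropped_pairs.append((drop_against[0], col, drop_against[1]))
    return report


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def build_design(
    features: pd.DataFrame, trait_index: int = 1, standardized: bool = True
) -> AnnotationDesign:
    """Assemble an AnnotationDesign (intercept + feature columns)."""
    design = AnnotationDesign.from_features(
        features.to_numpy(dtype=float) if len(features.columns) else np.empty((len(features), 0)),
        list(features.columns),
        trait_index=trait_index,
    )
    design.standardized = [False] + [standardized] * (design.matrix.shape[1] - 1)
    return design


def select_by_effect_size(
    table: GeneTable,
    cohorts: CohortInfo,
    features: pd.DataFrame,
    options: FitOptions | None = None,
    cutoff: float = 0.01,
    trait_index: int = 1,
) -> tuple[FitResult, AnnotationDesign, FeatureSelectionReport]:
    """Effect-size selection stage: fit, keep |beta| > cutoff, refit.

    Fits the single-trait annotation model on the supplied features,
    retains non-intercept features with fitted |beta| above ``cutoff``, and
    refits on the retained set.  Selection is done per trait on that
    trait's own single-trait analysis; multi-trait designs are assembled
    afterwards from each trait's survivors.
    """
    report = FeatureSelectionReport(kept_after_correlation=list(features.columns))
    design = build_design(features, trait_index)
    first = fit_single(table, cohorts, design, options)
    if not first.converged:
        raise RuntimeError(
            "single-trait selection fit did not converge; cannot rank features"
        )
    effects = dict(zip(features.columns, first.params.beta1[1:]))
    report.effect_sizes = {k: float(v) for k, v in effects.items()}
    keep = [name for name, b in effects.items() if abs(b) > cutoff]
    report.kept_after_effect_size = keep
    final_design = build_design(features[keep], trait_index)
    final_fit = fit_single(table, cohorts, final_design, options)
    return final_fit, final_design, report


def select_features(
    table: GeneTable,
    cohorts: CohortInfo,
    features: pd.DataFrame,
    options: FitOptions | None = None,
    corr_threshold: float = 0.7,
    effect_cutoff: float = 0.01,
    absolute_corr: bool = False,
    trait_index: int = 1,
) -> tuple[FitResult, AnnotationDesign, FeatureSelectionReport]:
    """Full two-stage pipeline: correlation pruning then effect-size refit."""
    stage1 = prune_correlated(features, corr_threshold, absolute_corr)
    fit, design, report = select_by_effect_size(
        table,
        cohorts,
        features[stage1.kept_after_correlation],
        options,
        effect_cutoff,
        trait_index,
    )
    report.kept_after_correlation = stage1.kept_after_correlation
    report.dropped_pairs = stage1.dropped_pairs
    return fit, design, report
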