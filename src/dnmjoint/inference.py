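"""Risk-gene identification by joint local false discovery rate (Jlfdr).

For trait 1 the Jlfdr of a gene is the posterior probability that the gene
is null for that trait given both traits' counts, i.e. the posterior mass on
the classes (00, 01).  Sorting Jlfdr values ascending and thresholding at
the largest rank whose running mean stays at or below the nominal level q
controls the global false discovery rate at q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em import FitResult
from .model import GeneTable, PosteriorMatrix

__all__ = ["jlfdr", "fdr_threshold", "run_inference", "ThresholdResult"]


def jlfdr(posterior: PosteriorMatrix, trait: int = 1) -> np.ndarray:
    """Per-gene Jlfdr for one trait from the class posterior matrix.

    Two-trait posteriors (columns 00, 10, 01, 11): trait 1 sums columns
    (00, 01); trait 2 sums (00, 10).  Single-trait posteriors: the null
    column.
    """
    posterior = np.asarray(posterior, dtype=float)
    if posterior.shape[1] == 2:
        if trait != 1:
            raise ValueError("single-trait posterior has only trait 1")
        out = posterior[:, 0]
    elif posterior.shape[1] != 4:
        raise ValueError("posterior must have 2 or 4 columns")
    elif trait == 1:
        out = posterior[:, 0] + posterior[:, 2]
    elif trait == 2:
        out = posterior[:, 0] + posterior[:, 1]
    else:
        raise ValueError(f"trait must be 1 or 2, got {trait}")
    # sums of posterior columns can exceed 1 by a rounding ulp
    return np.clip(out, 0.0, 1.0)


@dataclass
class ThresholdResult:
    threshold: float
    reject: np.ndarray
    running_fdr: np.ndarray
    n_rejected: int


def fdr_threshold(jlfdr_values: np.ndarray, q: float = 0.05) -> ThresholdResult:
    """Largest-rejection-region threshold controlling the global Fdr at q.

    Sort values ascending; the Fdr of rejecting the a smallest values is
    their running mean; the cut c is the largest a whose running mean is at
    most q; every gene with Jlfdr <= the c-th sorted value is rejected.
    Because the rejection region is {Jlfdr <= t}, ties are rejected as whole
    blocks and candidate cuts are evaluated at block boundaries, so the mean
    Jlfdr of the rejected set never exceeds q.  ``running_fdr`` is reported
    per gene in input order, at the gene's own rank.
    """
    values = np.asarray(jlfdr_values, dtype=float)
    if values.size == 0:
        raise ValueError("empty Jlfdr vector")
    if (values < 0).any() or (values > 1).any():
        raise ValueError("Jlfdr values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    running = np.cumsum(sorted_vals) / np.arange(1, values.size + 1)
    # candidate cuts lie at the end of a tie block: the region {jlfdr <= t}
    # always rejects whole blocks, so its Fdr is the running mean there
    block_end = np.ones(values.size, dtype=bool)
    block_end[:-1] = sorted_vals[:-1] != sorted_vals[1:]
    ok = np.nonzero((running <= q) & block_end)[0]
    if ok.size == 0:
        threshold = -np.inf
        reject = np.zeros(values.size, dtype=bool)
    else:
        c = ok[-1] + 1  # number of sorted values rejected
        threshold = float(sorted_vals[c - 1])
        reject = values <= threshold
    per_gene_fdr = np.empty(values.size)
    per_gene_fdr[order] = running
    return ThresholdResult(
        threshold=threshold,
        reject=reject,
        running_fdr=per_gene_fdr,
        n_rejected=int(reject.sum()),
    )


def run_inference(fit: FitResult, table: GeneTable, q: float = 0.05) -> pd.DataFrame:
    """Per-gene test table for every trait at global Fdr level ``q``.

    Returns a DataFrame sorted by trait-1 Jlfdr with one jlfdr/fdr/sig
    column triple per trait.
    """
    n_traits = 1 if fit.posterior.shape[1] == 2 else 2
    data: dict[str, np.ndarray] = {
        "gene_id": table.gene_id.astype(str),
        "mu": table.mu,
        "y1": table.y1,
    }
    if table.y2 is not None:
        data["y2"] = table.y2
    for t in range(1, n_traits + 1):
        lf = jlfdr(fit.posterior, t)
        thr = fdr_threshold(lf, q)
        data[f"jlfdr_t{t}"] = lf
        data[f"fdr_t{t}"] = thr.running_fdr
        data[f"sig_t{t}"] = thr.reject
    frame = pd.DataFrame(data)
    frame.attrs["q"] = q
    return frame.sort_values("jlfdr_t1", kind="stable").reset_index(drop=True)
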