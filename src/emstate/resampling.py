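"""Random-gene-set nulls and gene-subsampling robustness for survival signatures.

A signature's prognostic value is only meaningful relative to what random
gene sets of the same size achieve on the same cohort: many cohorts give
small logrank p-values to arbitrary sets.  ``permutation_null`` re-runs
the identical score -> best-cutoff -> logrank/Cox pipeline on random
same-size gene sets drawn from the cohort's gene universe and reports the
fraction of nulls at least as extreme as the observed signature (with the
add-one correction, so the p-value is never 0).
``bootstrap_subsignatures`` instead draws many small sub-signatures from a
fixed gene pool and summarizes how consistently they predict poor outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateCohortError, InvalidInputError, ShortageError
from .signatures import GeneSignature
from .survival import (
    DEFAULT_CUTOFF_QUANTILES,
    SurvivalCohort,
    SurvivalFit,
    evaluate_signature_survival,
)

__all__ = ["PermutationResult", "BootstrapSummary",
           "permutation_null", "bootstrap_subsignatures"]


@dataclass
class PermutationResult:
    observed: SurvivalFit
    null_stats: pd.DataFrame  # columns: hr, logrank_p
    n_perm: int
    permuted_p: float
    criterion: str


@dataclass
class BootstrapSummary:
    fits: pd.DataFrame  # columns: hr, logrank_p (one row per gene set)
    frac_hr_gt1: float
    frac_significant: float


def _signature_genes(signature: GeneSignature | Sequence[str]) -> list[str]:
    return signature.genes if isinstance(signature, GeneSignature) else list(signature)


def _evaluate_sets(
    cohort: SurvivalCohort,
    gene_sets: np.ndarray,
    subtype: str | None,
    candidates: Sequence[float],
    fixed_cutoff: float | None,
) -> pd.DataFrame:
    """Run the survival pipeline on many gene-index sets (rows).

    Identical to scoring each set with ``evaluate_signature_survival``; the
    expression frame is materialized once so each draw is a column-mean."""
    from .survival import fit_scores_survival

    sub = cohort.filter_subtype(subtype)
    expr = sub.expression.to_numpy(float)
    times = sub.patients["time"].to_numpy(float)
    events = sub.patients["event"].to_numpy(float)
    rows = []
    for idx in gene_sets:
        scores = expr[:, idx].mean(axis=1)
        try:
            fit = fit_scores_survival(scores, times, events, candidates,
                                      fixed_cutoff)
            rows.append((fit.hr, fit.logrank_p))
        except DegenerateCohortError:
            rows.append((np.nan, np.nan))
    return pd.DataFrame(rows, columns=["hr", "logrank_p"])


def permutation_null(
    cohort: SurvivalCohort,
    signature: GeneSignature | Sequence[str],
    n_perm: int = 999,
    rng_seed: int | np.random.Generator = 0,
    subtype: str | None = None,
    criterion: str = "signed",
    candidates: Sequence[float] = DEFAULT_CUTOFF_QUANTILES,
    fixed_cutoff: float | None = None,
) -> PermutationResult:
    """Random-gene-set permutation null for one signature.

    Each draw samples ``len(signature)`` genes uniformly without
    replacement from the cohort's full gene universe (the observed
    signature's genes are not excluded) and runs the identical pipeline.
    With ``criterion="signed"`` a null set counts as at least as extreme
    when its logrank p <= the observed p *and* its HR lies on the same side
    of 1 as the observed HR (the claim being direction-specific);
    ``criterion="two_sided"`` drops the HR-side condition.

    permuted_p = (1 + #extreme) / (n_perm + 1).
    """
    rng = np.random.default_rng(rng_seed)
    genes = _signature_genes(signature)
    universe = cohort.filter_subtype(subtype).genes
    if len(universe) < 10 * len(genes):
        raise InvalidInputError(
            f"gene universe ({len(universe)}) must be >= 10x signature size "
            f"({len(genes)})"
        )
    observed = evaluate_signature_survival(
        cohort, genes, subtype=subtype, candidates=candidates,
        fixed_cutoff=fixed_cutoff,
    )
    draws = np.stack(
        [rng.choice(len(universe), size=len(genes), replace=False)
         for _ in range(n_perm)]
    )
    nulls = _evaluate_sets(cohort, draws, subtype, candidates, fixed_cutoff)
    ok = nulls.dropna()
    if criterion == "signed":
        same_side = (ok["hr"] > 1) == (observed.hr > 1)
        extreme = ((ok["logrank_p"] <= observed.logrank_p) & same_side).sum()
    elif criterion == "two_sided":
        extreme = (ok["logrank_p"] <= observed.logrank_p).sum()
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    # failed draws count as non-extreme but stay in the denominator
    permuted_p = (1.0 + int(extreme)) / (n_perm + 1.0)
    return PermutationResult(
        observed=observed, null_stats=nulls, n_perm=n_perm,
        permuted_p=permuted_p, criterion=criterion,
    )


def bootstrap_subsignatures(
    cohort: SurvivalCohort,
    gene_pool: GeneSignature | Sequence[str],
    subsig_size: int = 10,
    n_sets: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    subtype: str | None = None,
    alpha: float = 0.05,
    candidates: Sequence[float] = DEFAULT_CUTOFF_QUANTILES,
) -> BootstrapSummary:
    """Gene-subsampling robustness: draw ``n_sets`` sub-signatures of
    ``subsig_size`` distinct genes from the pool, evaluate each with the
    survival pipeline, and summarize the fraction with HR > 1 and the
    fraction both significant (logrank p < alpha) and HR > 1."""
    rng = np.random.default_rng(rng_seed)
    pool = _signature_genes(gene_pool)
    if subsig_size > len(pool):
        raise ShortageError(
            f"subsig_size {subsig_size} exceeds pool size {len(pool)}"
        )
    sub = cohort.filter_subtype(subtype)
    pool_idx = np.array([sub.genes.get_loc(g) for g in pool])
    draws = np.stack(
        [pool_idx[rng.choice(len(pool), size=subsig_size, replace=False)]
         for _ in range(n_sets)]
    )
    fits = _evaluate_sets(sub, draws, None, candidates, None)
    ok = fits.dropna()
    frac_gt1 = float((ok["hr"] > 1).mean()) if len(ok) else float("nan")
    frac_sig = (
        float(((ok["hr"] > 1) & (ok["logrank_p"] < alpha)).mean())
        if len(ok) else float("nan")
    )
    return BootstrapSummary(fits=fits, frac_hr_gt1=frac_gt1, frac_significant=frac_sig)
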