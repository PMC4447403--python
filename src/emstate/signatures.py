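"""Derivation of epithelial (E), mesenchymal (M) and combined EM gene signatures.

The starting point is a clone-labelled log2 expression matrix (genes x
samples).  Genes are ranked by a two-sample comparison of E-clone versus
M-clone groups: the *effect size* is the difference of group means on the
log2 scale (a log2 fold change), and significance comes from a t-test with
a light empirical-Bayes variance moderation (each gene's pooled variance is
shrunk towards the across-gene mean variance).  The top ``n`` genes per
direction form the E and M signatures; interleaving the two gives the
combined EM signature used for survival scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    InsufficientReplicatesError,
    InvalidInputError,
    ShortageError,
)

__all__ = [
    "ExpressionMatrix",
    "DifferentialResult",
    "GeneSignature",
    "normalize_arrays",
    "derive_differential_genes",
    "rank_signature",
    "compose_em_signature",
]


@dataclass
class ExpressionMatrix:
    """Bulk log2 expression values with one group tag per sample.

    Parameters
    ----------
    values:
        ``genes x samples`` DataFrame of finite log2 intensities; the index
        holds unique gene (or probe) identifiers.
    sample_labels:
        Series mapping each sample id (column of ``values``) to its group
        tag, e.g. ``"E-clone"`` / ``"M-clone"``.
    """

    values: pd.DataFrame
    sample_labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.shape[1] == 0 or self.values.shape[0] == 0:
            raise InvalidInputError("expression matrix is empty")
        if not self.values.index.is_unique:
            raise InvalidInputError("gene ids must be unique")
        labels = self.sample_labels.reindex(self.values.columns)
        if labels.isna().any():
            missing = list(labels.index[labels.isna()])
            raise InvalidInputError(f"samples without group tag: {missing}")
        self.sample_labels = labels
        if not np.isfinite(self.values.to_numpy()).all():
            raise InvalidInputError("expression values must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> list[str]:
        return list(self.sample_labels.index[self.sample_labels == group])


@dataclass
class DifferentialResult:
    """Per-gene two-group statistics, sorted by |effect size| within the
    significant set.  Positive effect size = higher in the E group."""

    table: pd.DataFrame  # columns: effect_size, t_stat, p, p_adj, significant
    group_e: str
    group_m: str
    alpha: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


@dataclass
class GeneSignature:
    """An ordered gene list with per-gene direction tags ('E' or 'M')."""

    name: str
    members: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "direction", "rank", "effect_size"]
        )
    )

    def __post_init__(self) -> None:
        genes = list(self.members["gene"])
        if len(genes) != len(set(genes)):
            raise InvalidInputError(f"signature {self.name!r} has duplicate genes")
        for direction, sub in self.members.groupby("direction"):
            ranks = sorted(sub["rank"])
            if ranks != list(range(1, len(ranks) + 1)):
                raise InvalidInputError(
                    f"ranks not contiguous from 1 in direction {direction!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.members["gene"])

    @property
    def k_e(self) -> int:
        return int((self.members["direction"] == "E").sum())

    @property
    def k_m(self) -> int:
        return int((self.members["direction"] == "M").sum())

    def __len__(self) -> int:
        return len(self.members)


def normalize_arrays(
    matrix: ExpressionMatrix,
    reference_groups: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Central-tendency normalization, optionally followed by relative
    normalization against a reference group.

    The central-tendency step shifts each sample (array) so its median is 0,
    removing per-array intensity offsets.  When ``reference_groups`` is
    given, each gene is then re-expressed relative to the mean of the
    reference samples for that gene, so 0 means "at the reference level".
    Both steps are additive on the log2 scale and therefore preserve
    between-group differences.
    """
    centered = matrix.values - matrix.values.median(axis=0)
    if reference_groups is not None:
        ref_samples: list[str] = []
        for g in reference_groups:
            ref_samples.extend(matrix.samples_in(g))
        if not ref_samples:
            raise InvalidInputError(
                f"no samples in reference groups {list(reference_groups)!r}"
            )
        centered = centered.sub(centered[ref_samples].mean(axis=1), axis=0)
    return ExpressionMatrix(centered, matrix.sample_labels)


def derive_differential_genes(
    matrix: ExpressionMatrix,
    group_e: str,
    group_m: str,
    alpha: float = 0.01,
    prior_df: float = 4.0,
    adjust: bool = True,
) -> DifferentialResult:
    """Moderated two-sample t-test of E-group versus M-group samples.

    effect_size is mean(E) - mean(M) on the log2 scale.  The per-gene pooled
    variance ``s2`` is shrunk towards the across-gene mean variance ``s0``
    with ``prior_df`` pseudo-degrees of freedom::

        s2_tilde = (prior_df * s0 + df * s2) / (prior_df + df)

    and the t statistic uses ``df + prior_df`` degrees of freedom.  Genes
    are flagged significant at ``p_adj < alpha`` (Benjamini-Hochberg), or
    raw ``p < alpha`` when ``adjust=False``; the returned table is sorted
    with the significant set first, by decreasing |effect_size|.
    """
    cols_e = matrix.samples_in(group_e)
    cols_m = matrix.samples_in(group_m)
    if len(cols_e) < 2:
        raise InsufficientReplicatesError(
            f"group {group_e!r} has {len(cols_e)} samples; need >= 2"
        )
    if len(cols_m) < 2:
        raise InsufficientReplicatesError(
            f"group {group_m!r} has {len(cols_m)} samples; need >= 2"
        )

    xe = matrix.values[cols_e].to_numpy(float)
    xm = matrix.values[cols_m].to_numpy(float)
    n_e, n_m = xe.shape[1], xm.shape[1]
    effect = xe.mean(axis=1) - xm.mean(axis=1)

    df_resid = n_e + n_m - 2
    ss = xe.var(axis=1, ddof=1) * (n_e - 1) + xm.var(axis=1, ddof=1) * (n_m - 1)
    s2 = ss / df_resid
    s0 = float(s2.mean())
    s2_tilde = (prior_df * s0 + df_resid * s2) / (prior_df + df_resid)
    se = np.sqrt(s2_tilde * (1.0 / n_e + 1.0 / n_m))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, effect / se, 0.0)
    df_mod = df_resid + prior_df
    p = 2.0 * stats.t.sf(np.abs(t_stat), df_mod)
    p_adj = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "effect_size": effect,
            "t_stat": t_stat,
            "p": p,
            "p_adj": p_adj,
        },
        index=matrix.genes,
    )
    crit = table["p_adj"] if adjust else table["p"]
    table["significant"] = crit < alpha
    # significant set first, |effect| descending; ties by smaller p then id
    order = np.lexsort(
        (
            table.index.to_numpy(),
            table["p"].to_numpy(),
            -np.abs(table["effect_size"].to_numpy()),
            ~table["significant"].to_numpy(),
        )
    )
    table = table.iloc[order]
    return DifferentialResult(table=table, group_e=group_e, group_m=group_m, alpha=alpha)


def _take_direction(
    diff: DifferentialResult, n: int, direction: str
) -> pd.DataFrame:
    sig = diff.significant()
    if direction == "E":
        sub = sig[sig["effect_size"] > 0]
    else:
        sub = sig[sig["effect_size"] < 0]
    if len(sub) < n:
        raise ShortageError(
            f"only {len(sub)} significant {direction}-direction genes; "
            f"requested {n}"
        )
    # table is already |effect| desc / p asc / gene id; keep that order
    top = sub.iloc[:n]
    return pd.DataFrame(
        {
            "gene": top.index,
            "direction": direction,
            "rank": np.arange(1, n + 1),
            "effect_size": top["effect_size"].to_numpy(),
        }
    )


def rank_signature(
    diff: DifferentialResult, n_per_direction: int
) -> tuple[GeneSignature, GeneSignature]:
    """Top ``n`` genes by positive effect size (E signature) and by negative
    effect size (M signature), among the significant set."""
    sig_e = GeneSignature(
        name=f"E_top{n_per_direction}",
        members=_take_direction(diff, n_per_direction, "E"),
    )
    sig_m = GeneSignature(
        name=f"M_top{n_per_direction}",
        members=_take_direction(diff, n_per_direction, "M"),
    )
    return sig_e, sig_m


def compose_em_signature(
    sig_e: GeneSignature, sig_m: GeneSignature, k: int, name: str | None = None
) -> GeneSignature:
    """Combined EM signature: the top ``k`` genes of each direction (2k total)."""
    if k > len(sig_e) or k > len(sig_m):
        raise ShortageError(
            f"k={k} exceeds signature size ({len(sig_e)} E / {len(sig_m)} M)"
        )
    parts = [
        sig_e.members.nsmallest(k, "rank"),
        sig_m.members.nsmallest(k, "rank"),
    ]
    members = pd.concat(parts, ignore_index=True)
    return GeneSignature(name=name or f"EM_{2 * k}", members=members)
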