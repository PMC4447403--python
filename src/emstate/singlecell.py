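"""Single-cell qPCR preprocessing and E-M state-space analysis.

Raw Fluidigm-style plates report a quantification cycle Cq per (well,
assay); later amplification means less transcript.  Expression is made
linear against a per-assay background Cbg estimated from no-template-
control (NTC) wells::

    expression = 2 ** (Cbg - Cq)   if Cq < Cbg, else 0 (non-detected)

then normalized per gene to the maximum over single-cell wells, giving
values in [0, 1] for single cells.  Each cell is projected into the E-M
state space as (mean normalized expression over the E panel, mean over the
M panel); hybrid cells sit near the diagonal.  Group separation in that
space is tested with the cross-match test (see :mod:`emstate.crossmatch`)
and per-panel Mann-Whitney U tests; standardized PCA and Pearson
correlation summaries complete the picture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crossmatch import CrossMatchResult, crossmatch_test
from .errors import InvalidInputError, MissingAssayError, MissingBackgroundError

__all__ = [
    "E_PANEL",
    "M_PANEL",
    "CqPlate",
    "CellExpressionProfile",
    "estimate_background",
    "cq_to_expression",
    "normalize_per_gene_max",
    "project_em_state",
    "count_coexpressing",
    "crossmatch_test",
    "CrossMatchResult",
    "mann_whitney_u",
    "pca_cells",
    "correlation_matrix",
]

#: Default epithelial marker panel (10 genes).
E_PANEL: tuple[str, ...] = (
    "CDH1", "CD24", "EPCAM", "IL1B", "KRT5",
    "LCN2", "TP63", "TRAIL", "SLPI", "S100A8",
)
#: Default mesenchymal marker panel (7 genes).
M_PANEL: tuple[str, ...] = (
    "ABCA6", "DCN", "IL1R1", "PCOLCE", "WNT5A", "VIM", "ZEB2",
)

#: Global detection-limit Cq used when an assay's NTC never amplified.
DEFAULT_BACKGROUND_FALLBACK = 24.0


@dataclass
class CqPlate:
    """Raw Cq values (wells x assays) plus well and assay metadata.

    ``cq`` may contain NaN for wells with no amplification.  ``well_meta``
    must carry boolean ``is_ntc`` and integer ``n_cells`` (1 for single
    cells, e.g. 100 for pooled wells) columns, and may carry arbitrary
    annotation columns (cell line, growth condition, sort gate).
    ``assay_meta`` maps each assay to a panel label ('E', 'M' or 'other').
    """

    cq: pd.DataFrame
    well_meta: pd.DataFrame
    assay_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.cq.index.equals(self.well_meta.index):
            self.well_meta = self.well_meta.reindex(self.cq.index)
            if self.well_meta.isna().all(axis=1).any():
                raise InvalidInputError("well metadata missing for some wells")
        for col in ("is_ntc", "n_cells"):
            if col not in self.well_meta.columns:
                raise InvalidInputError(f"well_meta needs a {col!r} column")
        missing = [a for a in self.cq.columns if a not in self.assay_meta.index]
        if missing:
            raise InvalidInputError(f"assays without metadata: {missing}")
        vals = self.cq.to_numpy(float)
        if np.isfinite(vals).any() and np.nanmin(vals) <= 0:
            raise InvalidInputError("Cq values must be > 0 where present")

    @property
    def assays(self) -> pd.Index:
        return self.cq.columns

    @property
    def ntc_wells(self) -> pd.Index:
        return self.well_meta.index[self.well_meta["is_ntc"].astype(bool)]

    @property
    def single_cell_wells(self) -> pd.Index:
        m = (~self.well_meta["is_ntc"].astype(bool)) & (self.well_meta["n_cells"] == 1)
        return self.well_meta.index[m]


@dataclass
class CellExpressionProfile:
    """Background, linear and max-normalized expression for one plate."""

    background: pd.Series  # per-assay Cbg
    linear: pd.DataFrame  # wells x assays, >= 0; non-detected entries 0
    normalized: pd.DataFrame  # linear / per-gene single-cell max
    well_meta: pd.DataFrame

    def single_cells(self) -> pd.DataFrame:
        m = (~self.well_meta["is_ntc"].astype(bool)) & (self.well_meta["n_cells"] == 1)
        return self.normalized.loc[m]


def estimate_background(
    plate: CqPlate, fallback: float | None = DEFAULT_BACKGROUND_FALLBACK
) -> pd.Series:
    """Per-assay background Cbg = minimum Cq over that assay's NTC wells.

    Assays whose NTC wells never amplified (all NaN) receive the global
    ``fallback`` detection limit.  Taking the minimum is conservative:
    any amplification at or after the earliest NTC signal is treated as
    background.
    """
    ntc = plate.ntc_wells
    if len(ntc) == 0:
        if fallback is None:
            raise MissingBackgroundError(
                "plate has no NTC wells and no fallback background configured"
            )
        return pd.Series(float(fallback), index=plate.assays, name="c_bg")
    mins = plate.cq.loc[ntc].min(axis=0, skipna=True)
    if mins.isna().any():
        if fallback is None:
            raise MissingBackgroundError(
                f"no NTC amplification for assays {list(mins.index[mins.isna()])} "
                "and no fallback configured"
            )
        mins = mins.fillna(float(fallback))
    return mins.rename("c_bg")


def cq_to_expression(plate: CqPlate, background: pd.Series) -> pd.DataFrame:
    """Linear expression 2**(Cbg - Cq); non-detection (Cq >= Cbg or missing Cq)
    maps to exactly 0."""
    missing = [a for a in plate.assays if a not in background.index]
    if missing:
        raise MissingBackgroundError(f"background undefined for assays {missing}")
    cq = plate.cq.to_numpy(float)
    if np.nanmin(cq, initial=np.inf) < 0:
        raise InvalidInputError("negative Cq value")
    bg = background.reindex(plate.assays).to_numpy(float)
    with np.errstate(invalid="ignore"):
        expr = np.power(2.0, bg[None, :] - cq)
        expr[~(cq < bg[None, :])] = 0.0  # Cq >= Cbg and NaN both -> 0
    return pd.DataFrame(expr, index=plate.cq.index, columns=plate.assays)


def normalize_per_gene_max(
    linear: pd.DataFrame, single_cell_mask: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Divide each gene by its maximum over single-cell wells only.

    Pooled (e.g. 100-cell) wells are excluded from the maximum but divided
    by the same factor, so they may exceed 1.  A gene undetected in every
    single cell stays all zeros.
    """
    mask = np.asarray(single_cell_mask, bool)
    if mask.sum() == 0:
        raise InvalidInputError("need >= 1 single-cell well for normalization")
    gmax = linear.loc[mask].max(axis=0)
    denom = gmax.replace(0.0, 1.0)  # all-zero gene: leave zeros untouched
    return linear.div(denom, axis=1)


def process_plate(
    plate: CqPlate, fallback: float | None = DEFAULT_BACKGROUND_FALLBACK
) -> CellExpressionProfile:
    """Full preprocessing chain: background -> linear -> max-normalized."""
    bg = estimate_background(plate, fallback=fallback)
    linear = cq_to_expression(plate, bg)
    sc = plate.cq.index.isin(plate.single_cell_wells)
    normalized = normalize_per_gene_max(linear, sc)
    return CellExpressionProfile(
        background=bg, linear=linear, normalized=normalized,
        well_meta=plate.well_meta,
    )


def project_em_state(
    normalized: pd.DataFrame,
    e_panel: Sequence[str] = E_PANEL,
    m_panel: Sequence[str] = M_PANEL,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Project each cell to (mean_e, mean_m): unweighted panel means of
    normalized expression.  Returns a frame with columns ``mean_e``,
    ``mean_m`` and, when ``groups`` is given, ``group``."""
    e_panel, m_panel = list(e_panel), list(m_panel)
    if not e_panel or not m_panel:
        raise InvalidInputError("panels must be non-empty")
    if set(e_panel) & set(m_panel):
        raise InvalidInputError("E and M panels must be disjoint")
    absent = [g for g in e_panel + m_panel if g not in normalized.columns]
    if absent:
        raise MissingAssayError(f"panel genes missing from plate: {absent}")
    out = pd.DataFrame(
        {
            "mean_e": normalized[e_panel].mean(axis=1),
            "mean_m": normalized[m_panel].mean(axis=1),
        },
        index=normalized.index,
    )
    if groups is not None:
        out["group"] = groups.reindex(out.index)
    return out


def count_coexpressing(
    normalized: pd.DataFrame,
    e_panel: Sequence[str] = E_PANEL,
    m_panel: Sequence[str] = M_PANEL,
) -> dict:
    """Detection-based cell classes.

    A gene is detected in a cell when its normalized value is > 0.  A cell
    is *co-expressing* when >= 1 E-panel and >= 1 M-panel gene are
    detected, *exclusive E/M* when only one panel is detected, *silent*
    when neither is.  Also reports per-gene detection counts.
    """
    e_det = (normalized[list(e_panel)] > 0).sum(axis=1)
    m_det = (normalized[list(m_panel)] > 0).sum(axis=1)
    return {
        "coexpressing": int(((e_det > 0) & (m_det > 0)).sum()),
        "exclusive_e": int(((e_det > 0) & (m_det == 0)).sum()),
        "exclusive_m": int(((e_det == 0) & (m_det > 0)).sum()),
        "silent": int(((e_det == 0) & (m_det == 0)).sum()),
        "n_cells": int(len(normalized)),
        "per_gene_detection": (normalized[list(e_panel) + list(m_panel)] > 0)
        .sum(axis=0)
        .astype(int)
        .to_dict(),
    }


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p-value when both samples have <= ``exact_max_n`` observations
    and there are no ties; tie-corrected normal approximation otherwise.
    Returns (U statistic of ``x``, p).  If every value across both samples
    is identical the test is vacuous: p = 1 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1")
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact"
        if (len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pca_cells(
    profiles: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Standardized PCA of cells x genes expression.

    Each gene is centered to mean 0 and scaled to variance 1 (zero-variance
    genes are dropped with a warning), then decomposed by SVD.  The sign of
    each component is fixed so its largest-magnitude loading is positive.
    Returns (scores per cell, loadings per gene, variance fractions).
    """
    if profiles.shape[0] < 2:
        raise InvalidInputError("need >= 2 cells for PCA")
    sd = profiles.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance genes before PCA"
        )
    if keep.sum() < 2:
        raise InvalidInputError("need >= 2 genes with nonzero variance")
    x = profiles.loc[:, keep]
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    from sklearn.decomposition import PCA

    k = n_components or min(z.shape[0] - 1, z.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T  # genes x components
    # deterministic sign: largest-|loading| gene positive per component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return (
        pd.DataFrame(scores, index=profiles.index, columns=comp_names),
        pd.DataFrame(loadings, index=x.columns, columns=comp_names),
        pca.explained_variance_ratio_,
    )


def correlation_matrix(
    data: pd.DataFrame, blocks: pd.Series | None = None
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation between observations (rows) across the
    feature columns.  Zero-variance observations yield NaN against every
    partner.  With ``blocks``, also returns the block-averaged correlation
    (mean r within each pair of annotation blocks, diagonal excluding
    self-correlations)."""
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise InvalidInputError("need >= 2 observations and >= 2 features")
    r = data.T.corr(method="pearson")
    if blocks is None:
        return r
    blocks = blocks.reindex(data.index)
    labels = blocks.unique()
    avg = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for a in labels:
        for b in labels:
            sub = r.loc[blocks == a, blocks == b].to_numpy(float).copy()
            if a == b:
                np.fill_diagonal(sub, np.nan)
            avg.loc[a, b] = np.nanmean(sub)
    return r, avg
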