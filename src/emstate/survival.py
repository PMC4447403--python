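"""Signature-based survival analysis.

Patients are scored by the mean log2 expression of a gene signature,
dichotomized at the best of a small set of candidate quantiles (median,
tertiles, quartiles, as a clinical best-cutoff scan would do), and the
high- versus low-scoring groups are compared with a two-group logrank test
and a single-binary-covariate Cox proportional-hazards model (Breslow tie
handling).  Marker-probe cutoffs on ESR1, MKI67 and HER2 assign each
patient one of four clinical subtypes (luminal A, luminal B, basal, HER2).

The logrank statistic and the scalar Cox fit are implemented directly on
numpy arrays so that resampling procedures can run tens of thousands of
fits; unit tests cross-check both against lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateCohortError,
    InvalidInputError,
    NoOverlapError,
)
from .signatures import GeneSignature

__all__ = [
    "SUBTYPES",
    "DEFAULT_PROBE_CUTOFFS",
    "DEFAULT_CUTOFF_QUANTILES",
    "SurvivalCohort",
    "SurvivalFit",
    "classify_subtype",
    "score_signature",
    "select_best_cutoff",
    "kaplan_meier",
    "logrank_test",
    "cox_hr",
    "evaluate_signature_survival",
]

SUBTYPES = ("luminalA", "luminalB", "basal", "HER2")

#: Linear-scale marker probe cutoffs (ESR1 probe 500, MKI67 probe 470,
#: HER2 probe 4800); "positive" means strictly greater than the cutoff.
DEFAULT_PROBE_CUTOFFS: Mapping[str, float] = {"esr": 500.0, "mki67": 470.0, "her2": 4800.0}

#: Candidate dichotomization quantiles: quartiles, tertiles and the median.
DEFAULT_CUTOFF_QUANTILES: tuple[float, ...] = (0.25, 1.0 / 3.0, 0.5, 2.0 / 3.0, 0.75)


def classify_subtype(
    esr: float | None,
    mki67: float | None,
    her2: float | None,
    cutoffs: Mapping[str, float] = DEFAULT_PROBE_CUTOFFS,
) -> str:
    """Clinical subtype from three marker probes.

    ESR+/HER2-/MKI67-low -> luminal A; ESR+ with either HER2+ or MKI67-high
    -> luminal B; ESR-/HER2- -> basal; ESR-/HER2+ -> HER2.  A missing probe
    yields ``"unclassified"`` with a warning.
    """
    probes = {"esr": esr, "mki67": mki67, "her2": her2}
    for name, v in probes.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            warnings.warn(f"missing {name} probe; patient unclassified")
            return "unclassified"
        if v < 0:
            raise InvalidInputError(f"{name} probe value must be >= 0, got {v}")
    esr_pos = esr > cutoffs["esr"]
    her2_pos = her2 > cutoffs["her2"]
    ki_high = mki67 > cutoffs["mki67"]
    if esr_pos:
        if her2_pos or ki_high:
            return "luminalB"
        return "luminalA"
    return "HER2" if her2_pos else "basal"


@dataclass
class SurvivalCohort:
    """Patient-level survival data plus a patients x genes expression frame.

    ``patients`` must carry columns ``time`` (months, > 0) and ``event``
    (1 = death/relapse, 0 = censored) and may carry ``esr_probe``,
    ``mki67_probe``, ``her2_probe``; ``expression`` is indexed by the same
    patient ids with gene columns (log2 scale).
    """

    patients: pd.DataFrame
    expression: pd.DataFrame
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if len(self.patients) == 0:
            raise InvalidInputError("cohort has no patients")
        if (self.patients["time"] <= 0).any():
            raise InvalidInputError("follow-up times must be > 0")
        if not self.patients["event"].isin([0, 1]).all():
            raise InvalidInputError("event flags must be 0 or 1")
        if not self.patients.index.equals(self.expression.index):
            self.expression = self.expression.reindex(self.patients.index)
            if self.expression.isna().any().any():
                raise InvalidInputError("expression missing for some patients")
        if "subtype" not in self.patients.columns:
            self.patients = self.patients.assign(subtype=self.assign_subtypes())

    def assign_subtypes(
        self, cutoffs: Mapping[str, float] = DEFAULT_PROBE_CUTOFFS
    ) -> pd.Series:
        cols = {"esr_probe", "mki67_probe", "her2_probe"}
        if not cols.issubset(self.patients.columns):
            return pd.Series("unclassified", index=self.patients.index)
        return pd.Series(
            [
                classify_subtype(r.esr_probe, r.mki67_probe, r.her2_probe, cutoffs)
                for r in self.patients.itertuples()
            ],
            index=self.patients.index,
        )

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns

    def filter_subtype(self, subtype: str | None) -> "SurvivalCohort":
        if subtype is None or subtype == "all":
            return self
        mask = self.patients["subtype"] == subtype
        if mask.sum() == 0:
            raise DegenerateCohortError(f"no patients with subtype {subtype!r}")
        return SurvivalCohort(
            self.patients[mask], self.expression[mask], endpoint=self.endpoint
        )


@dataclass
class SurvivalFit:
    """High-vs-low comparison summary for one signature on one cohort."""

    hr: float
    ci_low: float
    ci_high: float
    logrank_chi2: float
    logrank_p: float
    cutoff: float
    cutoff_value: float
    n_high: int
    n_low: int
    flagged: bool = False  # separation guard tripped

    def as_dict(self) -> dict:
        return {
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "cutoff": self.cutoff,
            "cutoff_value": self.cutoff_value,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "flagged": self.flagged,
        }


def score_signature(
    expression: pd.DataFrame | pd.Series | Mapping[str, float],
    signature: GeneSignature | Sequence[str],
) -> pd.Series | float:
    """Mean log2 expression over the signature genes present in the profile.

    Accepts a single profile (Series/dict -> float) or a patients x genes
    frame (-> Series).  Missing signature genes are dropped with a warning;
    zero overlap raises :class:`NoOverlapError`.
    """
    genes = signature.genes if isinstance(signature, GeneSignature) else list(signature)
    if isinstance(expression, Mapping) and not isinstance(expression, pd.Series):
        expression = pd.Series(expression)
    if isinstance(expression, pd.Series):
        present = [g for g in genes if g in expression.index]
        _warn_missing(genes, present)
        return float(expression[present].mean())
    present = [g for g in genes if g in expression.columns]
    _warn_missing(genes, present)
    return expression[present].mean(axis=1)


def _warn_missing(genes: Sequence[str], present: Sequence[str]) -> None:
    if not present:
        raise NoOverlapError("no signature gene present in the expression profile")
    n_missing = len(genes) - len(present)
    if n_missing:
        warnings.warn(f"{n_missing} of {len(genes)} signature genes missing; "
                      f"score uses the {len(present)} present")


# ---------------------------------------------------------------------------
# core estimators (numpy fast paths, cross-checked against lifelines)
# ---------------------------------------------------------------------------


def _risk_table(times: np.ndarray, events: np.ndarray, groups: np.ndarray):
    """Shared risk-set bookkeeping for logrank/Cox.

    Returns, per distinct event time: total deaths ``d``, group-1 deaths
    ``d1``, at-risk counts ``n`` and ``n1``.
    """
    order = np.argsort(times, kind="mergesort")
    t, e, g = times[order], events[order].astype(bool), groups[order].astype(bool)
    event_times, first_idx = np.unique(t[e], return_index=True)
    n_total = len(t)
    # at-risk counts just before each event time
    n_at = n_total - np.searchsorted(t, event_times, side="left")
    n1_cum = np.cumsum(g)
    total_g1 = n1_cum[-1]
    idx = np.searchsorted(t, event_times, side="left")
    n1_at = total_g1 - np.where(idx > 0, n1_cum[idx - 1], 0)
    # deaths per event time
    d = np.zeros(len(event_times))
    d1 = np.zeros(len(event_times))
    pos = np.searchsorted(event_times, t[e])
    np.add.at(d, pos, 1.0)
    np.add.at(d1, pos, g[e].astype(float))
    return d, d1, n_at.astype(float), n1_at.astype(float)


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group logrank test: (chi2, p) with 1 degree of freedom.

    Observed minus expected group-B deaths over the shared risk sets, with
    the hypergeometric variance at each distinct event time.
    """
    times = np.concatenate([np.asarray(times_a, float), np.asarray(times_b, float)])
    events = np.concatenate([np.asarray(events_a, float), np.asarray(events_b, float)])
    groups = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    if events.sum() == 0:
        raise DegenerateCohortError("logrank undefined with zero events")
    d, d1, n, n1 = _risk_table(times, events, groups)
    exp1 = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    var = np.where(n > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    chi2 = float((d1 - exp1).sum() ** 2 / v)
    return chi2, float(stats.chi2.sf(chi2, 1))


def cox_hr(
    groups: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
    beta_cap: float = 15.0,
) -> tuple[float, float, float, bool]:
    """Cox proportional-hazards fit for a single binary covariate.

    Newton iteration on the Breslow partial likelihood; returns
    ``(hr, ci_low, ci_high, flagged)`` where ``flagged`` marks a divergence
    guard (complete separation -> coefficient capped, infinite-HR surrogate).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    groups = np.asarray(groups, float)
    if groups.min() == groups.max():
        raise DegenerateCohortError("both groups must be non-empty")
    if events.sum() == 0:
        raise DegenerateCohortError("Cox fit undefined with zero events")
    d, d1, n, n1 = _risk_table(times, events, groups)
    n0 = n - n1
    s1 = d1.sum()  # events in group 1
    beta = 0.0
    flagged = False
    for _ in range(max_iter):
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        mu = n1 * eb / denom  # E[x | risk set] under beta
        grad = s1 - float((d * mu).sum())
        hess = -float((d * mu * (1 - mu)).sum())
        if hess == 0.0:
            flagged = True
            break
        step = -grad / hess
        beta_new = beta + np.clip(step, -2.0, 2.0)
        if abs(beta_new) > beta_cap:
            beta = np.sign(beta_new) * beta_cap
            flagged = True
            break
        if abs(beta_new - beta) < tol:
            beta = beta_new
            break
        beta = beta_new
    eb = np.exp(beta)
    denom = n0 + n1 * eb
    mu = n1 * eb / denom
    info = float((d * mu * (1 - mu)).sum())
    se = np.inf if info <= 0 else 1.0 / np.sqrt(info)
    z = stats.norm.ppf(0.975)
    hr = float(np.exp(beta))
    return hr, float(np.exp(beta - z * se)), float(np.exp(beta + z * se)), flagged


def kaplan_meier(
    times: np.ndarray, events: np.ndarray
) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step table with columns ``time``, ``survival`` and
    ``at_risk``; survival drops only at event times, is right-continuous,
    non-increasing, and starts at S(0) = 1.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    if len(times) == 0:
        raise InvalidInputError("empty input to kaplan_meier")
    if (times <= 0).any():
        raise InvalidInputError("times must be > 0")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(float),
         "survival": surv.to_numpy(float),
         "at_risk": at_risk.to_numpy(float)}
    )


def select_best_cutoff(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    candidates: Sequence[float] = DEFAULT_CUTOFF_QUANTILES,
    min_group: int = 2,
) -> tuple[float, float, np.ndarray]:
    """Best-cutoff scan over candidate quantiles of the score.

    For each candidate quantile the cohort is split into high (score
    strictly greater than the quantile value) versus low, and the logrank p
    is evaluated; the quantile with the smallest p wins (ties broken by
    proximity to the median, then by the smaller quantile, for
    determinism).  Candidates leaving fewer than ``min_group`` patients on
    either side are skipped; if every candidate is skipped the cohort is
    degenerate.

    Returns ``(quantile, cutoff_value, high_mask)``.
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    best = None
    for q in candidates:
        cut = float(np.quantile(scores, q))
        high = scores > cut
        n_hi = int(high.sum())
        n_lo = len(scores) - n_hi
        if n_hi < min_group or n_lo < min_group:
            continue
        try:
            _, p = logrank_test(times[~high], events[~high], times[high], events[high])
        except DegenerateCohortError:
            continue
        key = (p, abs(q - 0.5), q)
        if best is None or key < best[0]:
            best = (key, q, cut, high)
    if best is None:
        raise DegenerateCohortError("no candidate cutoff yields two usable groups")
    _, q, cut, high = best
    return q, cut, high


def fit_scores_survival(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    candidates: Sequence[float] = DEFAULT_CUTOFF_QUANTILES,
    fixed_cutoff: float | None = None,
) -> SurvivalFit:
    """Dichotomize scores and fit logrank + Cox (high vs low).

    The shared core behind :func:`evaluate_signature_survival` and the
    resampling engines; ``fixed_cutoff`` (a quantile) bypasses the
    best-cutoff scan.
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    if fixed_cutoff is not None:
        cut = float(np.quantile(scores, fixed_cutoff))
        high = scores > cut
        if high.sum() == 0 or (~high).sum() == 0:
            raise DegenerateCohortError("fixed cutoff yields an empty group")
        q = float(fixed_cutoff)
    else:
        q, cut, high = select_best_cutoff(scores, times, events, candidates)
    chi2, p = logrank_test(times[~high], events[~high], times[high], events[high])
    hr, lo, hi, flagged = cox_hr(high.astype(float), times, events)
    return SurvivalFit(
        hr=hr, ci_low=lo, ci_high=hi,
        logrank_chi2=chi2, logrank_p=p,
        cutoff=q, cutoff_value=cut,
        n_high=int(high.sum()), n_low=int((~high).sum()),
        flagged=flagged,
    )


def evaluate_signature_survival(
    cohort: SurvivalCohort,
    signature: GeneSignature | Sequence[str],
    subtype: str | None = None,
    candidates: Sequence[float] = DEFAULT_CUTOFF_QUANTILES,
    fixed_cutoff: float | None = None,
) -> SurvivalFit:
    """Full pipeline: score -> dichotomize -> logrank + Cox (high vs low).

    The hazard ratio is oriented high-expression versus low-expression, so
    HR > 1 means high signature expression predicts poor outcome.
    """
    sub = cohort.filter_subtype(subtype)
    scores = np.asarray(score_signature(sub.expression, signature), float)
    times = sub.patients["time"].to_numpy(float)
    events = sub.patients["event"].to_numpy(float)
    return fit_scores_survival(scores, times, events, candidates, fixed_cutoff)
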