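"""Synthetic data generators with known ground truth.

Three generators emulate the three data modalities the pipeline consumes:

* ``generate_clone_matrix`` — a clone-labelled bulk log2 expression matrix
  (6 epithelial vs 4 mesenchymal samples by default) with planted E-up and
  M-up gene sets, per-sample array offsets, and i.i.d. Normal noise.
* ``generate_cohort`` — a patient cohort whose hazard is log-linear in a
  latent score expressed by the signature genes, with exponential survival
  times, uniform censoring calibrated to a target fraction, and marker
  probes (ESR1/MKI67/HER2) populating four clinical subtypes around the
  cutoffs 500/470/4800.
* ``generate_cq_plate`` — a Fluidigm-style Cq plate with three latent cell
  states (E, M, hybrid E/M), per-gene expression offsets, logistic
  detection dropout, Cq measurement noise, NTC wells and 100-cell pools.

All generators are pure functions of (spec, seed): the same inputs always
return identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InvalidSpecError
from .signatures import ExpressionMatrix, GeneSignature
from .singlecell import E_PANEL, M_PANEL, CqPlate
from .survival import SurvivalCohort

__all__ = [
    "SyntheticSpec",
    "generate_clone_matrix",
    "generate_cohort",
    "generate_two_group_cohort",
    "generate_cq_plate",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the study layout: 6 E-clone vs 4 M-clone arrays with
    30 planted genes per direction and a +3 log2 shift; cohorts with
    log-hazard ``beta`` per unit latent score and ~20% censoring; 48-well
    plates of 24 E + 24 M single cells with NTC wells and 100-cell pools.
    """

    seed: int = 0
    # clone expression matrix
    n_genes: int = 1000
    n_e_samples: int = 6
    n_m_samples: int = 4
    n_planted: int = 30
    effect_size: float = 3.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    sample_offset_sd: float = 0.3
    # survival cohort
    n_patients: int = 300
    n_cohort_genes: int = 300
    beta: float = 0.7
    score_loading: float = 1.0
    expression_noise_sd: float = 1.0
    baseline_hazard: float = 0.02
    censor_frac: float = 0.2
    subtype_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "luminalA": 0.35, "luminalB": 0.30, "basal": 0.20, "HER2": 0.15,
        }
    )
    # single-cell Cq plate
    n_cells_per_state: Mapping[str, int] = field(
        default_factory=lambda: {"E": 24, "M": 24, "hybrid": 0}
    )
    n_pooled_per_state: int = 2
    n_ntc: int = 4
    cbg: float = 24.0
    cq_noise_sd: float = 0.5
    dropout_slope: float = 1.5
    dropout_midpoint: float = 1.0  # log2 latent at 50% detection
    cell_sd: float = 0.75  # per-cell log2 spread around the archetype
    gene_offset_sd: float = 0.5  # fixed per-gene log2 expression offsets
    archetype_means: Mapping[str, tuple[float, float]] = field(
        # state -> (E-panel latent mean, M-panel latent mean), linear units;
        # hybrid = 0.5x the pure-state "on" level on both panels.  E cells
        # carry low-level M expression (promiscuous, near the detection
        # limit) while M cells are nearly silent on the E panel, mirroring
        # the asymmetry seen in single-cell qPCR of these cell types.
        default_factory=lambda: {
            "E": (64.0, 1.0), "M": (0.25, 64.0), "hybrid": (32.0, 32.0),
        }
    )

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.cq_noise_sd < 0:
            raise InvalidSpecError("noise sd must be >= 0")
        if not (0 <= self.censor_frac < 1):
            raise InvalidSpecError("censor_frac must be in [0, 1)")
        if self.n_genes < 2 * self.n_planted:
            raise InvalidSpecError("n_genes must be >= 2 x planted count")
        for state, (e, m) in self.archetype_means.items():
            if e < 0 or m < 0:
                raise InvalidSpecError(f"archetype {state!r} has negative mean")


def generate_clone_matrix(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Two-group clone matrix with planted E-up/M-up genes.

    Values are ``baseline_mean`` + Normal(0, noise_sd) per (gene, sample),
    plus a per-sample array offset; the first ``n_planted`` genes gain
    ``effect_size`` in E samples, the next ``n_planted`` gain it in M
    samples.  Returns the matrix and the planted truth sets.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_s = spec.n_e_samples + spec.n_m_samples
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    samples = [f"E{i + 1}" for i in range(spec.n_e_samples)] + [
        f"M{i + 1}" for i in range(spec.n_m_samples)
    ]
    x = rng.normal(spec.baseline_mean, spec.noise_sd, size=(spec.n_genes, n_s))
    e_up = genes[: spec.n_planted]
    m_up = genes[spec.n_planted : 2 * spec.n_planted]
    x[: spec.n_planted, : spec.n_e_samples] += spec.effect_size
    x[spec.n_planted : 2 * spec.n_planted, spec.n_e_samples :] += spec.effect_size
    x += rng.normal(0, spec.sample_offset_sd, size=n_s)[None, :]
    labels = pd.Series(
        ["E-clone"] * spec.n_e_samples + ["M-clone"] * spec.n_m_samples,
        index=samples,
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=samples), labels
    )
    return matrix, {"e_up": e_up, "m_up": m_up}


def _uniform_censor_max(hazards: np.ndarray, censor_frac: float) -> float:
    """Horizon c of U(0, c) censoring achieving the target expected censored
    fraction for exponential event times with the given per-patient hazards
    (averaged exactly over the hazard vector, so hazard heterogeneity does
    not bias the realized fraction)."""
    if censor_frac <= 0:
        return np.inf
    hazards = np.asarray(hazards, float)
    hbar = float(hazards.mean())

    def frac(c: float) -> float:
        lc = hazards * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc)) - censor_frac

    return float(optimize.brentq(frac, 1e-9 / hbar, 1e7 / hbar))


def _draw_probes(rng: np.random.Generator, subtype: str) -> tuple[float, float, float]:
    """Marker probe values landing the patient in the requested subtype
    (strict-greater positivity at cutoffs 500 / 470 / 4800)."""
    esr_pos = rng.uniform(600, 3000)
    esr_neg = rng.uniform(10, 400)
    ki_hi = rng.uniform(520, 2000)
    ki_lo = rng.uniform(50, 420)
    her2_pos = rng.uniform(5200, 20000)
    her2_neg = rng.uniform(200, 4600)
    if subtype == "luminalA":
        return esr_pos, ki_lo, her2_neg
    if subtype == "luminalB":
        # ESR+/HER2- with high MKI67, or ESR+/HER2+ (either route)
        if rng.random() < 0.5:
            return esr_pos, ki_hi, her2_neg
        return esr_pos, rng.uniform(50, 2000), her2_pos
    if subtype == "basal":
        return esr_neg, rng.uniform(50, 2000), her2_neg
    if subtype == "HER2":
        return esr_neg, rng.uniform(50, 2000), her2_pos
    raise InvalidSpecError(f"unknown subtype {subtype!r}")


def generate_cohort(
    spec: SyntheticSpec,
    signature: GeneSignature | Sequence[str] | None = None,
    seed: int | None = None,
) -> tuple[SurvivalCohort, dict]:
    """Patient cohort with signature-driven hazard.

    A latent score s ~ N(0,1) per patient drives both the signature genes'
    expression (``score_loading * s`` + noise around a log2 baseline) and
    the hazard ``baseline_hazard * exp(beta * s)``; survival times are
    exponential, censoring is uniform on a horizon calibrated so the
    expected censored fraction matches ``censor_frac``.  Non-signature
    genes are independent noise.  Returns the cohort and the truth
    (latent scores, beta, censor horizon).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genes = [f"c{i:05d}" for i in range(spec.n_cohort_genes)]
    if signature is None:
        sig_genes: list[str] = genes[: 10]
    else:
        sig_genes = (
            signature.genes if isinstance(signature, GeneSignature) else list(signature)
        )
        unknown = [g for g in sig_genes if g not in genes]
        if unknown and len(unknown) == len(sig_genes):
            raise InvalidSpecError(
                "signature genes entirely outside the generated universe"
            )
    if not sig_genes:
        raise InvalidSpecError("empty signature")
    n = spec.n_patients
    s = rng.normal(0, 1, n)
    expr = pd.DataFrame(
        rng.normal(spec.baseline_mean, spec.expression_noise_sd,
                   size=(n, len(genes))),
        index=[f"p{i:05d}" for i in range(n)],
        columns=genes,
    )
    for g in sig_genes:
        if g in expr.columns:
            expr[g] += spec.score_loading * s

    hazard = spec.baseline_hazard * np.exp(spec.beta * s)
    t_event = rng.exponential(1.0 / hazard)
    c_max = _uniform_censor_max(hazard, spec.censor_frac)
    c = rng.uniform(0, c_max, n) if np.isfinite(c_max) else np.full(n, np.inf)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    time = np.maximum(time, 1e-6)  # guard: strictly positive follow-up

    subs = list(spec.subtype_probs)
    probs = np.array([spec.subtype_probs[k] for k in subs], float)
    labels = rng.choice(subs, size=n, p=probs / probs.sum())
    probes = np.array([_draw_probes(rng, lab) for lab in labels])
    patients = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "esr_probe": probes[:, 0],
            "mki67_probe": probes[:, 1],
            "her2_probe": probes[:, 2],
        },
        index=expr.index,
    )
    cohort = SurvivalCohort(patients, expr)
    truth = {
        "score": pd.Series(s, index=expr.index),
        "beta": spec.beta,
        "signature_genes": sig_genes,
        "censor_horizon": c_max,
    }
    return cohort, truth


def generate_two_group_cohort(
    n: int,
    true_hr: float,
    censor_frac: float = 0.2,
    baseline_hazard: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary-covariate cohort with a known hazard ratio.

    Half the patients carry the covariate; their hazard is ``true_hr``
    times the baseline.  Exponential times, exponential censoring whose
    rate targets the requested censored fraction.  Returns
    ``(groups, times, events)`` — the direct parameter-recovery fixture
    for the Cox estimator.
    """
    rng = np.random.default_rng(seed)
    groups = (np.arange(n) % 2).astype(float)
    hazard = baseline_hazard * np.power(true_hr, groups)
    t_event = rng.exponential(1.0 / hazard)
    if censor_frac > 0:
        mu = hazard.mean() * censor_frac / (1.0 - censor_frac)
        c = rng.exponential(1.0 / mu, n)
    else:
        c = np.full(n, np.inf)
    times = np.maximum(np.minimum(t_event, c), 1e-9)
    events = (t_event <= c).astype(float)
    return groups, times, events


def generate_cq_plate(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[CqPlate, pd.Series]:
    """Cq plate with three latent cell states and detection dropout.

    Per cell and gene the latent log2 expression is the state archetype's
    panel level plus a fixed per-gene offset and per-cell Normal spread;
    detection is Bernoulli with logistic probability in the latent log2
    value; detected wells report ``Cq = cbg - log2(latent) + noise`` and
    anything at or past the background (or a dropout) is recorded as no
    amplification (NaN).  100-cell pools sum 100 latent draws; NTC wells
    are silent except for rare late signals past the background.  Returns
    the plate and the per-well true state (NTC wells labelled "NTC").
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    assays = list(E_PANEL) + list(M_PANEL)
    panel = ["E"] * len(E_PANEL) + ["M"] * len(M_PANEL)
    gene_offset = rng.normal(0, spec.gene_offset_sd, len(assays))

    def latent_log2(state: str, n_draw: int) -> np.ndarray:
        e_mean, m_mean = spec.archetype_means[state]
        base = np.where(
            np.array(panel) == "E", np.log2(e_mean), np.log2(m_mean)
        )
        return (
            base[None, :]
            + gene_offset[None, :]
            + rng.normal(0, spec.cell_sd, size=(n_draw, len(assays)))
        )

    rows, meta_rows, states = [], [], []
    widx = 0

    def add_well(cq_row, state, n_cells, is_ntc):
        nonlocal widx
        rows.append(cq_row)
        meta_rows.append(
            {"well": f"w{widx:03d}", "state": state, "n_cells": n_cells,
             "is_ntc": is_ntc}
        )
        states.append("NTC" if is_ntc else state)
        widx += 1

    for state, n_cells in spec.n_cells_per_state.items():
        if n_cells == 0:
            continue
        log2lat = latent_log2(state, n_cells)
        p_det = 1.0 / (
            1.0 + np.exp(-spec.dropout_slope * (log2lat - spec.dropout_midpoint))
        )
        detected = rng.random(log2lat.shape) < p_det
        cq = spec.cbg - log2lat + rng.normal(0, spec.cq_noise_sd, log2lat.shape)
        cq[~detected] = np.nan
        cq[cq >= spec.cbg] = np.nan  # at/past background -> no amplification
        for r in range(n_cells):
            add_well(cq[r], state, 1, False)

    for state in spec.n_cells_per_state:
        if spec.n_cells_per_state[state] == 0:
            continue
        for _ in range(spec.n_pooled_per_state):
            lin = np.power(2.0, latent_log2(state, 100)).sum(axis=0)
            cq = (
                spec.cbg - np.log2(lin)
                + rng.normal(0, spec.cq_noise_sd, len(assays))
            )
            cq[cq >= spec.cbg] = np.nan
            add_well(cq, state, 100, False)

    for _ in range(spec.n_ntc):
        cq = np.full(len(assays), np.nan)
        late = rng.random(len(assays)) < 0.05
        cq[late] = spec.cbg + rng.uniform(0.0, 2.0, int(late.sum()))
        add_well(cq, "NTC", 0, True)

    meta = pd.DataFrame(meta_rows).set_index("well")
    plate = CqPlate(
        cq=pd.DataFrame(np.vstack(rows), index=meta.index, columns=assays),
        well_meta=meta,
        assay_meta=pd.DataFrame({"panel": panel}, index=assays),
    )
    return plate, pd.Series(states, index=meta.index, name="state")
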