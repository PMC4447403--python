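"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (first column gene id, header sample
ids) with a companion sample sheet CSV (``sample_id,group``); gene sets as
GMT plus a detailed per-gene CSV; cohorts as a single CSV with survival
and probe columns followed by gene columns; Cq plates as a wide CSV with
empty cells meaning no amplification, plus well- and assay-metadata CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .signatures import ExpressionMatrix, GeneSignature
from .singlecell import CqPlate
from .survival import SurvivalCohort

NON_GENE_COHORT_COLUMNS = (
    "time", "event", "endpoint", "esr_probe", "mki67_probe", "her2_probe",
    "subtype",
)


# -- expression matrices ----------------------------------------------------

def read_expression_matrix(matrix_tsv: str | Path, samples_csv: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_csv)
    if not {"sample_id", "group"}.issubset(sheet.columns):
        raise InvalidInputError("sample sheet needs sample_id and group columns")
    labels = sheet.set_index("sample_id")["group"]
    return ExpressionMatrix(values, labels)


def write_expression_matrix(
    matrix: ExpressionMatrix, matrix_tsv: str | Path, samples_csv: str | Path
) -> None:
    matrix.values.to_csv(matrix_tsv, sep="\t", index_label="gene_id")
    matrix.sample_labels.rename("group").rename_axis("sample_id").reset_index().to_csv(
        samples_csv, index=False
    )


# -- gene signatures --------------------------------------------------------

def write_gmt(signatures: Sequence[GeneSignature], path: str | Path,
              description: str = "") -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, description, *sig.genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InvalidInputError(f"{path}:{i + 1}: malformed GMT line")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_signature_csv(sig: GeneSignature, path: str | Path,
                        p_adj: Mapping[str, float] | None = None) -> None:
    out = sig.members.copy()
    if p_adj is not None:
        out["p_adj"] = [p_adj.get(g, np.nan) for g in out["gene"]]
    out.to_csv(path, index=False)


def read_signature_csv(path: str | Path, name: str | None = None) -> GeneSignature:
    members = pd.read_csv(path)
    needed = {"gene", "direction", "rank", "effect_size"}
    if not needed.issubset(members.columns):
        raise InvalidInputError(f"{path}: signature CSV needs columns {sorted(needed)}")
    return GeneSignature(name=name or Path(path).stem,
                         members=members[list(needed)])


# -- survival cohorts -------------------------------------------------------

def read_cohort(path: str | Path, endpoint: str = "OS") -> SurvivalCohort:
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in ("time", "event") if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: cohort CSV lacks columns {missing}")
    patient_cols = [c for c in NON_GENE_COHORT_COLUMNS if c in df.columns]
    gene_cols = [c for c in df.columns if c not in NON_GENE_COHORT_COLUMNS]
    return SurvivalCohort(df[patient_cols], df[gene_cols], endpoint=endpoint)


def write_cohort(cohort: SurvivalCohort, path: str | Path) -> None:
    pd.concat([cohort.patients, cohort.expression], axis=1).to_csv(
        path, index_label="patient_id"
    )


# -- Cq plates --------------------------------------------------------------

def read_cq_plate(cq_csv: str | Path, wells_csv: str | Path,
                  assays_csv: str | Path) -> CqPlate:
    cq = pd.read_csv(cq_csv, index_col=0)
    wells = pd.read_csv(wells_csv, index_col=0)
    assays = pd.read_csv(assays_csv, index_col=0)
    if "is_ntc" in wells.columns:
        wells["is_ntc"] = wells["is_ntc"].astype(bool)
    return CqPlate(cq=cq, well_meta=wells, assay_meta=assays)


def write_cq_plate(plate: CqPlate, cq_csv: str | Path, wells_csv: str | Path,
                   assays_csv: str | Path) -> None:
    plate.cq.to_csv(cq_csv, index_label="well")
    plate.well_meta.to_csv(wells_csv, index_label="well")
    plate.assay_meta.to_csv(assays_csv, index_label="assay")


# -- reports ----------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
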