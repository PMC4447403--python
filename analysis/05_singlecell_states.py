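#!/usr/bin/env python
"""Single-cell qPCR chain: raw Cq plate -> E-M state space -> statistics.

Estimates per-assay background from NTC wells, converts Cq to linear
expression, max-normalizes per gene over single cells, projects each cell
to (mean E, mean M), counts co-expressing cells, and tests E-vs-M group
separation with the cross-match test and per-panel Mann-Whitney U tests;
standardized PCA and block-averaged Pearson correlations summarize the
structure.
"""

import argparse
from pathlib import Path

import pandas as pd

from emstate import (
    count_coexpressing,
    crossmatch_test,
    io,
    mann_whitney_u,
    pca_cells,
    process_plate,
    project_em_state,
)
from emstate.singlecell import correlation_matrix

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "singlecell")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    plate = io.read_cq_plate(args.data / "cq.csv", args.data / "cq_wells.csv",
                             args.data / "cq_assays.csv")
    states = pd.read_csv(args.data / "cq_truth_states.csv", index_col=0)["state"]

    profile = process_plate(plate)
    profile.normalized.to_csv(args.out / "normalized.csv", index_label="well")
    sc = profile.single_cells()
    pts = project_em_state(sc, groups=states)
    pts.to_csv(args.out / "state_space.csv", index_label="cell_id")

    g = pts.groupby("group")[["mean_e", "mean_m"]].mean()
    print("group means in the E-M state space:")
    print(g.round(3).to_string())

    counts = count_coexpressing(sc)
    e_mask = (states.loc[sc.index] == "E").to_numpy()
    ce = count_coexpressing(sc[e_mask])
    cm = count_coexpressing(sc[~e_mask])
    print(f"E cells: {ce['coexpressing']}/{ce['n_cells']} co-express E and M "
          f"genes; M cells: {cm['exclusive_m']}/{cm['n_cells']} exclusively M")

    res = crossmatch_test(pts[["mean_e", "mean_m"]].to_numpy(),
                          pts["group"].to_numpy(), ids=list(pts.index))
    e_pts = pts[pts["group"] == "E"]
    m_pts = pts[pts["group"] == "M"]
    _, p_e = mann_whitney_u(e_pts["mean_e"], m_pts["mean_e"])
    _, p_m = mann_whitney_u(e_pts["mean_m"], m_pts["mean_m"])
    print(f"cross-match: A1={res.a1} of {res.n_total // 2} pairs, "
          f"p={res.p:.2e}; Mann-Whitney p (E panel)={p_e:.2e}, "
          f"(M panel)={p_m:.2e}")
    io.write_json(
        {"coexpression": counts,
         "coexpression_e_cells": ce, "coexpression_m_cells": cm,
         "crossmatch": {"a1": res.a1, "p": res.p, "n_total": res.n_total},
         "mann_whitney_p": {"E": p_e, "M": p_m}},
        args.out / "statistics.json",
    )

    scores, loadings, varfrac = pca_cells(sc)
    scores.to_csv(args.out / "pca_scores.csv", index_label="cell_id")
    loadings.to_csv(args.out / "pca_loadings.csv", index_label="gene")
    print(f"PCA: first two components explain "
          f"{varfrac[0]:.0%} + {varfrac[1]:.0%} of variance")

    _, block_r = correlation_matrix(sc, blocks=states.loc[sc.index])
    block_r.to_csv(args.out / "correlation_block_averages.csv")
    print("block-averaged Pearson r:")
    print(block_r.astype(float).round(3).to_string())


if __name__ == "__main__":
    main()
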