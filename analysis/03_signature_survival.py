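#!/usr/bin/env python
"""Score the simulated cohort with the planted signature, overall and per
clinical subtype.

For each stratum the score is dichotomized at the best of the
median/tertile/quartile cutoffs and summarized as a hazard ratio (high vs
low, Cox/Breslow) with the logrank p; a Kaplan-Meier table for the overall
split is written alongside.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from emstate import (
    evaluate_signature_survival,
    io,
    kaplan_meier,
    score_signature,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "survival")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = io.read_cohort(args.data / "cohort.csv")
    truth = json.loads((args.data / "cohort_truth.json").read_text())
    genes = truth["signature_genes"]

    results = {}
    for subtype in (None, "luminalA", "luminalB", "basal", "HER2"):
        label = subtype or "all"
        try:
            fit = evaluate_signature_survival(cohort, genes, subtype=subtype)
        except Exception as exc:  # small stratum may be degenerate
            print(f"{label}: skipped ({exc})")
            continue
        results[label] = fit.as_dict()
        print(f"{label:9s} HR={fit.hr:5.2f} [{fit.ci_low:.2f}, {fit.ci_high:.2f}]"
              f"  logrank p={fit.logrank_p:.2e}  cutoff q={fit.cutoff:.2f}"
              f"  ({fit.n_high} high / {fit.n_low} low)")
    io.write_json(results, args.out / "survival_fits.json")

    scores = score_signature(cohort.expression, genes)
    cut = np.quantile(scores, results["all"]["cutoff"])
    for name, mask in (("high", scores > cut), ("low", scores <= cut)):
        km = kaplan_meier(cohort.patients.loc[mask, "time"],
                          cohort.patients.loc[mask, "event"])
        km.to_csv(args.out / f"km_{name}.csv", index=False)
    print(f"KM tables written for the overall split at quantile "
          f"{results['all']['cutoff']:.2f}")


if __name__ == "__main__":
    main()
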