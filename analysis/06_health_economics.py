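#!/usr/bin/env python
"""Health-economic comparison of monitoring intervals across risk deciles.

Scores the validation cohort with the final model, selects one patient per
risk decile (5th, 15th, ..., 95th percentile of predicted 5-year risk), and
runs the event-tree model for 3-, 6-, 12- and 24-monthly monitoring:
deterministic base case, probabilistic sensitivity analysis, and the
three-fold illness-risk sensitivity analysis. Writes decile-by-strategy
tables under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from thiomon import health_econ as he
from thiomon.cohort import to_design_matrix
from thiomon.risk_model import PublishedModel, score_cohort

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "develop", Path(__file__).with_name("03_develop_model.py"))
_dev = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_dev)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--psa-draws", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=31)
    args = ap.parse_args()

    spec = json.loads((RESULTS / "model_final.json").read_text())
    model = PublishedModel(coefficients=spec["coefficients"],
                           shrinkage=spec["shrinkage"],
                           s0=spec["baseline_survival"]["5.0"])
    stack = _dev.load_stack("validation")
    risks = np.mean([score_cohort(to_design_matrix(d), model)["predicted_risk"]
                     for d in stack.datasets], axis=0)

    patients = he.select_decile_patients(risks, seed=args.seed)
    print("decile risks:", [round(p.five_year_risk, 3) for p in patients])

    params = he.default_params()
    strategies = he.default_strategies()

    det = he.run_deterministic(patients, strategies, params)
    det.to_csv(RESULTS / "he_deterministic.csv", index=False)
    best = det.loc[det.groupby("decile")["inmb_vs_3monthly"].idxmax()]
    print("base case, iNMB vs 3-monthly (GBP):")
    print(det.pivot(index="decile", columns="strategy",
                    values="inmb_vs_3monthly").round(1).to_string())
    print("most cost-effective per decile:", best.strategy.tolist())

    psa = he.run_psa(patients, strategies, params, n_draws=args.psa_draws,
                     seed=args.seed)
    psa.to_csv(RESULTS / "he_psa.csv", index=False)

    sens = he.run_deterministic(
        patients, strategies, he.sensitivity_scale_risk(params, 3.0))
    sens.to_csv(RESULTS / "he_sensitivity_3x.csv", index=False)
    best3 = sens.loc[sens.groupby("decile")["inmb_vs_3monthly"].idxmax()]
    print("3x illness-risk sensitivity, most cost-effective per decile:",
          best3.strategy.tolist())


if __name__ == "__main__":
    main()
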