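#!/usr/bin/env python
"""Evaluate the final (shrunken) model on the validation stack.

Applies the frozen equation without refitting: calibration slope, Royston D
(and its implied hazard ratio), R2_D, grouped and smoothed calibration at 5
years, and subgroup performance by inflammatory disease. Metrics are pooled
across imputations by Rubin's rules; calibration curve data are written per
imputation.
"""

import argparse
import json
from pathlib import Path

from thiomon.performance import evaluate
from thiomon.risk_model import PublishedModel

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "develop", Path(__file__).with_name("03_develop_model.py"))
_dev = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_dev)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--horizon", type=float, default=5.0)
    args = ap.parse_args()

    spec = json.loads((RESULTS / "model_final.json").read_text())
    model = PublishedModel(coefficients=spec["coefficients"],
                           shrinkage=spec["shrinkage"],
                           s0=spec["baseline_survival"][str(args.horizon)],
                           horizon=args.horizon)
    stack = _dev.load_stack("validation")

    report, curves = evaluate(model, stack, horizon=args.horizon)
    s = report.calibration_slope
    d = report.royston_d
    print(f"validation n={report.n}, events={report.events}")
    print(f"calibration slope {s.value:.2f} "
          f"({s.ci95[0]:.2f}, {s.ci95[1]:.2f})")
    print(f"Royston D {d.value:.2f} ({d.ci95[0]:.2f}, {d.ci95[1]:.2f}) "
          f"-> HR {report.implied_hr:.2f}")
    print(f"R2_D {report.r2_d:.2f} ({report.r2_ci[0]:.2f}, "
          f"{report.r2_ci[1]:.2f})")
    for i, curve in enumerate(curves):
        curve.groups.to_csv(RESULTS / f"calibration_groups_imp{i:02d}.csv",
                            index=False)
        curve.smooth.to_csv(RESULTS / f"calibration_smooth_imp{i:02d}.csv",
                            index=False)

    by_disease = evaluate(model, stack, horizon=args.horizon,
                          subgroup="disease")
    for level, (rep, _) in by_disease.items():
        print(f"  {level:14s} slope {rep.calibration_slope.value:5.2f}  "
              f"D {rep.royston_d.value:5.2f}  (n={rep.n}, "
              f"events={rep.events})")


if __name__ == "__main__":
    main()
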