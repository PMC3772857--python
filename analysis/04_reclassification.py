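#!/usr/bin/env python
"""Discrimination and reclassification: does adding genetics help?

Scores every complete-data subject under the non-genetic-only, genetic-only
and full fitted models; compares AUROCs pairwise with the DeLong test; then
computes lifetime risks (ages 50-85) under the non-genetic and full models,
cross-tabulates movement across the sex-specific twice-average-lifetime-risk
threshold, and reports the net reclassification improvement.
"""

import math
from pathlib import Path

import numpy as np
import pandas as pd

from pancrisk.absrisk import calibrate_baseline, lifetime_risk
from pancrisk.evaluate import auroc, delong_compare, nri, reclassify
from pancrisk.io import read_subjects
from pancrisk.rrmodel import RiskProfile, load_coefficients, relative_risk
from pancrisk.synth import simulate_life_table

OUT = Path(__file__).resolve().parent.parent / "results"
START_AGE = 50


def main() -> None:
    records = read_subjects(OUT / "subjects.tsv")
    coeffs = {spec: load_coefficients(OUT / f"coefficients_{spec}.tsv")
              for spec in ("full", "nongenetic_only", "genetic_only")}

    # complete-data subjects only, mirroring the evaluation protocol
    subjects = []
    for r in records:
        try:
            profile = RiskProfile.from_record(r)
        except ValueError:
            continue
        if not profile.has_missing():
            subjects.append((r, profile))
    print(f"evaluation subset: {sum(r.status == 'case' for r, _ in subjects)} "
          f"cases / {sum(r.status == 'control' for r, _ in subjects)} controls "
          f"with complete data")

    scores = {spec: {"case": [], "control": []} for spec in coeffs}
    for spec, cs in coeffs.items():
        for r, profile in subjects:
            scores[spec][r.status].append(
                math.log(relative_risk(profile, cs, model_spec=spec)))

    lines = []
    for spec in coeffs:
        a = auroc(scores[spec]["case"], scores[spec]["control"])
        lines.append({"model": spec, "auroc": a.auc, "ci_low": a.ci95[0],
                      "ci_high": a.ci95[1]})
        print(f"AUROC {spec}: {a.auc:.3f} ({a.ci95[0]:.3f}-{a.ci95[1]:.3f})")
    for other in ("nongenetic_only", "genetic_only"):
        _, _, diff, z, p = delong_compare(
            scores["full"]["case"], scores["full"]["control"],
            scores[other]["case"], scores[other]["control"])
        print(f"DeLong full vs {other}: diff {diff:+.4f}, z {z:.2f}, "
              f"p {p:.2e}")
    pd.DataFrame(lines).round(4).to_csv(OUT / "auroc.csv", index=False)

    # reclassification at twice the average lifetime risk, by sex
    nri_rows = []
    for sex in ("male", "female"):
        table = simulate_life_table(sex)
        sex_subjects = [(r, p) for r, p in subjects if r.sex == sex]
        controls = [p for r, p in sex_subjects if r.status == "control"]
        risks = {}
        for spec in ("nongenetic_only", "full"):
            baseline = calibrate_baseline(table, controls, coeffs[spec],
                                          model_spec=spec)
            risks[spec] = [lifetime_risk(p, START_AGE, baseline, table,
                                         coeffs[spec], model_spec=spec)
                           for _, p in sex_subjects]
        control_risks = [risk for (r, _), risk
                         in zip(sex_subjects, risks["full"])
                         if r.status == "control"]
        threshold = 2.0 * float(np.mean(control_risks))
        rtable = reclassify(risks["nongenetic_only"], risks["full"],
                            [r.status for r, _ in sex_subjects], threshold)
        result = nri(rtable)
        nri_rows.append({"sex": sex, "threshold": threshold,
                         "nri": result.nri, "se": result.se, "z": result.z,
                         "p_one_sided": result.p_one_sided,
                         "cases_up": int(rtable.cases[0, 1]),
                         "cases_down": int(rtable.cases[1, 0]),
                         "controls_up": int(rtable.controls[0, 1]),
                         "controls_down": int(rtable.controls[1, 0])})
        print(f"{sex}: threshold {100 * threshold:.2f}%, "
              f"NRI {result.nri:+.3f} +- {result.se:.3f} "
              f"(one-sided p = {result.p_one_sided:.2f})")
        print(f"  controls {rtable.controls.tolist()}  "
              f"cases {rtable.cases.tolist()}")
    pd.DataFrame(nri_rows).round(5).to_csv(OUT / "nri.csv", index=False)
    print(f"wrote {OUT / 'auroc.csv'} and {OUT / 'nri.csv'}")


if __name__ == "__main__":
    main()
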