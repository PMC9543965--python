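"""Case-control comparisons, biomarker/MRI correlations and pre/post change
models on the simulated cohorts.

Reads the cohorts written by 01_simulate_cohorts.py, tests every variable
between groups (t / Mann-Whitney / chi-square as flagged), computes Pearson
correlations between the biomarker panel and MRI measures within each group,
and fits change-score models 1-3 per biomarker within each RCT arm with
Bonferroni adjustment across the panel.  Writes tidy CSVs under results/stats/.
"""

import argparse
from pathlib import Path

import pandas as pd

from fibropanel import (
    compare_case_control,
    correlation_matrix,
    log10_transform,
    prepost_change_model,
    read_cohort,
    results_to_frame,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohorts", type=Path, default=Path("results/cohorts"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cc = read_cohort(args.cohorts / "case_control.csv",
                     args.cohorts / "case_control.schema.json")
    rct = read_cohort(args.cohorts / "rct.csv", args.cohorts / "rct.schema.json")

    biomarkers = cc.variables_by_role("biomarker")
    mri = cc.variables_by_role("mri")

    # biomarkers are analysed on the log10 scale, flagged parametric there
    cc_log = cc.copy()
    for b in biomarkers:
        cc_log.data[b] = log10_transform(cc_log.data[b])
    flags = {b: "parametric" for b in biomarkers}
    comparisons = compare_case_control(cc_log, flags=flags)
    results_to_frame(comparisons).to_csv(args.out / "case_control_comparisons.csv",
                                         index=False)
    sig = [r for r in comparisons
           if r.variable in biomarkers and r.p_raw == r.p_raw and r.p_raw < 0.05]
    print(f"case-control: {len(comparisons)} variables tested, "
          f"{len(sig)} biomarkers differ at raw p < 0.05")

    for group in ("control", "t2d"):
        r, p = correlation_matrix(cc_log, biomarkers, mri, group=group)
        r.to_csv(args.out / f"correlations_r_{group}.csv")
        p.to_csv(args.out / f"correlations_p_{group}.csv")
    print(f"correlation matrices ({len(biomarkers)}x{len(mri)}) written per group")

    rows = []
    m = len(biomarkers)
    for arm in rct.data["arm"].dropna().unique():
        for model_id in (1, 2, 3):
            for b in biomarkers:
                res = prepost_change_model(rct, b, model_id, arm=arm, m=m)
                row = res.to_row()
                row["arm"] = arm
                rows.append(row)
    changes = pd.DataFrame(rows)
    changes.to_csv(args.out / "change_models.csv", index=False)
    for arm in changes["arm"].unique():
        for model in sorted(changes["test"].unique()):
            hit = changes[(changes["arm"] == arm) & (changes["test"] == model)
                          & (changes["p_adjusted"] < 0.05)]
            print(f"  {arm:13s} {model}: {len(hit):2d}/{m} biomarkers changed "
                  f"(Bonferroni-adjusted p < 0.05)")


if __name__ == "__main__":
    main()
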