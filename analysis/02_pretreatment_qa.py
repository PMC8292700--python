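#!/usr/bin/env python
"""Pretreatment QA: independent recalculation of every RT plan.

For each cohort case, the reference dose is computed with the "TPS-like"
engine configuration and the plan is recomputed with the independent
"QA-like" configuration (offset attenuation/penumbra, 1% noise).  Gamma
(2%/1mm/20%) and the clinical DVH metric set are compared and classified
against the 90% GPR / 2% PTV Dmean limits.  Reference doses are kept for
the on-treatment stage; per-case reports land in
results/pretreatment_reports/.
"""

import pandas as pd

from _common import (RESULTS, case_file, qa_config, reference_file,
                     tps_config, write_report, PRESCRIPTION_GY)
from vmatqa import compute_dose, load_case, pretreatment_qa, save_case


def main() -> None:
    rows = []
    case_id = 0
    while case_file(case_id).exists():
        case = load_case(case_file(case_id))
        reference = compute_dose(case["plan"], case["phantom"],
                                 tps_config(case_id))
        reference_file(case_id).parent.mkdir(parents=True, exist_ok=True)
        save_case(reference_file(case_id), dose=reference)

        report = pretreatment_qa(case["plan"], case["phantom"],
                                 case["structures"], reference,
                                 cfg=qa_config(case_id),
                                 prescription_gy=PRESCRIPTION_GY)
        write_report("pretreatment", case_id, report)
        rows.append({
            "case_id": case_id,
            "gpr_overall": round(report.gamma_pct["overall"], 2),
            "gpr_ptv": round(report.gamma_pct["PTV"], 2),
            "ptv_dmean_diff_pct": round(report.ptv_dmean_diff_pct, 3),
            "passed": report.passed,
        })
        case_id += 1

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "pretreatment_qa.csv", index=False)
    print(f"Pretreatment QA on {len(table)} plans: "
          f"overall GPR {table.gpr_overall.mean():.1f} "
          f"+/- {table.gpr_overall.std():.1f}% "
          f"(range {table.gpr_overall.min():.1f}-"
          f"{table.gpr_overall.max():.1f}%), "
          f"PTV Dmean diff {table.ptv_dmean_diff_pct.mean():.2f} "
          f"+/- {table.ptv_dmean_diff_pct.std():.2f}%; "
          f"{int(table.passed.sum())}/{len(table)} pass.")


if __name__ == "__main__":
    main()
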