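#!/usr/bin/env python
"""On-treatment QA: deliver, log at 4 Hz, reconstruct, recompute, compare.

Each plan is delivered by the simulated linac with tolerance-bounded
jitter; the 4-Hz log is written in the plain-text dialect (one record per
0.25 s), reconstructed into an RT log file plan (one control point per
record) and recomputed with the independent engine configuration against
the stored reference dose.  This stage therefore checks the planning
calculation, the transfer to the machine, and the delivery itself.
"""

import argparse

import pandas as pd

from _common import (ARC_SECONDS, PRESCRIPTION_GY, RESULTS, case_file,
                     log_file, qa_config, read_reports, reference_file,
                     write_report)
from vmatqa import (JitterSpec, load_case, ontreatment_qa, read_log,
                    simulate_delivery, write_log)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--jitter-seed", type=int, default=17)
    args = ap.parse_args()

    rows = []
    case_id = 0
    while case_file(case_id).exists():
        case = load_case(case_file(case_id))
        reference = load_case(reference_file(case_id))["dose"]

        jitter = JitterSpec(seed=args.jitter_seed + case_id)
        log = simulate_delivery(case["plan"], jitter, ARC_SECONDS)
        log_file(case_id).parent.mkdir(parents=True, exist_ok=True)
        write_log(log, log_file(case_id))
        log = read_log(log_file(case_id))  # QA consumes the file, not memory

        report = ontreatment_qa(case["plan"], log, case["phantom"],
                                case["structures"], reference,
                                cfg=qa_config(case_id),
                                prescription_gy=PRESCRIPTION_GY)
        write_report("ontreatment", case_id, report)
        rows.append({
            "case_id": case_id,
            "records": len(log),
            "gpr_overall": round(report.gamma_pct["overall"], 2),
            "gpr_ptv": round(report.gamma_pct["PTV"], 2),
            "ptv_dmean_diff_pct": round(report.ptv_dmean_diff_pct, 3),
            "passed": report.passed,
        })
        case_id += 1

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "ontreatment_qa.csv", index=False)
    pre = read_reports("pretreatment")
    pre_gpr = sum(r.gamma_pct["overall"] for r in pre) / len(pre)
    print(f"On-treatment QA on {len(table)} delivered plans "
          f"({int(table.records.iloc[0])} log records each): "
          f"overall GPR {table.gpr_overall.mean():.1f} "
          f"+/- {table.gpr_overall.std():.1f}% "
          f"(pretreatment was {pre_gpr:.1f}%); "
          f"{int(table.passed.sum())}/{len(table)} pass.")


if __name__ == "__main__":
    main()
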