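#!/usr/bin/env python
"""Build the virtual-patient cohort: phantom, structures, normalized plans.

Generates N dual-arc prostate VMAT plans (PTV volumes drawn log-uniformly
over the clinical 61-630 ccm range, randomized modulation, leaf gap and
collimator angles) on a shared water-cylinder pelvis, each normalized so
the planning engine's PTV Dmean equals the 2 Gy prescription.  Cases are
stored as single-file HDF5 containers under results/cohort/ and indexed
by a plain-text manifest.
"""

import argparse

import pandas as pd

from _common import (ARC_SECONDS, CPS_PER_ARC, GRID_MM, PHANTOM_LENGTH_MM,
                     PHANTOM_RADIUS_MM, RESULTS, case_file, tps_config)
from vmatqa import make_phantom, save_case
from vmatqa.synthetic_data import generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("-n", type=int, default=10, help="cohort size")
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    phantom = make_phantom(PHANTOM_RADIUS_MM, PHANTOM_LENGTH_MM, GRID_MM,
                           anteroposterior_ratio=0.85)
    cases = generate_cohort(args.n, seed=args.seed, phantom=phantom,
                            engine_cfg=tps_config(0),
                            control_points_per_arc=CPS_PER_ARC)

    (RESULTS / "cohort").mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        save_case(case_file(case.case_id), phantom=case.phantom,
                  structures=case.structures, plan=case.plan)
        rows.append({
            "case_id": case.case_id,
            "ptv_volume_ccm": round(case.spec.ptv_volume_ccm, 1),
            "ptv_realized_ccm": round(case.structures.volume_ccm("PTV"), 1),
            "modulation": round(case.spec.modulation, 3),
            "min_leaf_gap_cm": round(case.spec.min_leaf_gap_cm, 2),
            "collimator_arc1_deg": round(case.spec.collimator_deg[0], 1),
            "collimator_arc2_deg": round(case.spec.collimator_deg[1], 1),
            "total_mu": round(case.plan.total_mu, 1),
            "control_points": case.plan.n_control_points,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(RESULTS / "cohort_manifest.csv", index=False)
    print(f"Built {len(cases)} virtual patients "
          f"(PTV {manifest.ptv_realized_ccm.min():.0f}-"
          f"{manifest.ptv_realized_ccm.max():.0f} ccm, "
          f"{manifest.total_mu.min():.0f}-{manifest.total_mu.max():.0f} MU); "
          f"arcs of {ARC_SECONDS:.0f} s assumed downstream.")
    print(f"Manifest: {RESULTS / 'cohort_manifest.csv'}")


if __name__ == "__main__":
    main()
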