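"""Shared constants and paths for the numbered analysis drivers.

Problem sizes for the desk-scale study: a 100 mm-radius water pelvis on a
4 mm grid, 31 control points per arc, 45 s arcs and 128 meterset samples
in the engine.  Engine seeds are offset per case so the reference
("TPS-like") and recalculation ("QA-like") noise fields are independent
across the cohort.
"""

from __future__ import annotations

import json
from pathlib import Path

from vmatqa import QaReport
from vmatqa.qa_pipeline import default_qa_config, default_tps_config

RESULTS = Path(__file__).resolve().parent.parent / "results"

PHANTOM_RADIUS_MM = 100.0
PHANTOM_LENGTH_MM = 140.0
GRID_MM = 4.0
CPS_PER_ARC = 31
ARC_SECONDS = 45.0
MU_SAMPLES = 128
PRESCRIPTION_GY = 2.0


def tps_config(case_id: int):
    return default_tps_config(GRID_MM, seed=1000 + case_id,
                              mu_samples=MU_SAMPLES)


def qa_config(case_id: int):
    return default_qa_config(GRID_MM, seed=2000 + case_id,
                             mu_samples=MU_SAMPLES)


def case_file(case_id: int) -> Path:
    return RESULTS / "cohort" / f"case_{case_id:02d}.h5"


def reference_file(case_id: int) -> Path:
    return RESULTS / "reference" / f"case_{case_id:02d}.h5"


def log_file(case_id: int) -> Path:
    return RESULTS / "logs" / f"case_{case_id:02d}.log"


def report_file(mode: str, case_id: int) -> Path:
    return RESULTS / f"{mode}_reports" / f"case_{case_id:02d}.json"


def write_report(mode: str, case_id: int, report: QaReport) -> None:
    path = report_file(mode, case_id)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report.to_dict(), indent=1))


def read_reports(mode: str) -> list[QaReport]:
    folder = RESULTS / f"{mode}_reports"
    reports = []
    for path in sorted(folder.glob("case_*.json")):
        reports.append(QaReport.from_dict(json.loads(path.read_text())))
    return reports
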