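"""Result serialization: operating-characteristic tables, decision traces,
per-trial records and run manifests.  All outputs are CSV or JSON."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DoseGrid
from .simulate import OperatingCharacteristics, TrialResult

__all__ = [
    "RunManifest",
    "write_oc_table",
    "read_oc_table",
    "write_decision_trace",
    "write_trial_records",
    "read_trial_records",
    "oc_from_trial_records",
]


@dataclass
class RunManifest:
    """Provenance record referenced by every output file of a run."""

    command: str
    seed: int | None
    config_hash: str = ""
    package_version: str = "0.1.0"
    created_utc: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    )
    params: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _oc_columns(grid: DoseGrid) -> list:
    cols = []
    for d in grid.doses:
        cols += [f"pct_selection_{d:g}", f"mean_patients_{d:g}"]
    return cols + ["pct_nds", "n_reps", "n_failed"]


def write_oc_table(oc: OperatingCharacteristics | None, grid: DoseGrid, path) -> None:
    """One-row wide CSV mirroring the per-dose selection/patients layout,
    always including the no-dose-selected (NDS) column.  ``oc=None`` writes a
    header-only file (an empty study)."""
    cols = _oc_columns(grid)
    if oc is None:
        df = pd.DataFrame(columns=cols)
    else:
        row = {}
        for j, d in enumerate(grid.doses):
            row[f"pct_selection_{d:g}"] = oc.pct_selection[j]
            row[f"mean_patients_{d:g}"] = oc.mean_patients[j]
        row["pct_nds"] = oc.pct_nds
        row["n_reps"] = oc.n_reps
        row["n_failed"] = oc.n_failed
        df = pd.DataFrame([row], columns=cols)
    df.to_csv(path, index=False)


def read_oc_table(path, grid: DoseGrid) -> OperatingCharacteristics | None:
    df = pd.read_csv(path)
    if df.empty:
        return None
    row = df.iloc[0]
    return OperatingCharacteristics(
        pct_selection=np.array([row[f"pct_selection_{d:g}"] for d in grid.doses]),
        pct_nds=float(row["pct_nds"]),
        mean_patients=np.array([row[f"mean_patients_{d:g}"] for d in grid.doses]),
        n_reps=int(row["n_reps"]),
        n_failed=int(row["n_failed"]),
    )


def write_decision_trace(result: TrialResult, grid: DoseGrid, path) -> None:
    """Per-cohort CSV: assigned dose (1-based), running n, per-dose expected
    utilities and admissibility flags, and the decision taken."""
    rows = []
    for rec in result.trace:
        row = {
            "cohort": rec["cohort"],
            "assigned_dose": rec["assigned_dose"],
            "n_total": rec["n_total"],
        }
        for j in range(grid.k):
            row[f"eu_{j + 1}"] = rec["expected_utilities"][j]
            row[f"admissible_{j + 1}"] = rec["admissible"][j]
        row["action"] = rec["action"]
        row["next_dose"] = rec["next_dose"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trial_records(results, grid: DoseGrid, path) -> None:
    """Per-replicate CSV (selected dose 1-based, blank means no dose)."""
    rows = []
    for i, r in enumerate(results):
        row = {
            "replicate": i + 1,
            "selected_dose": "" if r.selected is None else r.selected + 1,
            "total_n": r.total_n,
            "stopped_early": int(r.stopped_early),
            "failed": int(r.failed),
        }
        for j, d in enumerate(grid.doses):
            row[f"patients_{d:g}"] = int(r.patients_per_dose[j])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trial_records(path, grid: DoseGrid) -> list:
    df = pd.read_csv(path)
    results = []
    for _, row in df.iterrows():
        sel = row["selected_dose"]
        results.append(
            TrialResult(
                selected=None if pd.isna(sel) else int(sel) - 1,
                patients_per_dose=np.array(
                    [int(row[f"patients_{d:g}"]) for d in grid.doses]
                ),
                total_n=int(row["total_n"]),
                stopped_early=bool(row["stopped_early"]),
                failed=bool(row["failed"]),
            )
        )
    return results


def oc_from_trial_records(path, grid: DoseGrid) -> OperatingCharacteristics:
    return OperatingCharacteristics.from_results(read_trial_records(path, grid), grid.k)
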