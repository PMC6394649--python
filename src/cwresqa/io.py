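"""Reading and writing the NONMEM-dialect CSV formats and report files.

Dataset CSV columns: ID, TIME, AMT, DV, DVID, EVID, MDV (EVID 1 = dose,
0 = observation; MDV 1 = missing; DVID is 1-based).  CWRES tables round-trip
with columns ID, ROW, DVID, TIME, PRED_<dv>..., CWRES.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import Dataset, Design, Dose, SubjectData

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_cwres_table",
    "write_cwres_table",
    "write_json_report",
]


def read_dataset(path, dv_labels=("dv1",)) -> Dataset:
    """Load a NONMEM-dialect CSV into a :class:`Dataset`.

    DVID and MDV columns are optional (defaulting to 1 and 0); rows with
    MDV = 1 are dropped from the observation vector.
    """
    df = pd.read_csv(path)
    required = {"ID", "TIME", "DV", "EVID"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing columns {sorted(missing)}")
    if "DVID" not in df.columns:
        df["DVID"] = 1
    if "MDV" not in df.columns:
        df["MDV"] = 0
    if "AMT" not in df.columns:
        df["AMT"] = 0.0
    subjects = []
    for sid, block in df.groupby("ID", sort=False):
        block = block.sort_values("TIME", kind="stable")
        dose_rows = block[block["EVID"] == 1]
        obs = block[(block["EVID"] == 0) & (block["MDV"] == 0)]
        doses = tuple(
            Dose(time=float(r.TIME), amt=float(r.AMT)) for r in dose_rows.itertuples()
        )
        design = Design(
            times=obs["TIME"].to_numpy(float),
            dvid=obs["DVID"].to_numpy(int) - 1,
            doses=doses,
        )
        subjects.append(SubjectData(id=sid, design=design, y=obs["DV"].to_numpy(float)))
    if int(df["DVID"].max()) > len(dv_labels):
        raise ValueError(
            f"dataset uses DVID up to {int(df['DVID'].max())} but only "
            f"{len(dv_labels)} dv_labels given"
        )
    return Dataset(subjects=tuple(subjects))


def write_dataset(dataset: Dataset, path) -> None:
    rows = []
    for s in dataset:
        for d in s.design.doses:
            rows.append(
                {"ID": s.id, "TIME": d.time, "AMT": d.amt, "DV": np.nan,
                 "DVID": 1, "EVID": 1, "MDV": 1}
            )
        for t, dv, y in zip(s.design.times, s.design.dvid, s.y):
            rows.append(
                {"ID": s.id, "TIME": t, "AMT": 0.0, "DV": y,
                 "DVID": int(dv) + 1, "EVID": 0, "MDV": 0}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cwres_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cwres_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"ID", "ROW", "DVID", "TIME", "CWRES"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"CWRES table is missing columns {sorted(missing)}")
    return table


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")
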