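"""Plain-text (CSV) serialization of multimodal cohorts.

Layout written by :func:`write_cohort` into a directory:

* ``labs.csv`` — patient_id, lab_0..lab_{p-1} (NaN = missing)
* ``series.csv`` — patient_id, variable_id, timestamp, value (long format)
* ``ecg_emb.csv`` / ``note_emb.csv`` — patient_id, token, d0..d{k-1}
* ``labels.csv`` — patient_id, label
* ``modality_mask.csv`` — patient_id, lab, time, ecg, note (0/1 presence)
* ``aligned_series.csv`` (after preprocessing) — patient_id, grid_step,
  one column per variable
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import MODALITIES, MultimodalRecord, RawSeries

__all__ = ["write_cohort", "read_cohort"]


def write_cohort(records: list[MultimodalRecord], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    labs = pd.DataFrame(
        [r.lab for r in records],
        columns=[f"lab_{j}" for j in range(len(records[0].lab))],
    )
    labs.insert(0, "patient_id", [r.patient_id for r in records])
    labs.to_csv(out / "labs.csv", index=False)

    series_rows = [
        (r.patient_id, s.variable_id, t, v)
        for r in records
        for s in r.series
        for t, v in s.points
    ]
    pd.DataFrame(
        series_rows, columns=["patient_id", "variable_id", "timestamp", "value"]
    ).to_csv(out / "series.csv", index=False)

    for attr, name in (("ecg_emb", "ecg_emb.csv"), ("note_emb", "note_emb.csv")):
        rows = []
        for r in records:
            mat = getattr(r, attr)
            for k, row in enumerate(mat):
                rows.append([r.patient_id, k, *row])
        dim = len(rows[0]) - 2
        pd.DataFrame(
            rows, columns=["patient_id", "token", *[f"d{j}" for j in range(dim)]]
        ).to_csv(out / name, index=False)

    pd.DataFrame(
        {"patient_id": [r.patient_id for r in records],
         "label": [r.label for r in records]}
    ).to_csv(out / "labels.csv", index=False)

    mask = pd.DataFrame(
        [[int(r.present[m]) for m in MODALITIES] for r in records],
        columns=list(MODALITIES),
    )
    mask.insert(0, "patient_id", [r.patient_id for r in records])
    mask.to_csv(out / "modality_mask.csv", index=False)

    if records[0].aligned_series is not None:
        rows = []
        n_vars = records[0].aligned_series.shape[1]
        for r in records:
            for step, vals in enumerate(r.aligned_series):
                rows.append([r.patient_id, step, *vals])
        pd.DataFrame(
            rows, columns=["patient_id", "grid_step", *[f"v{j}" for j in range(n_vars)]]
        ).to_csv(out / "aligned_series.csv", index=False)


def read_cohort(in_dir) -> list[MultimodalRecord]:
    src = Path(in_dir)
    labs = pd.read_csv(src / "labs.csv").set_index("patient_id")
    labels = pd.read_csv(src / "labels.csv").set_index("patient_id")["label"]
    mask = pd.read_csv(src / "modality_mask.csv").set_index("patient_id")
    series = pd.read_csv(src / "series.csv")
    embs = {
        name: pd.read_csv(src / f"{name}.csv") for name in ("ecg_emb", "note_emb")
    }
    aligned_path = src / "aligned_series.csv"
    aligned = pd.read_csv(aligned_path) if aligned_path.exists() else None

    records = []
    for pid in labs.index:
        p_series = series[series["patient_id"] == pid]
        raw = [
            RawSeries(vid, list(zip(grp["timestamp"], grp["value"])))
            for vid, grp in p_series.groupby("variable_id", sort=True)
        ]
        mats = {}
        for name, df in embs.items():
            sub = df[df["patient_id"] == pid].sort_values("token")
            mats[name] = sub.drop(columns=["patient_id", "token"]).to_numpy(dtype=float)
        rec = MultimodalRecord(
            patient_id=pid,
            lab=labs.loc[pid].to_numpy(dtype=float),
            series=raw,
            ecg_emb=mats["ecg_emb"],
            note_emb=mats["note_emb"],
            present={m: bool(mask.loc[pid, m]) for m in MODALITIES},
            label=int(labels.loc[pid]),
        )
        if aligned is not None:
            sub = aligned[aligned["patient_id"] == pid].sort_values("grid_step")
            rec.aligned_series = sub.drop(
                columns=["patient_id", "grid_step"]
            ).to_numpy(dtype=float)
        records.append(rec)
    return records
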