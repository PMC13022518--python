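"""Plain-text I/O for datasets, fit tables, and ROI time series."""

from __future__ import annotations

import numpy as np
import pandas as pd

DATASET_COLUMNS = ["subject", "block", "context", "pair", "valence", "trial",
                   "trial_in_pair", "choice", "outcome", "rt", "valid",
                   "condition"]


def write_dataset(dataset: pd.DataFrame, path, sep: str = ",") -> None:
    dataset[DATASET_COLUMNS].to_csv(path, sep=sep, index=False)


def read_dataset(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset file missing columns: {missing}")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_table(table: pd.DataFrame, path, sep: str = ",") -> None:
    table.to_csv(path, sep=sep, index=False)


def write_roi_series(ts, path, sep: str = ",") -> None:
    """ROI series as long-format text (subject, roi, trial, volume_time, value)."""
    rows = []
    for i in range(ts.n_trials):
        meta = ts.meta.iloc[i]
        for t, v in zip(ts.times, ts.data[i]):
            rows.append({"subject": meta["subject"], "roi": ts.roi,
                         "trial": meta["trial"], "volume_time": t, "value": v})
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_roi_series(path, meta: pd.DataFrame | None = None, sep: str = ","):
    """Rebuild an RoiTimeSeries from its long-format text form."""
    from .bold import RoiTimeSeries

    df = pd.read_csv(path, sep=sep)
    times = np.sort(df["volume_time"].unique())
    trials = df.drop_duplicates(["subject", "trial"])[["subject", "trial"]]
    data = np.empty((len(trials), len(times)))
    for i, (_, row) in enumerate(trials.iterrows()):
        sub = df[(df["subject"] == row["subject"]) & (df["trial"] == row["trial"])]
        data[i] = sub.sort_values("volume_time")["value"].to_numpy()
    meta = meta if meta is not None else trials.reset_index(drop=True)
    return RoiTimeSeries(roi=str(df["roi"].iloc[0]), times=times, data=data,
                         meta=meta)
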