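"""Long-format event datasets: dosing regimens, concentration and SOWS records.

The on-disk form is a plain CSV with one row per event and a fixed column
order (subject, event, time, amount, tau, conc, blq, sows); `#`-prefixed
header comments carry provenance (generator seed / config hash).  Rows are
one of three event types:

  dose : one per subject, describing the steady-state regimen (amount, tau)
  conc : plasma concentration (ng/ml) at `time` hours after the last dose,
         with a BLQ flag for values below the 5 ng/ml quantification limit
  sows : SOWS withdrawal total (integer 0-64) at `time` hours after the dose
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pk import DoseRegimen

__all__ = ["LLOQ", "EventDataset", "read_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

#: lower limit of quantification of the plasma assay, ng/ml
LLOQ = 5.0

COLUMNS = ["subject", "event", "time", "amount", "tau", "conc", "blq", "sows"]
EVENTS = {"dose", "conc", "sows"}


class DatasetError(ValueError):
    """Structured parse/validation error naming the offending row and column."""

    def __init__(self, row, column, message):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column {column!r}: {message}")


@dataclass
class EventDataset:
    """Validated cohort of dosing, concentration and SOWS records."""

    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.events.copy()
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        extra = set(df.columns) - set(COLUMNS)
        if extra:
            raise DatasetError("-", sorted(extra)[0], "unknown column")
        df = df[COLUMNS].reset_index(drop=True)
        df["blq"] = df["blq"].astype("boolean").fillna(False).astype(bool)
        self._validate(df)
        self.events = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        for i, row in df.iterrows():
            if row["event"] not in EVENTS:
                raise DatasetError(i, "event", f"unknown event type {row['event']!r}")
            t = row["time"]
            if not np.isfinite(t) or t < 0:
                raise DatasetError(i, "time", f"negative or non-numeric time {t!r}")
            if row["event"] == "dose":
                if not np.isfinite(row["amount"]) or row["amount"] < 0:
                    raise DatasetError(i, "amount", "dose amount must be >= 0")
                if not np.isfinite(row["tau"]) or row["tau"] <= 0:
                    raise DatasetError(i, "tau", "dosing interval must be > 0")
            elif row["event"] == "conc":
                if not np.isfinite(row["conc"]) or row["conc"] < 0:
                    raise DatasetError(i, "conc", "concentration must be >= 0")
            else:  # sows
                s = row["sows"]
                if not np.isfinite(s) or not (0 <= s <= 64) or s != int(s):
                    raise DatasetError(i, "sows", f"SOWS total must be an integer in [0, 64], got {s!r}")
        for subj, grp in df.groupby("subject"):
            ndose = int((grp["event"] == "dose").sum())
            if ndose != 1:
                raise DatasetError("-", "event", f"subject {subj!r} has {ndose} dose rows, expected 1")
            tau = float(grp.loc[grp["event"] == "dose", "tau"].iloc[0])
            obs = grp[grp["event"] != "dose"]
            if (obs["time"] > tau).any():
                raise DatasetError("-", "time", f"subject {subj!r} has observation times beyond tau")

    # -- accessors ---------------------------------------------------------

    @property
    def subjects(self) -> list:
        return list(self.events["subject"].unique())

    def regimen(self, subject) -> DoseRegimen:
        row = self.events[(self.events["subject"] == subject) & (self.events["event"] == "dose")].iloc[0]
        return DoseRegimen(dose=float(row["amount"]), tau=float(row["tau"]))

    def conc_records(self, subject, include_blq: bool = False) -> pd.DataFrame:
        sel = (self.events["subject"] == subject) & (self.events["event"] == "conc")
        df = self.events[sel]
        if not include_blq:
            df = df[~df["blq"]]
        return df[["time", "conc", "blq"]].reset_index(drop=True)

    def sows_records(self, subject=None) -> pd.DataFrame:
        sel = self.events["event"] == "sows"
        if subject is not None:
            sel &= self.events["subject"] == subject
        return (
            self.events[sel][["subject", "time", "sows"]]
            .astype({"sows": float})
            .reset_index(drop=True)
        )

    def doses(self) -> pd.Series:
        df = self.events[self.events["event"] == "dose"]
        return df.set_index("subject")["amount"].astype(float)

    def troughs(self) -> pd.Series:
        """Pre-dose (t = 0) plasma concentrations per subject."""
        df = self.events[(self.events["event"] == "conc") & (self.events["time"] == 0)]
        return df.set_index("subject")["conc"].astype(float)


def read_dataset(path) -> EventDataset:
    """Read an event CSV; concentrations below the LLOQ are auto-flagged BLQ."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("#").strip().split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    if "subject" not in df.columns:
        raise DatasetError("-", "subject", "header row missing")
    for col in ("time", "amount", "tau", "conc", "sows"):
        if col in df.columns and df[col].notna().any() \
                and not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "-"
            raise DatasetError(row, col, "non-numeric field")
    if "blq" not in df.columns:
        df["blq"] = False
    df["blq"] = df["blq"].astype("boolean").fillna(False).astype(bool)
    low = (df["event"] == "conc") & (df["conc"] < LLOQ) & ~df["blq"]
    if low.any():
        logger.info("flagging %d concentration records below LLOQ=%g ng/ml", int(low.sum()), LLOQ)
        df.loc[low, "blq"] = True
    return EventDataset(events=df, meta=meta)


def write_dataset(ds: EventDataset, path) -> None:
    """Write the event CSV with `# key = value` provenance comments."""
    with open(path, "w") as fh:
        for k, v in ds.meta.items():
            fh.write(f"# {k} = {v}\n")
        ds.events.to_csv(fh, index=False, lineterminator="\n")
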