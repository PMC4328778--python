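"""Delimited-text formats: encounter histories, schedules, samples, manifests.

One CSV dialect throughout: comma-separated, UTF-8, ``.`` decimal, times in
days.  Encounter files carry one row per individual:

    id,type,entry,last_alive,first_dead,history,<covariate columns...>

``type`` is ``radio`` or ``marked``; an empty ``first_dead`` means right
censored (``inf``); ``history`` is a 0/1 string over the surveys after entry
(marked animals); empty covariate cells are missing values.  A marked row may
alternatively carry ``nn``/``ns`` columns (sighting count and 1-based index
of the last-seen survey) instead of the full history.  Survey schedules live
in a sidecar CSV of ``name,value`` pairs (``survey`` rows plus ``study_end``).
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import MarkRecord, RadioRecord, SurveySchedule

__all__ = [
    "read_encounter_csv",
    "write_encounter_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "RunManifest",
]

_RESERVED = {"id", "type", "entry", "last_alive", "first_dead", "history",
             "nn", "ns"}


def write_schedule_csv(path, schedule: SurveySchedule) -> None:
    rows = [{"name": "survey", "value": t} for t in schedule.stimes]
    rows.append({"name": "study_end", "value": schedule.study_end})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_schedule_csv(path) -> SurveySchedule:
    frame = pd.read_csv(path)
    stimes = frame.loc[frame["name"] == "survey", "value"].to_numpy(float)
    end = frame.loc[frame["name"] == "study_end", "value"]
    if end.empty:
        raise ValueError(f"{path}: schedule file lacks a study_end row")
    return SurveySchedule(stimes=stimes, study_end=float(end.iloc[0]))


def write_encounter_csv(path, radio_records, mark_records,
                        schedule: SurveySchedule) -> None:
    cov_names = sorted(
        {k for r in list(radio_records) + list(mark_records)
         for k in r.covariates}
    )
    rows = []
    for r in radio_records:
        row = {
            "id": r.ident or f"radio_{len(rows)}",
            "type": "radio",
            "entry": r.entry,
            "last_alive": r.last_alive,
            "first_dead": "" if not np.isfinite(r.first_dead) else r.first_dead,
            "history": "",
        }
        for k in cov_names:
            v = r.covariates.get(k)
            row[k] = "" if v is None else v
        rows.append(row)
    for m in mark_records:
        if m.history is not None:
            hist = "".join(str(int(h)) for h in m.history)
        else:
            hist = ""
        row = {
            "id": m.ident or f"marked_{len(rows)}",
            "type": "marked",
            "entry": m.entry,
            "last_alive": "" if m.last_seen is None else m.last_seen,
            "first_dead": "" if not np.isfinite(m.first_dead) else m.first_dead,
            "history": hist,
            "nn": m.n_sightings,
        }
        for k in cov_names:
            v = m.covariates.get(k)
            row[k] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _row_error(i, ident, msg) -> ValueError:
    return ValueError(f"row {i} (id={ident}): {msg}")


def read_encounter_csv(
    path, schedule: SurveySchedule
) -> tuple[list[RadioRecord], list[MarkRecord]]:
    """Parse and validate an encounter-history CSV against a schedule.

    Raises row-addressed ``ValueError``s for inconsistent intervals,
    malformed histories, or unknown ``type`` values.
    """
    frame = pd.read_csv(path, dtype={"history": str}, keep_default_na=False)
    cov_names = [c for c in frame.columns if c not in _RESERVED]
    radio_records, mark_records = [], []
    for i, row in frame.iterrows():
        ident = str(row["id"])
        cov = {}
        for k in cov_names:
            raw = row[k]
            cov[k] = None if raw == "" else float(raw)
        entry = float(row["entry"])
        first_dead = (
            np.inf if row["first_dead"] == "" else float(row["first_dead"])
        )
        kind = str(row["type"]).strip().lower()
        if kind == "radio":
            last_alive = float(row["last_alive"])
            if np.isfinite(first_dead) and first_dead <= last_alive:
                raise _row_error(i, ident, "first_dead must exceed last_alive")
            radio_records.append(
                RadioRecord(entry=entry, last_alive=last_alive,
                            first_dead=first_dead, covariates=cov, ident=ident)
            )
        elif kind == "marked":
            hist = str(row.get("history", "") or "")
            if hist:
                expected = schedule.surveys_in(entry, schedule.study_end).size
                if len(hist) != expected:
                    raise _row_error(
                        i, ident,
                        f"history length {len(hist)} != surveys after entry "
                        f"({expected})",
                    )
                try:
                    bits = [int(ch) for ch in hist]
                except ValueError:
                    raise _row_error(i, ident, "history must be a 0/1 string")
                rec = MarkRecord.from_history(
                    entry, bits, schedule, first_dead=first_dead,
                    covariates=cov, ident=ident,
                )
                if row.get("nn", "") != "" and int(float(row["nn"])) != rec.n_sightings:
                    raise _row_error(
                        i, ident, "nn column inconsistent with history"
                    )
            else:
                nn = int(float(row["nn"])) if row.get("nn", "") != "" else 0
                if row.get("ns", "") != "":
                    ns = int(float(row["ns"]))
                    if not 1 <= ns <= schedule.n_surveys:
                        raise _row_error(i, ident, "ns outside survey range")
                    last_seen = float(schedule.stimes[ns - 1])
                elif row.get("last_alive", "") != "":
                    last_seen = float(row["last_alive"])
                else:
                    last_seen = None
                if (last_seen is None) != (nn == 0):
                    raise _row_error(i, ident, "nn inconsistent with last_seen")
                rec = MarkRecord(
                    entry=entry, last_seen=last_seen, n_sightings=nn,
                    first_dead=first_dead, covariates=cov, ident=ident,
                )
            mark_records.append(rec)
        else:
            raise _row_error(i, ident, f"unknown type {row['type']!r}")
    return radio_records, mark_records


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's outputs exactly."""

    config: dict
    master_seed: int
    replicate_seeds: list = field(default_factory=list)
    version: str = "0.1.0"
    timestamp: str = field(
        default_factory=lambda: _time.strftime("%Y-%m-%dT%H:%M:%S")
    )
    acceptance_rates: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
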