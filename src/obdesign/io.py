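"""Patient-level delimited-text input/output.

Long-format observations CSV: patient_id, dose_index, obs_time, eff_flag,
tox_flag.  Events CSV: patient_id, event_type, event_time, attributes
(semicolon-separated key=value pairs, optional).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .estimand import ICEvent, Observation, PatientRecord

__all__ = ["read_patient_records", "write_patient_records"]

PathLike = Union[str, Path]


def _parse_attributes(text: object) -> dict[str, str]:
    if not isinstance(text, str) or not text.strip():
        return {}
    out = {}
    for part in text.split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_patient_records(
    observations_csv: PathLike, events_csv: Optional[PathLike] = None
) -> list[PatientRecord]:
    """Assemble PatientRecords from observation and (optional) event files."""
    obs = pd.read_csv(observations_csv, dtype={"patient_id": str})
    required = {"patient_id", "dose_index", "obs_time", "eff_flag", "tox_flag"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observations file missing columns: {sorted(missing)}")

    events_by_pid: dict[str, list[ICEvent]] = {}
    if events_csv is not None:
        ev = pd.read_csv(events_csv, dtype={"patient_id": str})
        req = {"patient_id", "event_type", "event_time"}
        missing = req - set(ev.columns)
        if missing:
            raise ValueError(f"events file missing columns: {sorted(missing)}")
        for row in ev.itertuples(index=False):
            events_by_pid.setdefault(row.patient_id, []).append(
                ICEvent(
                    type=row.event_type,
                    time=float(row.event_time),
                    attributes=_parse_attributes(getattr(row, "attributes", "")),
                )
            )

    records = []
    for pid, group in obs.groupby("patient_id", sort=True):
        doses = group["dose_index"].unique()
        if len(doses) != 1:
            raise ValueError(f"patient {pid} appears at multiple doses {doses.tolist()}")
        records.append(
            PatientRecord(
                patient_id=str(pid),
                dose_index=int(doses[0]),
                observations=tuple(
                    Observation(float(r.obs_time), int(r.eff_flag), int(r.tox_flag))
                    for r in group.itertuples(index=False)
                ),
                events=tuple(events_by_pid.get(str(pid), ())),
                pending=bool(group["pending"].iloc[0]) if "pending" in group else False,
            )
        )
    return records


def write_patient_records(
    records: Sequence[PatientRecord],
    observations_csv: PathLike,
    events_csv: Optional[PathLike] = None,
) -> None:
    """Write records back to the long-format CSV pair."""
    obs_rows = [
        {
            "patient_id": r.patient_id,
            "dose_index": r.dose_index,
            "obs_time": o.time,
            "eff_flag": o.efficacy,
            "tox_flag": o.toxicity,
            "pending": int(r.pending),
        }
        for r in records
        for o in r.observations
    ]
    pd.DataFrame(obs_rows).to_csv(observations_csv, index=False)
    if events_csv is not None:
        ev_rows = [
            {
                "patient_id": r.patient_id,
                "event_type": e.type,
                "event_time": e.time,
                "attributes": ";".join(f"{k}={v}" for k, v in e.attributes.items()),
            }
            for r in records
            for e in r.events
        ]
        pd.DataFrame(
            ev_rows, columns=["patient_id", "event_type", "event_time", "attributes"]
        ).to_csv(events_csv, index=False)
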