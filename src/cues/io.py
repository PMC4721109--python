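"""Respondent (de)serialization: JSON objects, JSON Lines batches, CSV export."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .errors import CuesError
from .questionnaire import (
    BehaviorSet,
    ExposureEpoch,
    ResidencePeriod,
    Respondent,
)

__all__ = [
    "respondent_to_dict",
    "respondent_from_dict",
    "read_respondents_jsonl",
    "write_respondents_jsonl",
    "flatten_respondents",
]


def _behaviors_to_dict(b: BehaviorSet) -> dict:
    return {
        "tanning_bed_visits": b.tanning_bed_visits,
        "blistering_sunburns": b.blistering_sunburns,
        "sunscreen": b.sunscreen,
        "long_sleeves": b.long_sleeves,
        "hat": b.hat,
        "shade_seeking": b.shade_seeking,
    }


def respondent_to_dict(r: Respondent) -> dict:
    out = {
        "id": r.id,
        "age": r.age,
        "fitzpatrick": r.fitzpatrick,
        "personal_hx": r.personal_hx,
        "dx_age": r.dx_age,
        "dx_type": r.dx_type,
        "family_hx": sorted(r.family_hx),
        "behaviors_before": _behaviors_to_dict(r.behaviors_before),
        "behaviors_after": (
            _behaviors_to_dict(r.behaviors_after) if r.behaviors_after else None
        ),
        "epochs": [
            {
                "age_band": e.age_band,
                "weekday_hours_per_day": e.weekday_hours_per_day,
                "weekend_hours_per_day": e.weekend_hours_per_day,
            }
            for e in r.epochs
        ],
        "residences": [
            {"place": p.place, "start_age": p.start_age, "end_age": p.end_age}
            for p in r.residences
        ],
    }
    return out


def respondent_from_dict(d: dict) -> Respondent:
    try:
        return Respondent(
            id=d.get("id"),
            age=int(d["age"]),
            fitzpatrick=int(d["fitzpatrick"]),
            personal_hx=bool(d["personal_hx"]),
            dx_age=d.get("dx_age"),
            dx_type=d.get("dx_type"),
            family_hx=frozenset(d.get("family_hx") or ()),
            behaviors_before=BehaviorSet(**d["behaviors_before"]),
            behaviors_after=(
                BehaviorSet(**d["behaviors_after"]) if d.get("behaviors_after") else None
            ),
            epochs=[ExposureEpoch(**e) for e in d["epochs"]],
            residences=[ResidencePeriod(**p) for p in d["residences"]],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CuesError(f"malformed respondent record: {exc}") from exc


def read_respondents_jsonl(path: Union[str, Path]) -> list[Respondent]:
    """Read one respondent JSON object per line."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CuesError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            out.append(respondent_from_dict(d))
    return out


def write_respondents_jsonl(respondents: Iterable[Respondent], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in respondents:
            fh.write(json.dumps(respondent_to_dict(r), sort_keys=True) + "\n")


def flatten_respondents(respondents: Iterable[Respondent]) -> pd.DataFrame:
    """Flat per-respondent table of scalar fields (for CSV export)."""
    rows = []
    for r in respondents:
        row = {
            "id": r.id,
            "age": r.age,
            "fitzpatrick": r.fitzpatrick,
            "personal_hx": r.personal_hx,
            "dx_age": r.dx_age,
            "dx_type": r.dx_type,
            "family_hx": ";".join(sorted(r.family_hx)),
            "n_residences": len(r.residences),
        }
        row.update({f"before_{k}": v for k, v in _behaviors_to_dict(r.behaviors_before).items()})
        rows.append(row)
    return pd.DataFrame(rows)


def respondent_schema() -> dict:
    """The JSON Schema for serialized respondent records (shipped with the
    package as ``data/respondent.schema.json``)."""
    from importlib import resources

    return json.loads(
        (resources.files("cues.data") / "respondent.schema.json").read_text()
    )
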