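"""CSV/JSON I/O for records, questionnaire answers and run provenance.

Wide record CSV (one row per respondent x device):
``respondent_id, stratum, group, device, sub1..sub5, gus_total`` — sub-score
columns optional when only totals are available; when present the total is
recomputed and cross-checked.

Long answer CSV (one row per respondent x device x item):
``respondent_id, stratum, group, device, item, value``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from importlib import metadata

import pandas as pd

from .devices import canonical_device, canonical_stratum
from .errors import RecordIntegrityError
from .scoring import GUSRecord, GUS_MAX, QuestionnaireResponse

SUB_COLS = [f"sub{i}" for i in range(1, 6)]
REQUIRED_COLS = ["respondent_id", "stratum", "group", "device"]


def _maybe_int(x: float):
    return int(x) if float(x).is_integer() else float(x)


def load_records(path) -> list[GUSRecord]:
    """Read and validate a wide record CSV.

    Device/stratum names are trimmed and canonicalized; an unknown device or
    a total disagreeing with its sub-scores raises
    :class:`RecordIntegrityError` naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise RecordIntegrityError(f"missing required columns: {missing}")
    has_subs = all(c in df.columns for c in SUB_COLS)
    if not has_subs and "gus_total" not in df.columns:
        raise RecordIntegrityError("need either sub1..sub5 or gus_total columns")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            device = canonical_device(str(row.device))
            stratum = canonical_stratum(str(row.stratum))
        except ValueError as exc:
            raise RecordIntegrityError(f"row {row_no}: {exc}") from exc
        if has_subs:
            subs = tuple(_maybe_int(getattr(row, c)) for c in SUB_COLS)
            total = sum(subs)
            if "gus_total" in df.columns and not pd.isna(row.gus_total):
                stated = _maybe_int(row.gus_total)
                if stated != total:
                    raise RecordIntegrityError(
                        f"row {row_no}: gus_total {stated} != sum of sub-scores {total}"
                    )
        else:
            total = _maybe_int(row.gus_total)
            subs = None
        if not 0 <= total <= GUS_MAX:
            raise RecordIntegrityError(
                f"row {row_no}: gus_total {total} outside [0, {GUS_MAX}]"
            )
        if subs is None:
            # only the total is known; park it on box 5 to honour the
            # total-equals-sum invariant (box-level analyses need sub columns)
            subs = (0, 0, 0, 0, total)
        records.append(
            GUSRecord(
                respondent_id=str(row.respondent_id),
                stratum=stratum,
                group=int(row.group),
                device=device,
                subscores=subs,  # type: ignore[arg-type]
                gus_total=total,
            )
        )
    return records


def records_frame(records: list[GUSRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "respondent_id": r.respondent_id,
            "stratum": r.stratum,
            "group": r.group,
            "device": r.device,
        }
        row.update({c: s for c, s in zip(SUB_COLS, r.subscores)})
        row["gus_total"] = r.gus_total
        rows.append(row)
    return pd.DataFrame(rows, columns=REQUIRED_COLS + SUB_COLS + ["gus_total"])


def save_records(records: list[GUSRecord], path) -> None:
    records_frame(records).to_csv(path, index=False)


def answers_frame(responses: list[QuestionnaireResponse]) -> pd.DataFrame:
    rows = []
    for resp in responses:
        for device, items in resp.answers.items():
            for item, value in items.items():
                rows.append(
                    {
                        "respondent_id": resp.respondent_id,
                        "stratum": resp.stratum,
                        "group": resp.group,
                        "device": device,
                        "item": item,
                        "value": value,
                    }
                )
    return pd.DataFrame(
        rows, columns=["respondent_id", "stratum", "group", "device", "item", "value"]
    )


def save_answers(responses: list[QuestionnaireResponse], path) -> None:
    answers_frame(responses).to_csv(path, index=False)


def load_answers(path) -> list[QuestionnaireResponse]:
    df = pd.read_csv(path)
    out: dict[str, QuestionnaireResponse] = {}
    grouped: dict[str, dict] = {}
    meta: dict[str, tuple[str, int]] = {}
    for row in df.itertuples(index=False):
        rid = str(row.respondent_id)
        device = canonical_device(str(row.device))
        grouped.setdefault(rid, {}).setdefault(device, {})[str(row.item)] = row.value
        meta[rid] = (canonical_stratum(str(row.stratum)), int(row.group))
    return [
        QuestionnaireResponse(
            respondent_id=rid, stratum=meta[rid][0], group=meta[rid][1], answers=answers
        )
        for rid, answers in grouped.items()
    ]


def package_version() -> str:
    try:
        return metadata.version("dpi-usability")
    except metadata.PackageNotFoundError:
        return "unknown"


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, *, seed: int, config: dict, extra: dict | None = None) -> None:
    payload = {
        "package": "dpi-usability",
        "version": package_version(),
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
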