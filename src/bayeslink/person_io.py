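"""Readers and writers for person files, hashed files, and results.

Plaintext person files are CSV (RFC 4180, header required, multi-valued
identifiers as numbered columns ``forename_1``, ``forename_1_start``, …)
or JSON Lines (one object per person with list-valued fields).  Hashed
files are JSON Lines with a leading header object carrying a format
version and the file mode ("proband" files must carry frequencies,
"sample" files need not).  All files are UTF-8; dates are ISO 8601.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable

from .engine import LinkageResult
from .records import (
    DatedValue,
    HashedDob,
    HashedGender,
    HashedName,
    HashedPersonRecord,
    HashedPostcode,
    HashedSurname,
    PersonRecord,
)

__all__ = [
    "ParseError", "FileReadResult", "SchemaError",
    "read_plaintext_file", "write_plaintext_csv", "write_plaintext_jsonl",
    "read_hashed_file", "write_hashed_file", "write_results",
]

HASHED_FORMAT = "bayeslink-hashed"
HASHED_VERSION = 1

GENDER_CODES = {"F", "M", "X"}


@dataclass(frozen=True)
class ParseError:
    """One unparseable row, recorded without aborting the run."""
    row: int
    message: str


@dataclass
class FileReadResult:
    records: list
    errors: list[ParseError]


class SchemaError(ValueError):
    """A hashed file violates its schema; names the offending field."""


def _parse_date(text: str | None) -> date | None:
    if text is None or text == "":
        return None
    return date.fromisoformat(text)


def _parse_gender(text: str | None) -> str | None:
    if text is None or text == "":
        return None
    code = text.strip().upper()
    if code not in GENDER_CODES:
        raise ValueError(f"gender must be one of F/M/X or empty, got {text!r}")
    return code


# ---------------------------------------------------------------------------
# Plaintext person files
# ---------------------------------------------------------------------------

def _record_from_json(obj: dict) -> PersonRecord:
    def dated_list(key: str) -> list[DatedValue]:
        out = []
        for item in obj.get(key) or []:
            if isinstance(item, str):
                out.append(DatedValue(item))
            else:
                out.append(DatedValue(item["value"],
                                      _parse_date(item.get("start_date")),
                                      _parse_date(item.get("end_date"))))
        return out

    local_id = obj.get("local_id")
    if not local_id:
        raise ValueError("missing local_id")
    return PersonRecord(
        local_id=str(local_id),
        forenames=dated_list("forenames"),
        surnames=dated_list("surnames"),
        dob=_parse_date(obj.get("dob")),
        gender=_parse_gender(obj.get("gender")),
        postcodes=dated_list("postcodes"),
        perfect_ids={str(k): str(v) for k, v in (obj.get("perfect_ids") or {}).items()},
        payload=obj.get("payload"),
    )


def _record_from_csv_row(row: dict[str, str]) -> PersonRecord:
    def dated_list(prefix: str) -> list[DatedValue]:
        out = []
        i = 1
        while f"{prefix}_{i}" in row:
            value = (row.get(f"{prefix}_{i}") or "").strip()
            if value:
                out.append(DatedValue(value,
                                      _parse_date(row.get(f"{prefix}_{i}_start")),
                                      _parse_date(row.get(f"{prefix}_{i}_end"))))
            i += 1
        return out

    local_id = (row.get("local_id") or "").strip()
    if not local_id:
        raise ValueError("missing local_id")
    perfect_ids = {key[len("perfect_id_"):]: value.strip()
                   for key, value in row.items()
                   if key.startswith("perfect_id_") and value and value.strip()}
    payload_text = (row.get("payload") or "").strip()
    return PersonRecord(
        local_id=local_id,
        forenames=dated_list("forename"),
        surnames=dated_list("surname"),
        dob=_parse_date((row.get("dob") or "").strip() or None),
        gender=_parse_gender(row.get("gender")),
        postcodes=dated_list("postcode"),
        perfect_ids=perfect_ids,
        payload=json.loads(payload_text) if payload_text else None,
    )


def read_plaintext_file(path: str | Path, dialect: str | None = None) -> FileReadResult:
    """Read a plaintext person file; dialect "csv"/"jsonl" or by extension.

    Unparseable rows are collected into the error report with their row
    number; the read is fatal only if rows were present but none parsed.
    """
    path = Path(path)
    if dialect is None:
        dialect = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson", ".json") else "csv"
    if dialect not in ("csv", "jsonl"):
        raise ValueError(f"dialect must be 'csv' or 'jsonl', got {dialect!r}")

    records: list[PersonRecord] = []
    errors: list[ParseError] = []
    saw_rows = False
    with open(path, encoding="utf-8", newline="") as fh:
        if dialect == "csv":
            for row_number, row in enumerate(csv.DictReader(fh), start=2):
                saw_rows = True
                try:
                    records.append(_record_from_csv_row(row))
                except Exception as exc:
                    errors.append(ParseError(row_number, str(exc)))
        else:
            for row_number, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                saw_rows = True
                try:
                    records.append(_record_from_json(json.loads(line)))
                except Exception as exc:
                    errors.append(ParseError(row_number, str(exc)))
    if saw_rows and not records:
        raise ValueError(f"no valid records in {path}: "
                         f"first error: row {errors[0].row}: {errors[0].message}")
    return FileReadResult(records=records, errors=errors)


def _dated_to_json(values: list[DatedValue]) -> list[dict]:
    return [{"value": dv.value,
             "start_date": dv.start_date.isoformat() if dv.start_date else None,
             "end_date": dv.end_date.isoformat() if dv.end_date else None}
            for dv in values]


def write_plaintext_jsonl(records: Iterable[PersonRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps({
                "local_id": record.local_id,
                "forenames": _dated_to_json(record.forenames),
                "surnames": _dated_to_json(record.surnames),
                "dob": record.dob.isoformat() if record.dob else None,
                "gender": record.gender,
                "postcodes": _dated_to_json(record.postcodes),
                "perfect_ids": record.perfect_ids,
                "payload": record.payload,
            }, ensure_ascii=False) + "\n")


def write_plaintext_csv(records: list[PersonRecord], path: str | Path) -> None:
    counts = {prefix: max((len(getattr(r, attr)) for r in records), default=0) or 1
              for prefix, attr in (("forename", "forenames"),
                                   ("surname", "surnames"),
                                   ("postcode", "postcodes"))}
    perfect_names = sorted({name for r in records for name in r.perfect_ids})
    header = ["local_id", "dob", "gender"]
    for prefix in ("forename", "surname", "postcode"):
        for i in range(1, counts[prefix] + 1):
            header += [f"{prefix}_{i}", f"{prefix}_{i}_start", f"{prefix}_{i}_end"]
    header += [f"perfect_id_{name}" for name in perfect_names] + ["payload"]

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            row = [r.local_id, r.dob.isoformat() if r.dob else "", r.gender or ""]
            for prefix, attr in (("forename", "forenames"), ("surname", "surnames"),
                                 ("postcode", "postcodes")):
                values = getattr(r, attr)
                for i in range(counts[prefix]):
                    if i < len(values):
                        dv = values[i]
                        row += [dv.value,
                                dv.start_date.isoformat() if dv.start_date else "",
                                dv.end_date.isoformat() if dv.end_date else ""]
                    else:
                        row += ["", "", ""]
            row += [r.perfect_ids.get(name, "") for name in perfect_names]
            row.append(json.dumps(r.payload) if r.payload is not None else "")
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Hashed files (JSONL with header line)
# ---------------------------------------------------------------------------

def _hashed_name_to_json(hn: HashedName) -> dict:
    return {"name": hn.name, "metaphone": hn.metaphone, "f2c": hn.f2c,
            "name_freq": hn.name_freq, "metaphone_freq": hn.metaphone_freq,
            "f2c_freq": hn.f2c_freq,
            "start_date": hn.start_date.isoformat() if hn.start_date else None,
            "end_date": hn.end_date.isoformat() if hn.end_date else None}


def _hashed_name_from_json(obj: dict, mode: str, where: str) -> HashedName:
    for key in ("name", "metaphone", "f2c"):
        if not isinstance(obj.get(key), str):
            raise SchemaError(f"{where}.{key}: missing digest")
    if mode == "proband":
        for key in ("name_freq", "metaphone_freq", "f2c_freq"):
            if not isinstance(obj.get(key), (int, float)):
                raise SchemaError(f"{where}.{key}: frequency required in a proband file")
    return HashedName(
        name=obj["name"], metaphone=obj["metaphone"], f2c=obj["f2c"],
        name_freq=obj.get("name_freq"), metaphone_freq=obj.get("metaphone_freq"),
        f2c_freq=obj.get("f2c_freq"),
        start_date=_parse_date(obj.get("start_date")),
        end_date=_parse_date(obj.get("end_date")))


def write_hashed_file(records: Iterable[HashedPersonRecord], path: str | Path,
                      mode: str | None = None) -> None:
    """Write hashed records as JSONL with a leading format-header line."""
    records = list(records)
    if mode is None:
        mode = records[0].mode if records else "sample"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"format": HASHED_FORMAT, "version": HASHED_VERSION,
                             "mode": mode}) + "\n")
        for r in records:
            obj = {
                "local_id": r.local_id,
                "forenames": [_hashed_name_to_json(hn) for hn in r.forenames],
                "surnames": [{
                    "fragments": [_hashed_name_to_json(hn) for hn in hs.fragments],
                    "start_date": hs.start_date.isoformat() if hs.start_date else None,
                    "end_date": hs.end_date.isoformat() if hs.end_date else None,
                } for hs in r.surnames],
                "dob": ({"full": r.dob.full, "year_month": r.dob.year_month,
                         "month_day": r.dob.month_day, "year_day": r.dob.year_day}
                        if r.dob else None),
                "gender": ({"digest": r.gender.digest, "freq": r.gender.frequency}
                           if r.gender else None),
                "postcodes": [{
                    "unit": hp.unit, "sector": hp.sector, "pseudo": hp.pseudo,
                    "unit_freq": hp.unit_freq, "sector_freq": hp.sector_freq,
                    "start_date": hp.start_date.isoformat() if hp.start_date else None,
                    "end_date": hp.end_date.isoformat() if hp.end_date else None,
                } for hp in r.postcodes],
                "perfect_ids": r.perfect_ids,
                "payload": r.payload,
                "forename_error_rates": (list(r.forename_error_rates)
                                         if r.forename_error_rates else None),
                "surname_error_rates": (list(r.surname_error_rates)
                                        if r.surname_error_rates else None),
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_hashed_file(path: str | Path) -> list[HashedPersonRecord]:
    """Read a hashed JSONL file, validating against its declared mode."""
    records: list[HashedPersonRecord] = []
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid header line: {exc}") from exc
        if header.get("format") != HASHED_FORMAT:
            raise SchemaError(f"header.format: expected {HASHED_FORMAT!r}")
        mode = header.get("mode")
        if mode not in ("proband", "sample"):
            raise SchemaError("header.mode: must be 'proband' or 'sample'")
        for line_number, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            obj = json.loads(line)
            where = f"line {line_number}"
            local_id = obj.get("local_id")
            if not local_id:
                raise SchemaError(f"{where}.local_id: missing")
            forenames = [_hashed_name_from_json(fn, mode, f"{where}.forenames[{i}]")
                         for i, fn in enumerate(obj.get("forenames") or [])]
            surnames = []
            for i, hs in enumerate(obj.get("surnames") or []):
                fragments = tuple(
                    _hashed_name_from_json(fr, mode, f"{where}.surnames[{i}].fragments[{j}]")
                    for j, fr in enumerate(hs.get("fragments") or []))
                if not fragments:
                    raise SchemaError(f"{where}.surnames[{i}]: no fragments")
                surnames.append(HashedSurname(fragments=fragments,
                                              start_date=_parse_date(hs.get("start_date")),
                                              end_date=_parse_date(hs.get("end_date"))))
            dob = None
            if obj.get("dob") is not None:
                d = obj["dob"]
                for key in ("full", "year_month", "month_day", "year_day"):
                    if not isinstance(d.get(key), str):
                        raise SchemaError(f"{where}.dob.{key}: missing digest")
                dob = HashedDob(full=d["full"], year_month=d["year_month"],
                                month_day=d["month_day"], year_day=d["year_day"])
            gender = None
            if obj.get("gender") is not None:
                g = obj["gender"]
                if not isinstance(g.get("digest"), str):
                    raise SchemaError(f"{where}.gender.digest: missing")
                if mode == "proband" and not isinstance(g.get("freq"), (int, float)):
                    raise SchemaError(f"{where}.gender.freq: required in a proband file")
                gender = HashedGender(digest=g["digest"], frequency=g.get("freq"))
            postcodes = []
            for i, hp in enumerate(obj.get("postcodes") or []):
                if not isinstance(hp.get("unit"), str) or not isinstance(hp.get("sector"), str):
                    raise SchemaError(f"{where}.postcodes[{i}]: missing digest")
                pseudo = bool(hp.get("pseudo"))
                if mode == "proband" and not pseudo and \
                        not isinstance(hp.get("unit_freq"), (int, float)):
                    raise SchemaError(f"{where}.postcodes[{i}].unit_freq: "
                                      "required in a proband file")
                postcodes.append(HashedPostcode(
                    unit=hp["unit"], sector=hp["sector"], pseudo=pseudo,
                    unit_freq=hp.get("unit_freq"), sector_freq=hp.get("sector_freq"),
                    start_date=_parse_date(hp.get("start_date")),
                    end_date=_parse_date(hp.get("end_date"))))
            forename_rates = obj.get("forename_error_rates")
            surname_rates = obj.get("surname_error_rates")
            if mode == "proband":
                if forename_rates is None or surname_rates is None:
                    raise SchemaError(f"{where}: error-rate triples required "
                                      "in a proband file")
            records.append(HashedPersonRecord(
                local_id=str(local_id), mode=mode,
                forenames=forenames, surnames=surnames, dob=dob, gender=gender,
                postcodes=postcodes,
                perfect_ids={str(k): str(v)
                             for k, v in (obj.get("perfect_ids") or {}).items()},
                payload=obj.get("payload"),
                forename_error_rates=tuple(forename_rates) if forename_rates else None,
                surname_error_rates=tuple(surname_rates) if surname_rates else None))
    return records


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results(results: list[LinkageResult], path: str | Path,
                  include_leader: bool = False) -> None:
    """One row per proband: declared match, scores, decision basis.

    ``include_leader`` adds the best candidate's ID even when no winner was
    declared (the validation option used to study threshold effects).
    """
    def fmt(x: float | None) -> str:
        if x is None:
            return ""
        return repr(x)

    header = ["proband_local_id", "match_local_id", "leader_log_odds",
              "runner_up_log_odds", "basis"]
    if include_leader:
        header.append("leader_local_id")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in results:
            row = [r.proband_local_id, r.match_local_id or "",
                   fmt(r.leader_log_odds), fmt(r.runner_up_log_odds), r.basis]
            if include_leader:
                row.append(r.leader_local_id or "")
            writer.writerow(row)
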