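"""Reading and writing the spectra CSV interchange dialect.

One row per (subject, visit, condition, frequency): columns
``subject_id, group, visit, condition, frequency_hz, resistance, reactance``
— comma-separated, dot decimals, UTF-8, regardless of locale. Readers
validate, reject duplicates naming the offending row, and sort records
canonically so downstream results are order-invariant.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import CohortDataset, SubjectVisit
from .models import ImpedanceSpectrum, InvalidInputError

__all__ = ["COLUMNS", "read_spectra", "write_spectra", "dataset_frame", "ParseError"]

COLUMNS = ("subject_id", "group", "visit", "condition", "frequency_hz", "resistance", "reactance")
_GROUPS = ("H", "SAI")
_VISITS = (2006, 2008)
_CONDITIONS = ("preB", "postB")


class ParseError(InvalidInputError):
    """Malformed spectra CSV; message names the first offending row."""


def dataset_frame(dataset: CohortDataset) -> pd.DataFrame:
    """Long-format frame of a dataset (one row per frequency point)."""
    rows = []
    for rec in dataset.records:
        for f, r, x in zip(rec.spectrum.frequencies, rec.spectrum.resistance, rec.spectrum.reactance):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "visit": rec.visit,
                    "condition": rec.condition,
                    "frequency_hz": f,
                    "resistance": r,
                    "reactance": x,
                }
            )
    return pd.DataFrame(rows, columns=list(COLUMNS))


def write_spectra(dataset: CohortDataset, path) -> None:
    """Write a dataset in the spectra CSV dialect (full float precision)."""
    df = dataset_frame(dataset)
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_spectra(path) -> CohortDataset:
    """Read a spectra CSV into a dataset skeleton (no latent parameters).

    Validates column names, numeric cells, key uniqueness and positive
    frequencies; errors carry the 1-based data row number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")

    def fail(i: int, msg: str) -> None:
        raise ParseError(f"{path}: row {i + 1}: {msg}")

    parsed = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        if rec["group"] not in _GROUPS:
            fail(i, f"group must be one of {_GROUPS}, got {rec['group']!r}")
        if rec["condition"] not in _CONDITIONS:
            fail(i, f"condition must be one of {_CONDITIONS}, got {rec['condition']!r}")
        try:
            visit = int(rec["visit"])
        except ValueError:
            fail(i, f"non-numeric visit {rec['visit']!r}")
        if visit not in _VISITS:
            fail(i, f"visit must be one of {_VISITS}, got {visit}")
        nums = {}
        for col in ("frequency_hz", "resistance", "reactance"):
            try:
                nums[col] = float(rec[col])
            except ValueError:
                fail(i, f"non-numeric {col} {rec[col]!r}")
        if nums["frequency_hz"] <= 0:
            fail(i, f"non-positive frequency {nums['frequency_hz']}")
        parsed.append((rec["subject_id"], rec["group"], visit, rec["condition"], nums))

    seen: dict[tuple, int] = {}
    for i, (sid, _g, visit, cond, nums) in enumerate(parsed):
        key = (sid, visit, cond, nums["frequency_hz"])
        if key in seen:
            raise ParseError(
                f"{path}: row {i + 1}: duplicate key {key} (first at row {seen[key] + 1})"
            )
        seen[key] = i

    groups: dict[tuple, list] = {}
    for sid, group, visit, cond, nums in parsed:
        groups.setdefault((sid, group, visit, cond), []).append(nums)
    records = []
    for (sid, group, visit, cond) in sorted(groups, key=lambda k: (k[0], k[2], k[3])):
        pts = groups[(sid, group, visit, cond)]
        try:
            spec = ImpedanceSpectrum.from_unsorted(
                [p["frequency_hz"] for p in pts],
                [p["resistance"] for p in pts],
                [p["reactance"] for p in pts],
            )
        except InvalidInputError as exc:
            raise ParseError(f"{path}: record ({sid}, {visit}, {cond}): {exc}") from exc
        records.append(SubjectVisit(sid, group, visit, cond, None, spec))
    if not records:
        raise ParseError(f"{path}: no data rows")
    return CohortDataset(tuple(records))
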