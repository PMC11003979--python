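"""CSV readers and writers for the three study data layers.

All files are comma-separated UTF-8 with a required header and dot
decimals. Readers validate row by row, collecting offending line numbers;
by default any invalid row aborts the read, while ``skip_invalid=True``
drops the bad rows and reports them on the returned result. Survival
records use a wide layout with one ``bbb_d<N>`` column per assessment day
(blank = not assessed / dead).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .biodistribution import BoronMeasurement, CellUptakeRecord
from .efficacy import AnimalRecord

__all__ = [
    "InvalidDataError",
    "RowError",
    "ReadResult",
    "read_uptake",
    "read_biodistribution",
    "read_animals",
    "write_uptake",
    "write_biodistribution",
    "write_animals",
]

UPTAKE_HEADER = [
    "cell_line",
    "exposure_conc_ugB_per_mL",
    "exposure_h",
    "washout",
    "boron_mass_ug",
    "cell_count",
    "replicate",
]
BIODIST_HEADER = ["subject_id", "model", "tissue", "time_h", "conc_ugB_per_g"]
ANIMALS_FIXED_HEADER = ["subject_id", "group", "survival_days", "event"]


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


class InvalidDataError(ValueError):
    def __init__(self, path: Path, errors: list[RowError]):
        self.path = path
        self.errors = errors
        detail = "; ".join(f"line {e.line}: {e.message}" for e in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{path}: {len(errors)} invalid row(s): {detail}{more}")


@dataclass
class ReadResult:
    records: list
    errors: list[RowError] = field(default_factory=list)


def _open_rows(path: str | Path, expected_fixed: list[str], wide: bool = False):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"empty input file: {path}") from None
        if wide:
            if header[: len(expected_fixed)] != expected_fixed:
                raise ValueError(
                    f"{path}: malformed header; expected it to start with "
                    f"{expected_fixed}, got {header[: len(expected_fixed)]}"
                )
        elif header != expected_fixed:
            raise ValueError(
                f"{path}: malformed header; expected {expected_fixed}, got {header}"
            )
        rows = list(reader)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return header, rows


def _finish(path: Path, result: ReadResult, skip_invalid: bool) -> ReadResult:
    if result.errors and not skip_invalid:
        raise InvalidDataError(Path(path), result.errors)
    return result


def read_uptake(path: str | Path, skip_invalid: bool = False) -> ReadResult:
    """Read cellular-uptake records from ``uptake.csv``."""
    _, rows = _open_rows(path, UPTAKE_HEADER)
    result = ReadResult(records=[])
    for offset, row in enumerate(rows):
        line = offset + 2  # header is line 1
        try:
            result.records.append(
                CellUptakeRecord(
                    cell_line=row[0],
                    exposure_conc=float(row[1]),
                    exposure_h=float(row[2]),
                    washout=row[3].strip().lower() in ("1", "true", "yes"),
                    boron_mass=float(row[4]),
                    cell_count=int(row[5]),
                    replicate=int(row[6]),
                )
            )
        except (ValueError, IndexError) as exc:
            result.errors.append(RowError(line, str(exc)))
    return _finish(Path(path), result, skip_invalid)


def read_biodistribution(path: str | Path, skip_invalid: bool = False) -> ReadResult:
    """Read organ boron measurements from ``biodistribution.csv``."""
    _, rows = _open_rows(path, BIODIST_HEADER)
    result = ReadResult(records=[])
    for offset, row in enumerate(rows):
        line = offset + 2
        try:
            result.records.append(
                BoronMeasurement(
                    subject_id=row[0],
                    model=row[1],
                    tissue=row[2],
                    time_h=float(row[3]),
                    conc=float(row[4]),
                )
            )
        except (ValueError, IndexError) as exc:
            result.errors.append(RowError(line, str(exc)))
    return _finish(Path(path), result, skip_invalid)


def read_animals(path: str | Path, skip_invalid: bool = False) -> ReadResult:
    """Read animal survival/BBB records from wide-format ``animals.csv``."""
    header, rows = _open_rows(path, ANIMALS_FIXED_HEADER, wide=True)
    day_cols: list[tuple[int, int]] = []
    for i, name in enumerate(header[len(ANIMALS_FIXED_HEADER):], start=len(ANIMALS_FIXED_HEADER)):
        if not name.startswith("bbb_d"):
            raise ValueError(f"{path}: unexpected column {name!r}")
        day_cols.append((i, int(name[len("bbb_d"):])))
    result = ReadResult(records=[])
    for offset, row in enumerate(rows):
        line = offset + 2
        try:
            series = {}
            for col, day in day_cols:
                cell = row[col].strip() if col < len(row) else ""
                if cell:
                    series[day] = int(float(cell))
            result.records.append(
                AnimalRecord(
                    subject_id=row[0],
                    group=row[1],
                    survival_days=float(row[2]),
                    event=int(row[3]),
                    bbb_series=series,
                )
            )
        except (ValueError, IndexError) as exc:
            result.errors.append(RowError(line, str(exc)))
    return _finish(Path(path), result, skip_invalid)


def _write_rows(path: str | Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_uptake(path: str | Path, records: list[CellUptakeRecord]) -> None:
    _write_rows(
        path,
        UPTAKE_HEADER,
        [
            [
                r.cell_line,
                repr(float(r.exposure_conc)),
                repr(float(r.exposure_h)),
                int(r.washout),
                repr(float(r.boron_mass)),
                r.cell_count,
                r.replicate,
            ]
            for r in records
        ],
    )


def write_biodistribution(path: str | Path, records: list[BoronMeasurement]) -> None:
    _write_rows(
        path,
        BIODIST_HEADER,
        [
            [r.subject_id, r.model, r.tissue, repr(float(r.time_h)), repr(float(r.conc))]
            for r in records
        ],
    )


def write_animals(path: str | Path, records: list[AnimalRecord]) -> None:
    max_day = 0
    for r in records:
        if r.bbb_series:
            max_day = max(max_day, max(r.bbb_series))
    header = ANIMALS_FIXED_HEADER + [f"bbb_d{d}" for d in range(max_day + 1)]
    rows = []
    for r in records:
        row: list = [r.subject_id, r.group, repr(float(r.survival_days)), r.event]
        for d in range(max_day + 1):
            row.append(r.bbb_series.get(d, ""))
        rows.append(row)
    _write_rows(path, header, rows)
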