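"""96-well plate-reader matrix I/O, layout binding and control validation.

Plates follow the SBS convention: 8 rows lettered A-H top to bottom and
12 columns numbered 1-12 left to right.  A plate matrix file is CSV with
three metadata lines, a header row and eight data rows::

    #plate_id=P01
    #assay=BODIPY_FA
    #storage_time_months=0.25;units=RFU
    row,1,2,...,12
    A,1510.2,...,...

Missing wells are encoded with an explicit token (default ``NA``), never
silently absent.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import (
    MISSING_TOKEN,
    FormatError,
    InvalidArgumentError,
    JoinError,
    ValidationError,
)

N_ROWS = 8
N_COLS = 12
ROW_LETTERS = "ABCDEFGH"

ASSAYS = ("BODIPY_FA", "GLYCEROL_GLO", "LYSOZYME", "PROTEASE", "TAC")
#: canonical readout units per assay
ASSAY_UNITS = {
    "BODIPY_FA": "RFU",
    "GLYCEROL_GLO": "RLU",
    "LYSOZYME": "RFU",
    "PROTEASE": "RFU",
    "TAC": "A570",
}

ROLES = ("sample", "vehicle_dmso", "vehicle_water", "positive_control", "empty")
VEHICLE_ROLES = ("vehicle_dmso", "vehicle_water")


def well_address(row_index: int, col_index: int) -> str:
    """0-based (row, col) indices -> SBS address like ``A1`` or ``H12``."""
    if not (0 <= row_index < N_ROWS and 0 <= col_index < N_COLS):
        raise InvalidArgumentError(f"well index out of range: ({row_index}, {col_index})")
    return f"{ROW_LETTERS[row_index]}{col_index + 1}"


def parse_address(address: str) -> tuple[int, int]:
    """SBS address -> 0-based (row, col); raises on out-of-bounds."""
    address = address.strip().upper()
    if len(address) < 2 or address[0] not in ROW_LETTERS:
        raise InvalidArgumentError(f"bad well address {address!r}")
    try:
        col = int(address[1:])
    except ValueError as exc:
        raise InvalidArgumentError(f"bad well address {address!r}") from exc
    if not 1 <= col <= N_COLS:
        raise InvalidArgumentError(f"column out of range in {address!r}")
    return ROW_LETTERS.index(address[0]), col - 1


@dataclass
class PlateLayout:
    """Role/compound annotation of one 96-well plate."""

    plate_id: str
    roles: np.ndarray  # (8, 12) array of role strings
    compound_ids: np.ndarray  # (8, 12) object array; None for non-sample wells
    dilution_index: np.ndarray = None  # (8, 12) float array; NaN = none

    def __post_init__(self):
        self.roles = np.asarray(self.roles, dtype=object)
        self.compound_ids = np.asarray(self.compound_ids, dtype=object)
        if self.dilution_index is None:
            self.dilution_index = np.full((N_ROWS, N_COLS), np.nan)
        self.dilution_index = np.asarray(self.dilution_index, dtype=float)
        if self.roles.shape != (N_ROWS, N_COLS):
            raise ValidationError("layout roles must be 8x12")
        bad = set(self.roles.ravel()) - set(ROLES)
        if bad:
            raise ValidationError(f"unknown roles: {sorted(bad)}")
        for r in range(N_ROWS):
            for c in range(N_COLS):
                if self.roles[r, c] == "sample" and not self.compound_ids[r, c]:
                    raise ValidationError(
                        f"sample well {well_address(r, c)} lacks compound_id"
                    )
        for role in VEHICLE_ROLES:
            if not (self.roles == role).any():
                raise ValidationError(f"plate {self.plate_id}: no {role} well")

    def wells_with_role(self, role: str) -> list[str]:
        rr, cc = np.nonzero(self.roles == role)
        return [well_address(r, c) for r, c in zip(rr, cc)]

    def to_frame(self) -> pd.DataFrame:
        """Long-form layout table (plate_id, well, role, compound_id, dilution_index)."""
        rows = []
        for r in range(N_ROWS):
            for c in range(N_COLS):
                d = self.dilution_index[r, c]
                rows.append(
                    {
                        "plate_id": self.plate_id,
                        "well": well_address(r, c),
                        "role": self.roles[r, c],
                        "compound_id": self.compound_ids[r, c],
                        "dilution_index": None if math.isnan(d) else int(d),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateLayout":
        plate_ids = df["plate_id"].unique()
        if len(plate_ids) != 1:
            raise ValidationError("layout frame must describe exactly one plate")
        roles = np.full((N_ROWS, N_COLS), "empty", dtype=object)
        compounds = np.full((N_ROWS, N_COLS), None, dtype=object)
        dil = np.full((N_ROWS, N_COLS), np.nan)
        for rec in df.itertuples(index=False):
            r, c = parse_address(rec.well)
            roles[r, c] = rec.role
            cid = rec.compound_id
            compounds[r, c] = None if (cid is None or (isinstance(cid, float) and math.isnan(cid))) else cid
            d = rec.dilution_index
            if d is not None and not (isinstance(d, float) and math.isnan(d)):
                dil[r, c] = float(d)
        return cls(str(plate_ids[0]), roles, compounds, dil)


@dataclass
class PlateRead:
    """One assay read of one plate: an 8x12 value matrix plus metadata."""

    plate_id: str
    assay: str
    storage_time: float  # months
    values: np.ndarray  # (8, 12) float matrix; NaN marks missing wells
    units: str = ""

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_ROWS, N_COLS):
            raise ValidationError("plate value matrix must be 8x12")
        if not self.units:
            self.units = ASSAY_UNITS[self.assay]
        elif self.units != ASSAY_UNITS[self.assay]:
            raise ValidationError(
                f"units {self.units!r} inconsistent with assay {self.assay}"
            )


def write_plate_matrix(read: PlateRead, path, missing_token: str = MISSING_TOKEN) -> None:
    """Serialise a PlateRead to the plate matrix CSV dialect.

    Floats are written with 17 significant digits so a write->read round
    trip is value-identical.
    """
    if read.values.size == 0:
        raise ValidationError("empty plate matrix")
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"#plate_id={read.plate_id}\n")
        fh.write(f"#assay={read.assay}\n")
        fh.write(f"#storage_time_months={read.storage_time!r};units={read.units}\n")
        writer = csv.writer(fh)
        writer.writerow(["row"] + [str(c) for c in range(1, N_COLS + 1)])
        for r in range(N_ROWS):
            row = [ROW_LETTERS[r]]
            for c in range(N_COLS):
                v = read.values[r, c]
                row.append(missing_token if math.isnan(v) else format(v, ".17g"))
            writer.writerow(row)


def read_plate_matrix(path, missing_token: str = MISSING_TOKEN) -> PlateRead:
    """Parse a plate matrix CSV; all 96 cells resolve to a value or NaN."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3 + 1 + N_ROWS:
        raise FormatError(f"{path}: truncated plate file")
    meta = {}
    for line in lines[:3]:
        if not line.startswith("#") or "=" not in line:
            raise FormatError(f"{path}: malformed metadata line {line!r}")
        for part in line[1:].split(";"):
            key, _, val = part.partition("=")
            meta[key.strip()] = val.strip()
    for key in ("plate_id", "assay", "storage_time_months", "units"):
        if key not in meta:
            raise FormatError(f"{path}: missing metadata field {key!r}")
    body = list(csv.reader(lines[3:]))
    header = body[0]
    if header[0] != "row" or header[1:] != [str(c) for c in range(1, N_COLS + 1)]:
        raise FormatError(f"{path}: malformed column header")
    values = np.full((N_ROWS, N_COLS), np.nan)
    data_rows = body[1 : 1 + N_ROWS]
    if len(data_rows) != N_ROWS or [row[0] for row in data_rows] != list(ROW_LETTERS):
        raise FormatError(f"{path}: expected data rows A-H in order")
    for r, row in enumerate(data_rows):
        if len(row) != N_COLS + 1:
            raise FormatError(f"{path}: row {row[0]} has {len(row) - 1} cells")
        for c, cell in enumerate(row[1:]):
            if cell == missing_token:
                continue
            try:
                values[r, c] = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at {well_address(r, c)}"
                ) from exc
    try:
        t = float(meta["storage_time_months"])
    except ValueError as exc:
        raise FormatError(f"{path}: bad storage time") from exc
    return PlateRead(meta["plate_id"], meta["assay"], t, values, meta["units"])


def annotate_and_validate(read: PlateRead, layout: PlateLayout) -> pd.DataFrame:
    """Join a read to its layout into a 96-row WellRecord table.

    Every well yields a record regardless of missingness, but a plate whose
    DMSO or water vehicle-control group is absent or entirely missing-valued
    is rejected: without both solvent references the screen's normalisation
    contract (1% v/v DMSO and 1% v/v water controls on every plate) is broken.
    """
    if read.plate_id != layout.plate_id:
        raise JoinError(
            f"plate_id mismatch: read {read.plate_id!r} vs layout {layout.plate_id!r}"
        )
    records = []
    for r in range(N_ROWS):
        for c in range(N_COLS):
            d = layout.dilution_index[r, c]
            records.append(
                {
                    "plate_id": read.plate_id,
                    "well": well_address(r, c),
                    "role": layout.roles[r, c],
                    "compound_id": layout.compound_ids[r, c],
                    "dilution_index": None if math.isnan(d) else int(d),
                    "assay": read.assay,
                    "storage_time": read.storage_time,
                    "value": read.values[r, c],
                    "units": read.units,
                }
            )
    table = pd.DataFrame(records)
    for role in VEHICLE_ROLES:
        vals = table.loc[table["role"] == role, "value"]
        if vals.empty or vals.isna().all():
            raise ValidationError(
                f"plate {read.plate_id}: {role} controls absent or all missing"
            )
    return table
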