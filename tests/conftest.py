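import numpy as np
import pandas as pd
import pytest

from lactoshelf.plate_io import N_COLS, N_ROWS, PlateLayout, PlateRead
from lactoshelf.synthetic_data import NoiseSpec, SimDefaults


@pytest.fixture
def noiseless():
    return NoiseSpec(cv=0.0, seed=7)


@pytest.fixture
def defaults():
    return SimDefaults()


@pytest.fixture
def small_layout():
    """One plate: 8 sample wells in column 1, vehicles in column 12."""
    roles = np.full((N_ROWS, N_COLS), "empty", dtype=object)
    compounds = np.full((N_ROWS, N_COLS), None, dtype=object)
    for r in range(N_ROWS):
        roles[r, 0] = "sample"
        compounds[r, 0] = f"C{r + 1:04d}"
    roles[0, N_COLS - 1] = "vehicle_dmso"
    roles[1, N_COLS - 1] = "vehicle_dmso"
    roles[2, N_COLS - 1] = "vehicle_water"
    roles[3, N_COLS - 1] = "vehicle_water"
    return PlateLayout("P01", roles, compounds)


@pytest.fixture
def small_read(small_layout):
    rng = np.random.default_rng(0)
    values = np.full((N_ROWS, N_COLS), np.nan)
    values[small_layout.roles != "empty"] = rng.normal(
        1000, 50, int((small_layout.roles != "empty").sum())
    )
    return PlateRead("P01", "BODIPY_FA", 0.25, values)


def wells_from(values_by_compound, vehicle_values, plate_id="P01", assay="BODIPY_FA"):
    """Build a minimal WellRecord table for triage tests."""
    rows = []
    for i, (cid, v) in enumerate(values_by_compound.items()):
        rows.append({"plate_id": plate_id, "well": f"A{i + 1}", "role": "sample",
                     "compound_id": cid, "dilution_index": None, "assay": assay,
                     "storage_time": 0.25, "value": v, "units": "RFU"})
    for i, v in enumerate(vehicle_values):
        role = "vehicle_dmso" if i % 2 == 0 else "vehicle_water"
        rows.append({"plate_id": plate_id, "well": f"H{i + 1}", "role": role,
                     "compound_id": None, "dilution_index": None, "assay": assay,
                     "storage_time": 0.25, "value": v, "units": "RFU"})
    return pd.DataFrame(rows)
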