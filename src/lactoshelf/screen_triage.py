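"""Hit-selection cascade for the lipolysis-inhibition screen.

Stages: per-plate Z-scores against pooled vehicle controls, absolute
RFU-threshold primary calls (wells at or below 400 RFU of BODIPY-FA
signal after ~1 week frozen), same-criterion retest confirmation,
dose-series summarisation (2-fold dilution series, indices 0 to -7 of
library stock), and a final gate demanding that candidate compounds
retain >75% of lysozyme and protease activity relative to reference
milk.  Z-scores are reported as diagnostics; the operative primary gate
is the absolute threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import (
    DegenerateInputError,
    InvalidArgumentError,
    ValidationError,
)
from .plate_io import VEHICLE_ROLES

STAGES = ("primary", "retested", "validated", "rejected")


@dataclass(frozen=True)
class TriageConfig:
    """Gate parameters of the triage cascade.

    rfu_threshold: primary-hit cutoff in RFU (default 400).
    threshold_inclusive: hit iff value <= threshold (default) vs strict <.
    retention_threshold: enzyme-retention cutoff as a fraction (default 0.75).
    retention_strict: pass requires ratio strictly > threshold (default).
    pool_vehicles: pool DMSO and water controls for Z-scores (default) or
        restrict the reference to one solvent group.
    """

    rfu_threshold: float = 400.0
    threshold_inclusive: bool = True
    z_report: bool = True
    retention_threshold: float = 0.75
    retention_strict: bool = True
    replicate_agg: str = "median"
    pool_vehicles: bool = True
    vehicle_role: str = "vehicle_dmso"  # used when pool_vehicles is False

    def __post_init__(self):
        if self.rfu_threshold <= 0:
            raise InvalidArgumentError("rfu_threshold must be > 0")
        if not 0.0 < self.retention_threshold < 1.0:
            raise InvalidArgumentError("retention_threshold must be in (0,1)")
        if self.replicate_agg != "median":
            raise InvalidArgumentError("only median replicate aggregation is supported")

    def passes_primary(self, value: float) -> bool:
        if np.isnan(value):
            return False
        if self.threshold_inclusive:
            return value <= self.rfu_threshold
        return value < self.rfu_threshold

    def passes_retention(self, ratio: float) -> bool:
        if self.retention_strict:
            return ratio > self.retention_threshold
        return ratio >= self.retention_threshold


@dataclass
class HitCall:
    """Per-compound triage outcome; stage transitions only move forward."""

    compound_id: str
    raw_value: float
    z: float = float("nan")
    stage: str = "rejected"
    reasons: list[str] = field(default_factory=list)

    _ORDER = {s: i for i, s in enumerate(("rejected", "primary", "retested", "validated"))}

    def advance(self, stage: str) -> None:
        if self._ORDER[stage] < self._ORDER.get(self.stage, 0) and self.stage != "rejected":
            raise ValidationError(f"stage cannot move backward: {self.stage} -> {stage}")
        self.stage = stage

    def reject(self, reason: str) -> None:
        self.stage = "rejected"
        self.reasons.append(reason)


@dataclass
class TriageReport:
    """Cascade stage counts plus the per-compound calls."""

    screened: int
    primary: int
    retested: int
    validated: int
    hits: list[HitCall]
    config: TriageConfig

    def __post_init__(self):
        if not self.screened >= self.primary >= self.retested >= self.validated:
            raise ValidationError("cascade containment violated")

    def to_json(self) -> str:
        from dataclasses import asdict

        payload = {
            "config": asdict(self.config),
            "stage_counts": {
                "screened": self.screened,
                "primary": self.primary,
                "retested": self.retested,
                "validated": self.validated,
            },
            "hits": [
                {
                    "compound_id": h.compound_id,
                    "stage": h.stage,
                    "raw": None if np.isnan(h.raw_value) else h.raw_value,
                    "z": None if np.isnan(h.z) else h.z,
                    "reasons": h.reasons,
                }
                for h in self.hits
            ],
        }
        return json.dumps(payload, indent=2)


def _vehicle_values(plate_wells: pd.DataFrame, config: TriageConfig) -> np.ndarray:
    roles = VEHICLE_ROLES if config.pool_vehicles else (config.vehicle_role,)
    vals = plate_wells.loc[
        plate_wells["role"].isin(roles), "value"
    ].dropna().to_numpy()
    return vals


def plate_zscores(
    wells: pd.DataFrame, config: TriageConfig = TriageConfig()
) -> pd.DataFrame:
    """Attach per-plate vehicle-referenced Z-scores to a WellRecord table.

    z = (value - mean of that plate's vehicle wells) / their SD (ddof=1);
    control wells receive a z as well.  Affine rescaling of a whole plate
    leaves z unchanged.
    """
    out = wells.copy()
    out["z"] = np.nan
    for plate_id, grp in wells.groupby("plate_id"):
        veh = _vehicle_values(grp, config)
        if len(veh) < 2:
            raise ValidationError(f"plate {plate_id}: <2 vehicle-control wells")
        sd = float(np.std(veh, ddof=1))
        if sd == 0:
            raise DegenerateInputError(f"plate {plate_id}: zero vehicle SD")
        out.loc[grp.index, "z"] = (grp["value"] - float(np.mean(veh))) / sd
    return out


def call_primary_hits(
    wells: pd.DataFrame, config: TriageConfig = TriageConfig()
) -> list[HitCall]:
    """Primary calls: sample wells at/below the RFU threshold.

    Only sample wells are eligible; controls are never called.  Replicate
    wells of one compound are aggregated by median before thresholding.
    """
    if not (wells["assay"] == "BODIPY_FA").all():
        raise ValidationError("primary hit calling expects BODIPY_FA wells")
    has_z = "z" in wells.columns
    calls = []
    samples = wells[wells["role"] == "sample"]
    for cid, grp in samples.groupby("compound_id", sort=True):
        value = float(grp["value"].median())
        z = float(grp["z"].median()) if has_z else float("nan")
        call = HitCall(cid, raw_value=value, z=z)
        if config.passes_primary(value):
            call.advance("primary")
        else:
            call.reject("above-threshold")
        calls.append(call)
    return calls


def confirm_retest(
    primary: list[HitCall],
    retest_wells: pd.DataFrame,
    config: TriageConfig = TriageConfig(),
) -> list[HitCall]:
    """Apply the primary criterion a second time on independent retest wells.

    Every primary hit must be covered by at least one retest well;
    failures become rejected("retest-fail").
    """
    retest = retest_wells[retest_wells["role"] == "sample"]
    by_compound = retest.groupby("compound_id")["value"].median()
    out = []
    for call in primary:
        if call.stage != "primary":
            out.append(call)
            continue
        if call.compound_id not in by_compound.index:
            raise ValidationError(
                f"no retest well for primary hit {call.compound_id}"
            )
        if config.passes_primary(float(by_compound[call.compound_id])):
            call.advance("retested")
        else:
            call.reject("retest-fail")
        out.append(call)
    return out


def summarize_dose_response(
    wells: pd.DataFrame, dilution_indices=tuple(range(0, -8, -1))
) -> dict[str, pd.DataFrame]:
    """Median-of-replicates dose table per compound, ordered index 0 -> -7.

    Dilution index -k means a 2^-k dilution of library stock; index 0 is
    undiluted stock.
    """
    allowed = set(dilution_indices)
    seen = set(int(d) for d in wells["dilution_index"].dropna())
    unknown = seen - allowed
    if unknown:
        raise ValidationError(f"unknown dilution indices: {sorted(unknown)}")
    tables = {}
    for cid, grp in wells.groupby("compound_id", sort=True):
        agg = (
            grp.dropna(subset=["dilution_index"])
            .groupby("dilution_index")["value"]
            .median()
        )
        table = pd.DataFrame(
            {
                "dilution_index": [int(d) for d in dilution_indices if d in agg.index],
                "response": [float(agg[d]) for d in dilution_indices if d in agg.index],
            }
        )
        tables[cid] = table
    return tables


def retention_gate(
    candidates: list[HitCall],
    lysozyme_ratios: dict[str, float] | pd.Series,
    protease_ratios: dict[str, float] | pd.Series,
    config: TriageConfig = TriageConfig(),
) -> list[HitCall]:
    """Final gate: both enzyme-retention ratios must exceed the threshold.

    Ratios are treated enzymatic signal over the reference (untreated or
    fresh) signal; a candidate failing either enzyme is rejected with a
    per-enzyme reason.
    """
    lys = pd.Series(lysozyme_ratios, dtype=float)
    prot = pd.Series(protease_ratios, dtype=float)
    out = []
    for call in candidates:
        if call.stage != "retested":
            out.append(call)
            continue
        cid = call.compound_id
        if cid not in lys.index or cid not in prot.index:
            raise ValidationError(f"missing enzyme measurement for {cid}")
        failed = False
        if not config.passes_retention(float(lys[cid])):
            call.reject("lysozyme-retention")
            failed = True
        if not config.passes_retention(float(prot[cid])):
            call.reject("protease-retention")
            failed = True
        if not failed:
            call.advance("validated")
        out.append(call)
    return out


def compute_retention_ratios(
    enzyme_wells: pd.DataFrame, reference_wells: pd.DataFrame
) -> pd.Series:
    """Per-compound treated/reference enzyme-signal ratio.

    The reference is the median of the reference wells (untreated milk at
    the matching storage time by default); it must be positive.
    """
    ref = float(reference_wells["value"].median())
    if not ref > 0:
        raise DegenerateInputError("reference enzyme signal must be > 0")
    treated = enzyme_wells[enzyme_wells["role"] == "sample"]
    return treated.groupby("compound_id")["value"].median() / ref


def run_triage(
    screen_wells: pd.DataFrame,
    retest_wells: pd.DataFrame,
    lysozyme_wells: pd.DataFrame,
    lysozyme_reference: pd.DataFrame,
    protease_wells: pd.DataFrame,
    protease_reference: pd.DataFrame,
    config: TriageConfig = TriageConfig(),
) -> TriageReport:
    """Run the full cascade and return a TriageReport.

    Enzyme wells need cover only the retest-confirmed candidates.
    Deterministic: identical inputs yield identical reports.
    """
    wells = plate_zscores(screen_wells, config) if config.z_report else screen_wells
    calls = call_primary_hits(wells, config)
    n_primary = sum(c.stage == "primary" for c in calls)
    calls = confirm_retest(calls, retest_wells, config)
    n_retested = sum(c.stage == "retested" for c in calls)
    lys_ratios = compute_retention_ratios(lysozyme_wells, lysozyme_reference)
    prot_ratios = compute_retention_ratios(protease_wells, protease_reference)
    calls = retention_gate(calls, lys_ratios, prot_ratios, config)
    n_validated = sum(c.stage == "validated" for c in calls)
    return TriageReport(
        screened=len(calls),
        primary=n_primary,
        retested=n_retested,
        validated=n_validated,
        hits=calls,
        config=config,
    )
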