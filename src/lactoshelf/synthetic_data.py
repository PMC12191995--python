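"""Mechanistic forward model of frozen human-milk degradation.

Generates every input the analysis pipeline consumes — donor cohorts,
compound effects, screen plates with ground truth, multi-assay storage
time courses, and survey respondent tables — from an explicit kinetic
model with seeded noise.

The degradation model
---------------------
Freezing damages the milk-fat-globule membrane, letting endogenous
lipases hydrolyse triglycerides.  Glycerol accumulates from a finite
hydrolyzable pool with saturating first-order kinetics,

    G(t) = g_max * (1 - exp(-rho * k * t)),

where ``k`` (month^-1) is the donor's lipolysis rate constant and
``rho`` is a dimensionless rate multiplier carried by a treatment
(rho = 1 untreated; membrane-stabilising compounds have rho < 1).
Complete hydrolysis of one triglyceride yields three free fatty acids
and one glycerol, so FFA(t) = 3 * G(t) exactly in the noiseless model.

Lipase substrate signal decays as the enzyme loses activity in the
freezer; antioxidant capacity is the sum of a fast-decaying endogenous
ascorbate-equivalent pool, a persistent non-ascorbate pool, and any
supplemented ascorbate decaying at its own slower rate; lysozyme and
protease signals decay slowly and identically for treated and untreated
arms unless a compound carries an enzyme-suppression multiplier.

All noise is multiplicative mean-one lognormal per well/measurement;
treated and untreated arms of a donor share the same donor draw (paired
design).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import (
    InvalidArgumentError,
    LayoutOverflowError,
    lognormal_noise_factors,
    stream,
)
from .plate_io import (
    N_COLS,
    N_ROWS,
    PlateLayout,
    PlateRead,
    well_address,
)

ASSAY_LIST = ("GLYCEROL_GLO", "FFA", "BODIPY_FA", "TAC", "LYSOZYME", "PROTEASE")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise configuration.

    cv: per-assay coefficient of variation (fraction, >= 0).
    plate_gradient: maximal fractional row+column drift across a plate
        (0 disables it; capped at 0.2).
    seed: master seed; identical seed => bit-identical outputs.
    """

    cv: float = 0.05
    plate_gradient: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise InvalidArgumentError("cv must be >= 0")
        if not 0.0 <= self.plate_gradient <= 0.2:
            raise InvalidArgumentError("plate_gradient must be in [0, 0.2]")


@dataclass(frozen=True)
class SimDefaults:
    """Calibrated default parameters of the degradation model.

    Units: rates in month^-1, glycerol pool in µM, signals in RFU or
    A570-equivalent arbitrary units.
    """

    k_base: float = 0.30  # lipolysis rate constant, month^-1
    donor_sigma: float = 0.3  # sd of log donor multiplier on k_base
    g_max: float = 500.0  # hydrolyzable glycerol pool, µM
    rho_treated: float = 0.225  # pectin + ascorbate combined rate multiplier
    active_rho_cut: float = 0.20  # ground-truth activity boundary for screens
    inactive_rho_mean: float = 1.0
    inactive_rho_sigma: float = 0.10
    lipase_bg: float = 100.0  # background lipase signal, RFU
    lipase_amp: float = 1400.0  # lipase signal amplitude, RFU
    lipase_decay: float = 0.5  # lipase signal decay, month^-1
    enzyme_decay: float = 0.04  # lysozyme/protease decay, month^-1
    a_endog: float = 1.0  # endogenous ascorbate-equivalent capacity, A570
    a_stable: float = 0.5  # persistent non-ascorbate capacity, A570
    endog_aox_decay: float = 2.3  # freezer decay of endogenous ascorbate, month^-1
    supplement_aox_decay: float = 0.1  # decay of 100 µg/mL supplemented ascorbate
    lys0: float = 1000.0  # baseline lysozyme signal, RFU
    prot0: float = 1000.0  # baseline protease signal, RFU


@dataclass(frozen=True)
class DonorParams:
    """Latent kinetic parameters of one donor's milk."""

    donor_id: str
    k_base: float  # month^-1
    g_max: float  # µM
    lip0: float  # baseline lipase amplitude, RFU
    a_endog: float  # A570 units
    a_stable: float  # A570 units
    lys0: float  # RFU
    prot0: float  # RFU

    def __post_init__(self):
        vals = (self.k_base, self.g_max, self.lip0, self.a_endog,
                self.a_stable, self.lys0, self.prot0)
        if not all(np.isfinite(vals)) or any(v <= 0 for v in vals):
            raise InvalidArgumentError("DonorParams fields must be finite and > 0")


@dataclass(frozen=True)
class CompoundEffect:
    """Latent effect of one compound on the degradation model."""

    compound_id: str
    rho: float  # lipolysis rate multiplier
    lys_mult: float = 1.0
    prot_mult: float = 1.0
    aox_boost: float = 0.0  # added antioxidant capacity, A570
    is_active: bool = False

    def __post_init__(self):
        if self.rho <= 0 or self.lys_mult <= 0 or self.prot_mult <= 0:
            raise InvalidArgumentError("rho and enzyme multipliers must be > 0")


UNTREATED = CompoundEffect("untreated", rho=1.0)


def generate_donors(
    n: int,
    noise: NoiseSpec = NoiseSpec(),
    defaults: SimDefaults = SimDefaults(),
) -> list[DonorParams]:
    """Draw a donor cohort with lognormal inter-individual variability.

    Each donor's lipolysis rate is ``k_base`` times a lognormal(0,
    donor_sigma) multiplier, encoding the wide baseline variability seen
    across lactating donors; baselines of the other assays vary with the
    measurement CV.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    donors = []
    for i in range(n):
        donor_id = f"D{i + 1:02d}"
        rng = stream(noise.seed, "donor", donor_id)
        mult = float(np.exp(rng.normal(0.0, defaults.donor_sigma)))
        b = lognormal_noise_factors(rng, noise.cv, 6)
        donors.append(
            DonorParams(
                donor_id=donor_id,
                k_base=defaults.k_base * mult,
                g_max=defaults.g_max * b[0],
                lip0=defaults.lipase_amp * b[1],
                a_endog=defaults.a_endog * b[2],
                a_stable=defaults.a_stable * b[3],
                lys0=defaults.lys0 * b[4],
                prot0=defaults.prot0 * b[5],
            )
        )
    return donors


def _noiseless_signals(
    donor: DonorParams, effect: CompoundEffect, t: np.ndarray, defaults: SimDefaults
) -> dict[str, np.ndarray]:
    k = donor.k_base * effect.rho
    glycerol = donor.g_max * -np.expm1(-k * t)
    lipase = defaults.lipase_bg + donor.lip0 * effect.rho * np.exp(
        -defaults.lipase_decay * t
    )
    tac = (
        donor.a_endog * np.exp(-defaults.endog_aox_decay * t)
        + donor.a_stable
        + effect.aox_boost * np.exp(-defaults.supplement_aox_decay * t)
    )
    lys = donor.lys0 * effect.lys_mult * np.exp(-defaults.enzyme_decay * t)
    prot = donor.prot0 * effect.prot_mult * np.exp(-defaults.enzyme_decay * t)
    return {
        "GLYCEROL_GLO": glycerol,
        "FFA": 3.0 * glycerol,
        "BODIPY_FA": lipase,
        "TAC": tac,
        "LYSOZYME": lys,
        "PROTEASE": prot,
    }


def simulate_timecourses(
    donors: list[DonorParams],
    effect: CompoundEffect = UNTREATED,
    times=(0.0, 0.25, 1.0, 2.0, 3.0, 4.0, 6.0),
    noise: NoiseSpec = NoiseSpec(),
    defaults: SimDefaults = SimDefaults(),
    assays=ASSAY_LIST,
) -> pd.DataFrame:
    """Simulate per-donor storage trajectories for each assay.

    Returns a tidy frame (donor_id, treatment, assay, time_months, value,
    units).  The FFA trajectory is exactly three times the glycerol
    trajectory when cv = 0 (triglyceride -> 3 FFA + 1 glycerol); their
    noise draws are otherwise independent, as they are separate assays.
    """
    t = np.asarray(times, dtype=float)
    if (t < 0).any():
        raise InvalidArgumentError("storage times must be >= 0")
    if not np.all(np.diff(t) > 0):
        raise InvalidArgumentError("times must be strictly increasing")
    units = {"GLYCEROL_GLO": "uM", "FFA": "uM", "BODIPY_FA": "RFU",
             "TAC": "A570", "LYSOZYME": "RFU", "PROTEASE": "RFU"}
    frames = []
    for donor in donors:
        clean = _noiseless_signals(donor, effect, t, defaults)
        for assay in assays:
            rng = stream(noise.seed, "tc", donor.donor_id, effect.compound_id, assay)
            vals = clean[assay] * lognormal_noise_factors(rng, noise.cv, t.shape)
            frames.append(
                pd.DataFrame(
                    {
                        "donor_id": donor.donor_id,
                        "treatment": effect.compound_id,
                        "assay": assay,
                        "time_months": t,
                        "value": vals,
                        "units": units[assay],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _plate_gradient(gradient: float) -> np.ndarray:
    """Linear row+column ramp centred on 1.0 with max fractional drift."""
    if gradient == 0.0:
        return np.ones((N_ROWS, N_COLS))
    rows = np.linspace(-0.5, 0.5, N_ROWS)[:, None]
    cols = np.linspace(-0.5, 0.5, N_COLS)[None, :]
    return 1.0 + gradient * (rows + cols)


def generate_compound_effects(
    library_size: int,
    n_active: int,
    noise: NoiseSpec = NoiseSpec(),
    defaults: SimDefaults = SimDefaults(),
) -> list[CompoundEffect]:
    """Draw a compound library: n_active membrane-stabilisers among inerts.

    Actives get rho uniform on (0.05, active_rho_cut]; inactives get rho
    ~ Normal(1, 0.10) truncated positive.  Which library slots are active
    is itself a seeded draw.
    """
    if n_active > library_size:
        raise InvalidArgumentError("n_active cannot exceed library_size")
    rng = stream(noise.seed, "library")
    active_idx = set(
        rng.choice(library_size, size=n_active, replace=False).tolist()
    )
    effects = []
    for i in range(library_size):
        cid = f"C{i + 1:04d}"
        if i in active_idx:
            rho = float(rng.uniform(0.05, defaults.active_rho_cut))
            effects.append(CompoundEffect(cid, rho=rho, is_active=True))
        else:
            rho = 0.0
            while rho <= 0:
                rho = float(
                    rng.normal(defaults.inactive_rho_mean, defaults.inactive_rho_sigma)
                )
            effects.append(CompoundEffect(cid, rho=rho, is_active=False))
    return effects


def generate_screen_dataset(
    library_size: int = 2750,
    n_active: int = 21,
    n_plates: int = 30,
    noise: NoiseSpec = NoiseSpec(cv=0.05),
    defaults: SimDefaults = SimDefaults(),
    storage_time: float = 0.25,
    effects: list[CompoundEffect] | None = None,
) -> tuple[list[PlateRead], list[PlateLayout], pd.DataFrame]:
    """Lay a compound library out on 96-well plates and simulate the screen.

    Each plate carries two 1% v/v DMSO and two 1% v/v water vehicle
    wells in column 12, leaving 92 sample wells.  The single screening
    donor's milk is aliquoted across all plates; the primary read is the
    lipase (BODIPY-FA) signal after ~1 week at -20 °C.  Returns plate
    reads, layouts, and a ground-truth table linking compound -> rho.
    """
    usable = N_ROWS * N_COLS - 4
    if library_size > n_plates * usable:
        raise LayoutOverflowError(
            f"{library_size} compounds exceed {n_plates} x {usable} sample wells"
        )
    if effects is None:
        effects = generate_compound_effects(library_size, n_active, noise, defaults)
    elif len(effects) != library_size:
        raise InvalidArgumentError("effects list must match library_size")

    # single screening donor, drawn from its own stream
    donor = replace(generate_donors(1, noise, defaults)[0], donor_id="SCREEN_DONOR")

    control_wells = {
        (0, N_COLS - 1): "vehicle_dmso",
        (1, N_COLS - 1): "vehicle_dmso",
        (2, N_COLS - 1): "vehicle_water",
        (3, N_COLS - 1): "vehicle_water",
    }
    reads, layouts = [], []
    pos = 0
    t = np.array([storage_time])
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        rng = stream(noise.seed, "plate", plate_id)
        roles = np.full((N_ROWS, N_COLS), "empty", dtype=object)
        compounds = np.full((N_ROWS, N_COLS), None, dtype=object)
        clean = np.full((N_ROWS, N_COLS), np.nan)
        for (r, c), role in control_wells.items():
            roles[r, c] = role
            clean[r, c] = _noiseless_signals(donor, UNTREATED, t, defaults)["BODIPY_FA"][0]
        for r in range(N_ROWS):
            for c in range(N_COLS):
                if (r, c) in control_wells or pos >= library_size:
                    continue
                eff = effects[pos]
                roles[r, c] = "sample"
                compounds[r, c] = eff.compound_id
                clean[r, c] = _noiseless_signals(donor, eff, t, defaults)["BODIPY_FA"][0]
                pos += 1
        values = clean * _plate_gradient(noise.plate_gradient)
        values *= lognormal_noise_factors(rng, noise.cv, (N_ROWS, N_COLS))
        values[roles == "empty"] = np.nan
        layouts.append(PlateLayout(plate_id, roles, compounds))
        reads.append(PlateRead(plate_id, "BODIPY_FA", storage_time, values))
    truth = pd.DataFrame(
        {
            "compound_id": [e.compound_id for e in effects],
            "rho": [e.rho for e in effects],
            "is_active": [e.is_active for e in effects],
        }
    )
    return reads, layouts, truth


# ---------------------------------------------------------------------------
# Survey generator
# ---------------------------------------------------------------------------

#: §3.1-style default marginals; single-selects sum to 1 (±0.01 tolerated
#: for printed rounding), multi-selects are per-option probabilities.
DEFAULT_SURVEY_MARGINALS: dict = {
    "feeding_first6mo": {"breastmilk_only": 0.46, "formula_only": 0.11, "combination": 0.44},
    "delivery_mode": {"both": 0.55, "breast_only": 0.26, "pump_only": 0.19},
    "stored_milk": 0.83,
    "freezer_given_stored": 0.68,
    "refrigerator_given_freezer": 0.50,  # freezer users who also refrigerate
    "freezer_duration": {"<1mo": 0.31, "1-3mo": 0.40, "4-6mo": 0.17, ">6mo": 0.12},
    "freeze_reasons": {"oversupply": 0.63, "work": 0.38, "travel": 0.23},
    "discarded": 0.75,
    "discard_reasons": {"incomplete_feeding": 0.62, "questionable_storage": 0.38, "sensory_change": 0.23},
    "sensory_change": 0.20,
    "infant_rejection": {"never": 0.74, "occasional": 0.20, "persistent": 0.06},
    # duration-dependent sensory-change rates used when a storage-time trend
    # is planted (monotone by construction)
    "sensory_by_duration": {"<1mo": 0.10, "1-3mo": 0.18, "4-6mo": 0.28, ">6mo": 0.40},
    "race_ethnicity": {"white": 0.61, "black": 0.23, "hispanic_latino": 0.17,
                       "asian": 0.04, "native": 0.02, "mena": 0.01},
    "employment": {"full_time": 0.44, "part_time": 0.19, "unemployed": 0.22,
                   "student": 0.04, "other": 0.11},
    "income_band": {"<20k": 0.10, "20k-199k": 0.81, ">=200k": 0.09},
    "age_mean": 30.6,
    "age_sd": 6.7,
}


def _validate_marginals(m: dict) -> None:
    for key, val in m.items():
        if isinstance(val, dict):
            probs = list(val.values())
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise InvalidArgumentError(f"marginal {key}: probabilities outside [0,1]")
            single_selects = {"feeding_first6mo", "delivery_mode", "freezer_duration",
                              "infant_rejection", "employment", "income_band"}
            if key in single_selects and abs(sum(probs) - 1.0) > 0.01 + 1e-9:
                raise InvalidArgumentError(f"single-select marginal {key} must sum to 1±0.01")
        elif key not in ("age_mean", "age_sd") and not 0.0 <= val <= 1.0:
            raise InvalidArgumentError(f"marginal {key} outside [0,1]")


_SURVEY_COLUMNS = [
    "respondent_id", "youngest_child_birth_year", "feeding_first6mo",
    "attempted_breastfeeding", "consent_to_include", "delivery_mode",
    "stored_milk", "storage_methods", "freezer_duration", "freeze_reasons",
    "discarded", "discard_reasons", "sensory_change", "infant_rejection",
    "age", "race_ethnicity", "employment", "income_band",
]


def generate_survey_records(
    n: int,
    marginals: dict | None = None,
    seed: int = 0,
    plant_duration_trend: bool = False,
) -> pd.DataFrame:
    """Generate a branch-consistent survey respondent table.

    All generated respondents satisfy the eligibility screen (youngest
    child born 2020-2024; breastmilk or combination feeding, or formula
    with attempted breastfeeding and consent).  Branch rules: freezer
    questions only for freezer users, discard reasons only for
    discarders, sensory/rejection only for storers.  Multi-select
    answers are semicolon-joined tokens.

    With ``plant_duration_trend`` the sensory-change probability rises
    monotonically with freezer-storage duration; otherwise a single rate
    applies to all storers (independence null).
    """
    if n < 0:
        raise InvalidArgumentError("n must be >= 0")
    m = dict(DEFAULT_SURVEY_MARGINALS)
    if marginals:
        m.update(marginals)
    _validate_marginals(m)
    if n == 0:
        return pd.DataFrame(columns=_SURVEY_COLUMNS)

    rng = stream(seed, "survey")

    def pick(dist: dict, size: int) -> np.ndarray:
        cats = list(dist)
        p = np.asarray([dist[c] for c in cats], dtype=float)
        p = p / p.sum()
        return rng.choice(cats, size=size, p=p)

    def multi(dist: dict, size: int) -> list[str]:
        opts = list(dist)
        draws = rng.random((size, len(opts))) < np.asarray([dist[o] for o in opts])
        # guarantee at least one selection so the answer is never blank
        none = ~draws.any(axis=1)
        if none.any():
            first = np.argmax(np.asarray([dist[o] for o in opts]))
            draws[none, first] = True
        return [";".join(o for o, d in zip(opts, row) if d) for row in draws]

    feeding = pick(m["feeding_first6mo"], n)
    formula_only = feeding == "formula_only"
    stored = rng.random(n) < m["stored_milk"]
    freezer = stored & (rng.random(n) < m["freezer_given_stored"])
    fridge_too = freezer & (rng.random(n) < m["refrigerator_given_freezer"])
    methods = np.where(
        freezer,
        np.where(fridge_too, "refrigerator;freezer", "freezer"),
        "refrigerator",
    )
    methods = np.where(stored, methods, "")

    duration = np.where(freezer, pick(m["freezer_duration"], n), "")
    reasons = np.asarray(multi(m["freeze_reasons"], n), dtype=object)
    reasons[~freezer] = ""
    discarded = rng.random(n) < m["discarded"]
    discard_reasons = np.asarray(multi(m["discard_reasons"], n), dtype=object)
    discard_reasons[~discarded] = ""

    if plant_duration_trend:
        p_sens = np.full(n, m["sensory_change"])
        for dur, p in m["sensory_by_duration"].items():
            p_sens[duration == dur] = p
    else:
        p_sens = np.full(n, m["sensory_change"])
    sensory = stored & (rng.random(n) < p_sens)
    rejection = np.where(stored, pick(m["infant_rejection"], n), "")

    df = pd.DataFrame(
        {
            "respondent_id": [f"R{i + 1:05d}" for i in range(n)],
            "youngest_child_birth_year": rng.integers(2020, 2025, size=n),
            "feeding_first6mo": feeding,
            "attempted_breastfeeding": formula_only | (rng.random(n) < 0.99),
            "consent_to_include": True,
            "delivery_mode": pick(m["delivery_mode"], n),
            "stored_milk": stored,
            "storage_methods": methods,
            "freezer_duration": duration,
            "freeze_reasons": reasons,
            "discarded": discarded,
            "discard_reasons": discard_reasons,
            "sensory_change": np.where(stored, sensory.astype(object), ""),
            "infant_rejection": rejection,
            "age": np.clip(rng.normal(m["age_mean"], m["age_sd"], n), 18, 55).round(0),
            "race_ethnicity": multi(m["race_ethnicity"], n),
            "employment": pick(m["employment"], n),
            "income_band": pick(m["income_band"], n),
        }
    )
    return df[_SURVEY_COLUMNS]


def write_dataset(
    out_dir,
    seed: int = 0,
    n_donors: int = 14,
    times=(0.0, 0.25, 1.0, 2.0, 3.0, 4.0, 6.0),
    library_size: int = 2750,
    n_active: int = 21,
    n_plates: int = 30,
    n_respondents: int = 1049,
    cv: float = 0.05,
    defaults: SimDefaults = SimDefaults(),
) -> dict:
    """Emit a full synthetic dataset under ``out_dir`` with a manifest.

    Writes plate matrices, layout CSVs, ground truth, tidy time courses
    for untreated and treated (combined pectin + ascorbate) arms, and the
    survey table; the manifest JSON records the configuration and seed.
    """
    from .plate_io import write_plate_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    noise = NoiseSpec(cv=cv, seed=seed)
    donors = generate_donors(n_donors, noise, defaults)
    treated = CompoundEffect("pectin+ascorbate", rho=defaults.rho_treated,
                             aox_boost=1.0, is_active=True)
    tc = pd.concat(
        [
            simulate_timecourses(donors, UNTREATED, times, noise, defaults),
            simulate_timecourses(donors, treated, times, noise, defaults),
        ],
        ignore_index=True,
    )
    tc.to_csv(out / "timecourses.csv", index=False)

    reads, layouts, truth = generate_screen_dataset(
        library_size, n_active, n_plates, noise, defaults
    )
    plates_dir = out / "plates"
    layouts_dir = out / "layouts"
    plates_dir.mkdir(exist_ok=True)
    layouts_dir.mkdir(exist_ok=True)
    for read, layout in zip(reads, layouts):
        write_plate_matrix(read, plates_dir / f"{read.plate_id}.csv")
        layout.to_frame().to_csv(layouts_dir / f"{layout.plate_id}.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)

    survey = generate_survey_records(n_respondents, seed=seed)
    survey.to_csv(out / "survey.csv", index=False)

    manifest = {
        "seed": seed,
        "n_donors": n_donors,
        "times_months": list(times),
        "library_size": library_size,
        "n_active": n_active,
        "n_plates": n_plates,
        "n_respondents": n_respondents,
        "cv": cv,
        "outputs": {
            "timecourses": "timecourses.csv",
            "plates": "plates/",
            "layouts": "layouts/",
            "ground_truth": "ground_truth.csv",
            "survey": "survey.csv",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
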