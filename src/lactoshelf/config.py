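"""Run configuration (pydantic-validated YAML) and the pipeline driver.

A run is fully described by a PipelineConfig; the resolved config and
seed are echoed into the output manifest so any bundle can be
reproduced bit-identically from its manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator
from pydantic import ValidationError as PydanticValidationError

from ._util import ConfigError


class SimulationBlock(BaseModel):
    n_donors: int = Field(14, ge=1)
    times_months: list[float] = [0.0, 0.25, 1.0, 2.0, 3.0, 4.0, 6.0]
    library_size: int = Field(2750, ge=1)
    n_active: int = Field(21, ge=0)
    n_plates: int = Field(30, ge=1)
    n_respondents: int = Field(1049, ge=0)
    cv: float = Field(0.05, ge=0)
    k_base: float = Field(0.30, gt=0)
    donor_sigma: float = Field(0.3, ge=0)
    g_max: float = Field(500.0, gt=0)
    rho_treated: float = Field(0.225, gt=0)

    @field_validator("times_months")
    @classmethod
    def _times_ok(cls, v):
        if any(t < 0 for t in v) or sorted(v) != v:
            raise ValueError("times must be sorted and >= 0")
        return v


class TriageBlock(BaseModel):
    rfu_threshold: float = Field(400.0, gt=0)
    threshold_inclusive: bool = True
    retention_threshold: float = Field(0.75, gt=0, lt=1)
    retention_strict: bool = True
    pool_vehicles: bool = True


class StorageBlock(BaseModel):
    reduction_time_months: float = Field(6.0, gt=0)
    reduction_metric: str = "endpoint"  # or "auc"

    @field_validator("reduction_metric")
    @classmethod
    def _metric_ok(cls, v):
        if v not in ("endpoint", "auc"):
            raise ValueError("reduction_metric must be 'endpoint' or 'auc'")
        return v


class StatsBlock(BaseModel):
    alpha: float = Field(0.05, gt=0, lt=1)


class PipelineConfig(BaseModel):
    seed: int = 0
    simulation: SimulationBlock = SimulationBlock()
    triage: TriageBlock = TriageBlock()
    storage: StorageBlock = StorageBlock()
    stats: StatsBlock = StatsBlock()


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config; schema failures name the offending paths."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig.model_validate(raw)
    except PydanticValidationError as exc:
        paths = ["/".join(str(p) for p in e["loc"]) for e in exc.errors()]
        raise ConfigError(f"invalid config fields: {paths}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable YAML: {exc}") from exc


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run simulation -> triage -> storage metrics -> stats -> survey tabulation.

    Writes every stage's outputs plus a manifest JSON under ``out_dir``
    and returns the manifest.  Identical config+seed produce identical
    bundles.
    """
    from . import screen_triage, stats_suite, storage_kinetics, survey_tab, synthetic_data
    from .plate_io import annotate_and_validate

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    defaults = synthetic_data.SimDefaults(
        k_base=sim.k_base, donor_sigma=sim.donor_sigma,
        g_max=sim.g_max, rho_treated=sim.rho_treated,
    )
    noise = synthetic_data.NoiseSpec(cv=sim.cv, seed=config.seed)

    # --- simulate ---------------------------------------------------------
    donors = synthetic_data.generate_donors(sim.n_donors, noise, defaults)
    treated = synthetic_data.CompoundEffect(
        "pectin+ascorbate", rho=defaults.rho_treated, aox_boost=1.0, is_active=True
    )
    tc = pd.concat(
        [
            synthetic_data.simulate_timecourses(
                donors, synthetic_data.UNTREATED, sim.times_months, noise, defaults
            ),
            synthetic_data.simulate_timecourses(
                donors, treated, sim.times_months, noise, defaults
            ),
        ],
        ignore_index=True,
    )
    tc.to_csv(out / "timecourses.csv", index=False)

    effects = synthetic_data.generate_compound_effects(
        sim.library_size, sim.n_active, noise, defaults
    )
    reads, layouts, truth = synthetic_data.generate_screen_dataset(
        sim.library_size, sim.n_active, sim.n_plates, noise, defaults, effects=effects
    )
    truth.to_csv(out / "ground_truth.csv", index=False)
    wells = pd.concat(
        [annotate_and_validate(r, l) for r, l in zip(reads, layouts)],
        ignore_index=True,
    )

    # --- triage -----------------------------------------------------------
    tri_cfg = screen_triage.TriageConfig(
        rfu_threshold=config.triage.rfu_threshold,
        threshold_inclusive=config.triage.threshold_inclusive,
        retention_threshold=config.triage.retention_threshold,
        retention_strict=config.triage.retention_strict,
        pool_vehicles=config.triage.pool_vehicles,
    )
    retest_noise = synthetic_data.NoiseSpec(cv=sim.cv, seed=config.seed + 1)
    retest_reads, retest_layouts, _ = synthetic_data.generate_screen_dataset(
        sim.library_size, sim.n_active, sim.n_plates, retest_noise, defaults,
        effects=effects,
    )
    retest_wells = pd.concat(
        [annotate_and_validate(r, l) for r, l in zip(retest_reads, retest_layouts)],
        ignore_index=True,
    )
    # enzyme panel at month 6 for every library compound, from the same donor pool
    lys, prot, lys_ref, prot_ref = synthetic_data_enzyme_panel(
        effects, noise, defaults
    )
    report = screen_triage.run_triage(
        wells, retest_wells, lys, lys_ref, prot, prot_ref, tri_cfg
    )
    (out / "triage_report.json").write_text(report.to_json())

    # --- storage metrics --------------------------------------------------
    t_red = config.storage.reduction_time_months
    gly = tc[tc["assay"] == "GLYCEROL_GLO"]
    if config.storage.reduction_metric == "endpoint":
        summary = storage_kinetics.cohort_glycerol_reduction(
            tc, "pectin+ascorbate", "untreated", t_red
        )
    else:
        per_donor = {
            d: storage_kinetics.glycerol_auc_reduction(
                g[g["treatment"] == "pectin+ascorbate"], g[g["treatment"] == "untreated"]
            )
            for d, g in gly.groupby("donor_id")
        }
        summary = storage_kinetics.summarize_donors(per_donor, "glycerol_auc_reduction")
    lys_ret = storage_kinetics.cohort_enzyme_retention(tc, "pectin+ascorbate", "LYSOZYME", t_red)
    prot_ret = storage_kinetics.cohort_enzyme_retention(tc, "pectin+ascorbate", "PROTEASE", t_red)
    fits = {
        f"{d}/{trt}": storage_kinetics.fit_first_order(g)
        for (d, trt), g in gly.groupby(["donor_id", "treatment"])
    }
    storage_out = {
        "glycerol_reduction": {"mean": summary.mean, "sd": summary.sd,
                               "per_donor": summary.per_donor.to_dict()},
        "lysozyme_retention_pct": {"mean": lys_ret.mean, "sd": lys_ret.sd},
        "protease_retention_pct": {"mean": prot_ret.mean, "sd": prot_ret.sd},
        "kinetic_fits": {k: {"g_max_hat": f.g_max_hat, "k_hat": f.k_hat,
                             "converged": f.converged} for k, f in fits.items()},
    }
    (out / "storage_summary.json").write_text(json.dumps(storage_out, indent=2))

    # --- stats ------------------------------------------------------------
    gly6 = gly[gly["time_months"] == gly["time_months"].max()]
    groups = [g["value"].to_numpy() for _, g in gly6.groupby("treatment")]
    aov = stats_suite.one_way_anova(groups)
    bf = stats_suite.variance_homogeneity(groups, "brown_forsythe")
    bart = stats_suite.variance_homogeneity(groups, "bartlett")
    resid = pd.concat(
        [g["value"] - g["value"].mean() for _, g in gly6.groupby("treatment")]
    ).to_numpy()
    gate = stats_suite.normality_gate(resid)
    stats_out = {
        "one_way_anova_endpoint_glycerol": {
            "F": aov.terms["group"]["F"], "df": [aov.terms["group"]["df"],
                                                 aov.residual["df"]],
            "p": aov.terms["group"]["p"],
        },
        "brown_forsythe": {"statistic": bf[0], "p": bf[1]},
        "bartlett": {"statistic": bart[0], "p": bart[1]},
        "normality": {"skewness": gate.skewness,
                      "excess_kurtosis": gate.excess_kurtosis,
                      "pass": gate.normal_pass},
    }
    (out / "stats_results.json").write_text(json.dumps(stats_out, indent=2))

    # --- survey -----------------------------------------------------------
    survey = synthetic_data.generate_survey_records(sim.n_respondents, seed=config.seed)
    survey.to_csv(out / "survey.csv", index=False)
    tabs = {}
    if sim.n_respondents:
        eligible, _ = survey_tab.apply_eligibility(survey)
        for q in ("stored_milk", "freezer_duration", "freeze_reasons",
                  "discarded", "sensory_change", "infant_rejection"):
            t = survey_tab.tabulate(eligible, q)
            tabs[q] = {"denominator": t.denominator, "rule": t.denominator_rule,
                       "percent": t.percentages}
    (out / "survey_tabulations.json").write_text(json.dumps(tabs, indent=2))

    manifest = {
        "seed": config.seed,
        "config": config.model_dump(),
        "stage_counts": {
            "screened": report.screened,
            "primary": report.primary,
            "retested": report.retested,
            "validated": report.validated,
        },
        "outputs": {
            "timecourses": "timecourses.csv",
            "ground_truth": "ground_truth.csv",
            "triage_report": "triage_report.json",
            "storage_summary": "storage_summary.json",
            "stats_results": "stats_results.json",
            "survey": "survey.csv",
            "survey_tabulations": "survey_tabulations.json",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def synthetic_data_enzyme_panel(effects, noise, defaults, t: float = 6.0):
    """Month-6 lysozyme/protease wells for every compound plus untreated references.

    Built from the screening donor so the retention gate compares treated
    milk against untreated milk at the same storage time.
    """
    import numpy as np

    from ._util import lognormal_noise_factors, stream
    from .synthetic_data import UNTREATED, generate_donors, _noiseless_signals

    donor = generate_donors(1, noise, defaults)[0]
    t_arr = np.array([t])
    rows_lys, rows_prot = [], []
    for eff in effects:
        clean = _noiseless_signals(donor, eff, t_arr, defaults)
        rng = stream(noise.seed, "enzyme", eff.compound_id)
        f = lognormal_noise_factors(rng, noise.cv, 2)
        rows_lys.append({"compound_id": eff.compound_id, "role": "sample",
                         "value": clean["LYSOZYME"][0] * f[0]})
        rows_prot.append({"compound_id": eff.compound_id, "role": "sample",
                          "value": clean["PROTEASE"][0] * f[1]})
    ref_clean = _noiseless_signals(donor, UNTREATED, t_arr, defaults)
    rng = stream(noise.seed, "enzyme", "reference")
    f = lognormal_noise_factors(rng, noise.cv, 6)
    lys_ref = pd.DataFrame({"role": "reference",
                            "value": ref_clean["LYSOZYME"][0] * f[:3]})
    prot_ref = pd.DataFrame({"role": "reference",
                             "value": ref_clean["PROTEASE"][0] * f[3:]})
    return pd.DataFrame(rows_lys), pd.DataFrame(rows_prot), lys_ref, prot_ref
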