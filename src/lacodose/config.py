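"""Study configuration and the end-to-end table writer.

The default :class:`StudyConfig` reproduces the published study grid: two
CRRT modalities (CVVHD, pre-dilution CVVH) at effluent rates of 20, 25 and
35 mL/kg/h, the standard-dose regimen catalog evaluated against the trough
(5–10 mg/L) and standard AUC (80.25–143 mg·h/L) targets, the high-dose
catalog against the high AUC target (143–231 mg·h/L), with 10,000 fresh
virtual patients per regimen.  :func:`run_study` writes the PTA tables,
the optimal-regimen grid, the weight-effect tables and a run manifest;
identical config + seed yields byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clearance import CRRTPrescription
from .cohort import (
    CLNR_ML_MIN, SIEVING, VD_PER_KG, WEIGHT_KG, CohortSpec, ParameterDistribution,
    sample_cohort,
)
from .pk import DosingRegimen
from .pta import (
    PDTarget, PTASummary, daily_classification, derive_seed, run_catalog,
    select_optimal, summaries_to_frame,
)
from .weight_effect import (
    REFERENCE_WEIGHT_BIN_COUNTS, WeightBinTable, attainment_from_simulation,
    rr_vs_rest,
)

__all__ = [
    "StudyConfig",
    "STANDARD_REGIMENS",
    "HIGH_REGIMENS",
    "TROUGH_TARGET",
    "AUC_LOW_TARGET",
    "AUC_HIGH_TARGET",
    "run_study",
    "load_config",
    "save_config",
    "reference_rr_frame",
]

TROUGH_TARGET = PDTarget("trough", 5.0, 10.0, label="trough 5-10 mg/L")
AUC_LOW_TARGET = PDTarget("auc24", 80.25, 143.0, label="AUC24 80.25-143 mg.h/L")
AUC_HIGH_TARGET = PDTarget("auc24", 143.0, 231.0, label="AUC24 143-231 mg.h/L")

# Catalog of regimens evaluated against the standard targets
# (trough 5-10 mg/L and AUC 80.25-143 mg.h/L), in published order.
STANDARD_REGIMENS = (
    DosingRegimen(100, 8),
    DosingRegimen(150, 8),
    DosingRegimen(200, 12),
    DosingRegimen(200, 8),
    DosingRegimen(300, 12),
    DosingRegimen(250, 8),
)

# Catalog evaluated against the high AUC target (143-231 mg.h/L).
HIGH_REGIMENS = (
    DosingRegimen(250, 12),
    DosingRegimen(250, 12, loading_dose=300),
    DosingRegimen(250, 12, loading_dose=350),
    DosingRegimen(300, 12),
    DosingRegimen(150, 8),
    DosingRegimen(150, 8, loading_dose=200),
    DosingRegimen(150, 8, loading_dose=250),
    DosingRegimen(200, 8),
    DosingRegimen(200, 8, loading_dose=250),
)

_DIST_FIELDS = ("mean", "sd", "lower", "upper")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to rerun the study deterministically."""

    master_seed: int = 1
    n_patients: int = 10_000
    modalities: tuple[str, ...] = ("CVVHD", "CVVH")
    effluent_rates: tuple[float, ...] = (20.0, 25.0, 35.0)
    blood_flow: float = 200.0
    hematocrit: float = 0.30
    tie_margin: float = 5.0
    renal_clearance_l_h: float = 0.0
    weight_dist: ParameterDistribution = WEIGHT_KG
    vd_per_kg_dist: ParameterDistribution = VD_PER_KG
    clnr_dist: ParameterDistribution = CLNR_ML_MIN
    sc_dist: ParameterDistribution = SIEVING
    correlation: tuple[tuple[float, ...], ...] = (
        (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0),
    )
    standard_regimens: tuple[DosingRegimen, ...] = STANDARD_REGIMENS
    high_regimens: tuple[DosingRegimen, ...] = HIGH_REGIMENS
    # scenario behind the simulated weight-effect table
    weight_effect_modality: str = "CVVHD"
    weight_effect_rate: float = 25.0
    weight_effect_regimen: DosingRegimen = DosingRegimen(150, 8)
    weight_effect_target: str = "trough"

    def __post_init__(self) -> None:
        errors = []
        if self.n_patients < 1:
            errors.append(f"n_patients must be >= 1, got {self.n_patients}")
        if self.tie_margin < 0:
            errors.append(f"tie_margin must be >= 0, got {self.tie_margin}")
        for m in self.modalities:
            if m not in ("CVVHD", "CVVH"):
                errors.append(f"unknown modality {m!r}")
        for r in self.effluent_rates:
            if not r > 0:
                errors.append(f"effluent rate must be > 0, got {r}")
        if errors:
            raise ValueError("invalid study config: " + "; ".join(errors))

    def cohort_spec(self, seed: int | None = None) -> CohortSpec:
        return CohortSpec(
            n=self.n_patients,
            seed=self.master_seed if seed is None else seed,
            weight_dist=self.weight_dist,
            vd_per_kg_dist=self.vd_per_kg_dist,
            clnr_dist=self.clnr_dist,
            sc_dist=self.sc_dist,
            correlation=np.asarray(self.correlation),
        )

    def prescriptions(self) -> list[CRRTPrescription]:
        return [
            CRRTPrescription(m, r, blood_flow=self.blood_flow, hematocrit=self.hematocrit)
            for m in self.modalities
            for r in self.effluent_rates
        ]

    def targets(self) -> dict[str, PDTarget]:
        return {
            "trough": TROUGH_TARGET,
            "auc_low": AUC_LOW_TARGET,
            "auc_high": AUC_HIGH_TARGET,
        }

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("weight_dist", "vd_per_kg_dist", "clnr_dist", "sc_dist"):
            d[key] = {f: getattr(getattr(self, key), f) for f in _DIST_FIELDS}
        d["correlation"] = [list(row) for row in self.correlation]
        for key in ("standard_regimens", "high_regimens"):
            d[key] = [_regimen_dict(r) for r in getattr(self, key)]
        d["weight_effect_regimen"] = _regimen_dict(self.weight_effect_regimen)
        d["modalities"] = list(self.modalities)
        d["effluent_rates"] = list(self.effluent_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("weight_dist", "vd_per_kg_dist", "clnr_dist", "sc_dist"):
            if key in d:
                d[key] = ParameterDistribution(**d[key])
        for key in ("standard_regimens", "high_regimens"):
            if key in d:
                d[key] = tuple(_regimen_from_dict(r) for r in d[key])
        if "weight_effect_regimen" in d:
            d["weight_effect_regimen"] = _regimen_from_dict(d["weight_effect_regimen"])
        for key in ("modalities", "effluent_rates"):
            if key in d:
                d[key] = tuple(d[key])
        if "correlation" in d:
            d["correlation"] = tuple(tuple(row) for row in d["correlation"])
        return cls(**d)

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()


def _regimen_dict(r: DosingRegimen) -> dict:
    return {
        "maintenance_dose": r.maintenance_dose,
        "interval": r.interval,
        "loading_dose": r.loading_dose,
        "horizon": r.horizon,
    }


def _regimen_from_dict(d: dict) -> DosingRegimen:
    return DosingRegimen(**d)


def save_config(config: StudyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> StudyConfig:
    return StudyConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def _write_pta_csv(summaries: list[PTASummary], path: Path) -> None:
    frame = summaries_to_frame(summaries)
    frame.to_csv(path, index=False, float_format="%.2f")


def reference_rr_frame(
    counts: dict[str, tuple[int, int]] | None = None
) -> pd.DataFrame:
    """Risk-ratio table (bin vs rest) from a weight-bin count table."""
    table = WeightBinTable.from_counts(counts or REFERENCE_WEIGHT_BIN_COUNTS)
    rows = []
    for i, label in enumerate(table.labels):
        row = {
            "bin_label": label,
            "n_fail": int(table.n_fail[i]),
            "n_attain": int(table.n_attain[i]),
            "pct_attained": (
                100.0 * table.n_attain[i] / table.n_per_bin[i]
                if table.n_per_bin[i] > 0
                else np.nan
            ),
        }
        try:
            rr = rr_vs_rest(table, i)
            row |= {"rr": rr.rr, "ci_low": rr.ci_low, "ci_high": rr.ci_high, "p": rr.p}
        except ValueError:
            row |= {"rr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
        rows.append(row)
    return pd.DataFrame(rows)


def _optimal_frame(config: StudyConfig, summaries: list[PTASummary]) -> pd.DataFrame:
    """Optimal regimen per (modality, rate, target) plus the pooled
    standard-target recommendation (union of trough and low-AUC optima)."""
    rows = []
    by_scenario: dict[tuple, list[PTASummary]] = {}
    for s in summaries:
        key = (s.prescription.modality, s.prescription.effluent_rate, s.target.label)
        by_scenario.setdefault(key, []).append(s)
    pooled: dict[tuple, dict[str, str]] = {}
    for (modality, rate, target), group in sorted(
        by_scenario.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        best = select_optimal(group, tie_margin=config.tie_margin)
        rows.append(
            {
                "modality": modality,
                "effluent_rate": rate,
                "target": target,
                "optimal_regimen": best.regimen.label,
                "daily_dose_mg": best.regimen.daily_dose,
                "avg_in_pct": round(best.average_in, 2),
            }
        )
        if target in (TROUGH_TARGET.label, AUC_LOW_TARGET.label):
            pooled.setdefault((modality, rate), {})[target] = best.regimen.label
    for (modality, rate), choices in sorted(pooled.items()):
        labels = sorted(set(choices.values()))
        rows.append(
            {
                "modality": modality,
                "effluent_rate": rate,
                "target": "standard (pooled)",
                "optimal_regimen": " OR ".join(labels),
                "daily_dose_mg": np.nan,
                "avg_in_pct": np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, outdir) -> dict[str, Path]:
    """Run the full grid and write all study tables.

    Returns a mapping from logical table name to file path.  Deterministic:
    the same config and master seed give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.cohort_spec()
    prescriptions = config.prescriptions()
    targets = config.targets()

    standard = run_catalog(
        spec, prescriptions, config.standard_regimens,
        [targets["trough"], targets["auc_low"]],
        master_seed=config.master_seed,
        renal_clearance_l_h=config.renal_clearance_l_h,
    )
    high = run_catalog(
        spec, prescriptions, config.high_regimens, [targets["auc_high"]],
        master_seed=config.master_seed,
        renal_clearance_l_h=config.renal_clearance_l_h,
    )

    paths: dict[str, Path] = {}
    groups = {
        "pta_trough": [s for s in standard if s.target.metric == "trough"],
        "pta_auc_low": [s for s in standard if s.target.metric == "auc24"],
        "pta_auc_high": high,
    }
    for name, group in groups.items():
        paths[name] = outdir / f"{name}.csv"
        _write_pta_csv(group, paths[name])
    # full machine precision, all scenarios
    paths["pta_full"] = outdir / "pta_full.csv"
    summaries_to_frame(standard + high).to_csv(paths["pta_full"], index=False)

    paths["optimal"] = outdir / "optimal.csv"
    _optimal_frame(config, standard + high).to_csv(paths["optimal"], index=False)

    # weight effect: one documented scenario, simulated at the study size
    we_target = targets[
        "trough" if config.weight_effect_target == "trough" else config.weight_effect_target
    ]
    we_prescription = CRRTPrescription(
        config.weight_effect_modality, config.weight_effect_rate,
        blood_flow=config.blood_flow, hematocrit=config.hematocrit,
    )
    we_seed = derive_seed(
        config.master_seed, "weight-effect", config.weight_effect_regimen.label,
        we_prescription.modality, we_prescription.effluent_rate,
    )
    cohort = sample_cohort(spec.with_seed(we_seed))
    codes = daily_classification(
        cohort, we_prescription, config.weight_effect_regimen, we_target,
        config.renal_clearance_l_h,
    )
    _, we_table = attainment_from_simulation(cohort, codes)
    paths["weight_effect"] = outdir / "weight_effect.csv"
    reference_rr_frame(
        dict(zip(we_table.labels, zip(we_table.n_fail, we_table.n_attain)))
    ).to_csv(paths["weight_effect"], index=False, float_format="%.3f")
    paths["weight_effect_reference"] = outdir / "weight_effect_reference.csv"
    reference_rr_frame().to_csv(
        paths["weight_effect_reference"], index=False, float_format="%.3f"
    )

    manifest = {
        "master_seed": config.master_seed,
        "n_patients": config.n_patients,
        "config_sha256": config.config_hash(),
        "lacodose_version": __version__,
        "files": sorted(p.name for p in paths.values()),
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
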