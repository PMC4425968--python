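"""CSV schema, run configuration and the end-to-end pipeline.

The cohort CSV dialect is comma-separated UTF-8 with a period decimal
separator and a mandatory header; units are embedded in the column names so
a file is self-describing::

    id,spap_mmHg,dpap_mmHg,mpap_mmHg,pcwp_mmHg,co_L_min,hr_bpm,bsa_m2,age_years

``bsa_m2`` and ``age_years`` are optional; missing values are empty cells;
unknown columns are preserved on round-trip. All reports hold full-precision
values — rounding to presentation precision happens only in the
human-readable summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import cohort as cohort_mod
from . import hemo, models, stats
from .cohort import ClassificationResult, HemodynamicClassifier, Label, NormalBounds, PAHRule
from .errors import SchemaError
from .hemo import RHCRecord

MANDATORY_COLUMNS = [
    "id", "spap_mmHg", "dpap_mmHg", "mpap_mmHg", "pcwp_mmHg", "co_L_min", "hr_bpm",
]
OPTIONAL_COLUMNS = ["bsa_m2", "age_years"]

_COLUMN_TO_FIELD = {
    "spap_mmHg": "spap",
    "dpap_mmHg": "dpap",
    "mpap_mmHg": "mpap",
    "pcwp_mmHg": "pcwp",
    "co_L_min": "co",
    "hr_bpm": "hr",
    "bsa_m2": "bsa",
    "age_years": "age",
}


@dataclass(frozen=True)
class CohortTable:
    """A cohort as a DataFrame in the package CSV schema."""

    frame: pd.DataFrame

    def to_records(self) -> list[RHCRecord]:
        return frame_to_records(self.frame)

    def __len__(self) -> int:
        return len(self.frame)


def frame_to_records(frame: pd.DataFrame) -> list[RHCRecord]:
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col, field in _COLUMN_TO_FIELD.items():
            if col in frame.columns:
                v = row[col]
                kwargs[field] = None if pd.isna(v) else float(v)
            else:
                kwargs[field] = None
        records.append(RHCRecord(id=str(row["id"]), **kwargs))
    return records


def records_to_frame(records: Sequence[RHCRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "spap_mmHg": r.spap,
                "dpap_mmHg": r.dpap,
                "mpap_mmHg": r.mpap,
                "pcwp_mmHg": r.pcwp,
                "co_L_min": r.co,
                "hr_bpm": r.hr,
                "bsa_m2": r.bsa,
                "age_years": r.age,
            }
        )
    return pd.DataFrame(rows, columns=MANDATORY_COLUMNS + OPTIONAL_COLUMNS)


def read_cohort(path: str | Path) -> CohortTable:
    """Read and schema-validate a cohort CSV.

    Raises :class:`SchemaError` naming any missing mandatory column, or the
    first non-numeric cell with its (0-based) row index.
    """
    frame = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    numeric_cols = [c for c in frame.columns if c in _COLUMN_TO_FIELD]
    for col in numeric_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        frame[col] = coerced
    return CohortTable(frame=frame)


def write_cohort(table: CohortTable | pd.DataFrame | Sequence[RHCRecord],
                 path: str | Path) -> None:
    if isinstance(table, CohortTable):
        frame = table.frame
    elif isinstance(table, pd.DataFrame):
        frame = table
    else:
        frame = records_to_frame(list(table))
    frame.to_csv(path, index=False)


# --------------------------------------------------------------------------
# run configuration


class FitSettings(BaseModel):
    max_iter: int = 200
    rss_rtol: float = 1e-10
    b_margin: float = 1e-3


class PAHRuleConfig(BaseModel):
    mpap_min: Optional[float] = 25.0
    pcwp_max: Optional[float] = 15.0
    pvr_wood_min: Optional[float] = 3.0

    def build(self) -> PAHRule:
        return PAHRule(self.mpap_min, self.pcwp_max, self.pvr_wood_min)


class RunConfig(BaseModel):
    """Validated configuration; the defaults reproduce the package's
    reference analysis settings (published normal bounds, ±2 SD, PCWP gate
    at 15 mmHg, negative-DPG exclusion on)."""

    normal_bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(cohort_mod.KOVACS_NORMALS)
    )
    bounds_multiplier: float = 2.0
    pah_rule: PAHRuleConfig = Field(default_factory=PAHRuleConfig)
    exclude_negative_dpg: bool = True
    pcwp_max: float = 15.0
    strict_ci: bool = False
    correction_k: Optional[float] = None
    fit: FitSettings = Field(default_factory=FitSettings)
    seed: int = 0

    @field_validator("bounds_multiplier")
    @classmethod
    def _positive_multiplier(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("bounds_multiplier must be > 0")
        return v

    def build_bounds(self) -> NormalBounds:
        return NormalBounds(params=dict(self.normal_bounds),
                            multiplier=self.bounds_multiplier)

    def build_classifier(self) -> HemodynamicClassifier:
        return HemodynamicClassifier(
            bounds=self.build_bounds(),
            pah_rule=self.pah_rule.build(),
            exclude_negative_dpg=self.exclude_negative_dpg,
            pcwp_max=self.pcwp_max,
            strict_ci=self.strict_ci,
        ).fit()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=False)


# --------------------------------------------------------------------------
# pipeline


def derive_table(records: Sequence[RHCRecord]) -> pd.DataFrame:
    """Per-record derived quantities for all complete records."""
    rows = []
    for r in records:
        if not r.is_complete():
            continue
        d = hemo.derive_record(r)
        p = hemo.rv_power(r.spap, r.mpap, r.co)
        rows.append(
            {
                "id": r.id,
                "spap_mmHg": r.spap,
                "dpap_mmHg": r.dpap,
                "mpap_mmHg": r.mpap,
                "pcwp_mmHg": r.pcwp,
                "co_L_min": r.co,
                "hr_bpm": r.hr,
                "sv_mL": d.sv,
                "pp_mmHg": d.pp,
                "ca_mL_mmHg": d.ca,
                "pvr_wood": d.pvr_wood,
                "pvr_cgs": d.pvr_cgs,
                "tpr_wood": d.tpr_wood,
                "tpr_cgs": d.tpr_cgs,
                "dpg_mmHg": d.dpg,
                "rc_pvr_s": d.rc_pvr,
                "rc_tpr_s": d.rc_tpr,
                "mpap_spap_ratio": d.mpap_spap_ratio,
                "ci_L_min_m2": d.ci,
                "rv_power_mean_W": p.w_mean,
                "rv_power_total_W": p.w_total,
                "rv_power_osc_W": p.w_osc,
                "osc_fraction_pct": 100.0 * p.osc_fraction,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    records: Sequence[RHCRecord],
) -> dict:
    """screen → classify → derive → summarize → fit → group tests.

    Returns a report bundle: group/exclusion tallies (always summing to the
    input size), the per-record derived table, Table-style group summaries,
    flat fit reports for the inverse and linear model set with their
    group-difference F-tests, Wilcoxon group comparisons, and an exclusion
    log listing every excluded record with its fired rules. The pipeline is
    a pure function of (records, config): identical inputs give identical
    outputs.
    """
    records = list(records)
    classifier = config.build_classifier()
    results: list[ClassificationResult] = classifier.classify_all(records)
    labels = [res.label for res in results]

    tallies = {label.value: 0 for label in Label}
    for l in labels:
        tallies[l.value] += 1

    exclusion_log = [
        {
            "id": r.id,
            "label": res.label.value,
            "fired_rules": [str(rule) for rule in res.fired_rules],
        }
        for r, res in zip(records, results)
        if res.label not in (Label.NPH, Label.PAH)
    ]

    analysis = [
        (r, res.label)
        for r, res in zip(records, results)
        if res.label in (Label.NPH, Label.PAH)
    ]
    derived = derive_table([r for r, _ in analysis])
    derived["group"] = [l.value for _, l in analysis]

    summary = cohort_mod.summarize_cohort(records, labels)

    report: dict = {
        "n_input": len(records),
        "tallies": tallies,
        "summary": summary,
        "derived": derived,
        "exclusion_log": exclusion_log,
        "fits": {},
        "tests": {},
        "config": json.loads(config.model_dump_json()),
    }

    nph = derived[derived["group"] == "NPH"]
    pah = derived[derived["group"] == "PAH"]
    if len(nph) >= 4 and len(pah) >= 4:
        report["fits"], report["tests"] = _fit_model_set(derived, config)
        for column, name in [
            ("rc_pvr_s", "rc_pvr"),
            ("rc_tpr_s", "rc_tpr"),
            ("ca_mL_mmHg", "ca"),
            ("osc_fraction_pct", "osc_fraction"),
        ]:
            res = stats.wilcoxon_rank_sum(nph[column], pah[column])
            report["tests"][f"wilcoxon_{name}"] = {
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "method": res.method,
            }
    return report


def _fit_model_set(derived: pd.DataFrame, config: RunConfig) -> tuple[dict, dict]:
    """The reference model set: inverse Ca–PVR and Ca–TPR with group
    indicator (pooled vs per-group F-tests), RC-vs-mPAP line, per-group
    mPAP-vs-sPAP and oscillatory-fraction-vs-RC lines."""
    fits: dict = {}
    tests: dict = {}
    group = derived["group"].to_numpy()
    fs = config.fit.model_dump()

    for xcol, tag in [("pvr_wood", "ca_vs_pvr"), ("tpr_wood", "ca_vs_tpr")]:
        x = derived[xcol].to_numpy()
        y = derived["ca_mL_mmHg"].to_numpy()
        share = tag == "ca_vs_pvr"  # shared numerator for PVR, free for TPR
        pooled = models.fit_inverse_model(x, y, group=None, share_numerator=True, **fs)
        grouped = models.fit_inverse_model(x, y, group=group, share_numerator=share, **fs)
        fits[f"inverse_{tag}_pooled"] = pooled.to_report()
        fits[f"inverse_{tag}_grouped"] = grouped.to_report()
        ft = models.f_test_group_difference(pooled, grouped)
        tests[f"f_test_{tag}"] = ft.__dict__

    fits["linear_rc_vs_mpap"] = models.fit_linear(
        derived["mpap_mmHg"].to_numpy(), derived["rc_pvr_s"].to_numpy()
    ).to_report()

    for ycol, xcol, tag in [
        ("mpap_mmHg", "spap_mmHg", "mpap_vs_spap"),
        ("osc_fraction_pct", "rc_pvr_s", "oscfrac_vs_rc"),
    ]:
        xv = derived[xcol].to_numpy()
        yv = derived[ycol].to_numpy()
        pooled = models.fit_linear(xv, yv)
        grouped = models.fit_linear_grouped(xv, yv, group)
        fits[f"linear_{tag}_pooled"] = pooled.to_report()
        for glabel, gfit in grouped.by_group.items():
            fits[f"linear_{tag}_{glabel}"] = gfit.to_report()
        tests[f"f_test_{tag}"] = models.f_test_group_difference(pooled, grouped).__dict__
    return fits, tests
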