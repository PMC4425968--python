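"""Cohort selection: screening, exclusion rules and NPH/PAH/Other labels.

Implements the selection tree used to split a catheterization database into

* **NPH** — normal pulmonary hemodynamics: every measured parameter within
  ``multiplier`` (default 2) SDs of published healthy means (the Kovacs
  systematic-review values are the shipped default bounds),
* **PAH** — the hemodynamic definition of pulmonary arterial hypertension
  (default: mPAP ≥ 25 mmHg, PCWP ≤ 15 mmHg, PVR > 3 Wood units, each clause
  toggleable),
* **OTHER** — complete records with PCWP ≤ 15 that fit neither definition,

after excluding incomplete records, records with a negative diastolic
pressure gradient (dPAP < PCWP), and records with PCWP > 15 mmHg.
Every non-NPH/PAH outcome carries the rules that fired, with the offending
values, so a cohort report is auditable record by record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import hemo
from .errors import DomainError
from .hemo import RHCRecord


class Label(str, Enum):
    """Mutually exclusive cohort labels; one per screened record."""

    NPH = "NPH"
    PAH = "PAH"
    OTHER = "OTHER"
    EXCLUDED_INCOMPLETE = "EXCLUDED_INCOMPLETE"
    EXCLUDED_NEGATIVE_DPG = "EXCLUDED_NEGATIVE_DPG"
    EXCLUDED_HIGH_PCWP = "EXCLUDED_HIGH_PCWP"


@dataclass(frozen=True)
class FiredRule:
    rule: str
    value: Optional[float] = None
    bound: Optional[str] = None

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        s = self.rule
        if self.value is not None:
            s += f" (value={self.value:g}"
            s += f", bound={self.bound})" if self.bound else ")"
        return s


@dataclass(frozen=True)
class ClassificationResult:
    label: Label
    fired_rules: tuple[FiredRule, ...] = ()
    notes: tuple[str, ...] = ()


# Published healthy means ± SD from the systematic review of resting
# hemodynamics in healthy volunteers (Kovacs and colleagues).
KOVACS_NORMALS: dict[str, tuple[float, float]] = {
    "spap": (20.81, 4.4),
    "dpap": (8.75, 3.01),
    "mpap": (13.95, 3.27),
    "pcwp": (7.97, 2.85),
    "hr": (76.0, 14.0),
    "ci": (4.1, 1.26),
}


@dataclass(frozen=True)
class NormalBounds:
    """Per-parameter healthy mean ± SD, with an SD multiplier (default 2).

    A value v is compatible with normality when |v − mean| ≤ multiplier·SD
    (strict-inequality exclusion: a record is dropped from NPH only when it
    is *more than* ``multiplier`` SDs away).
    """

    params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(KOVACS_NORMALS)
    )
    multiplier: float = 2.0

    def __post_init__(self) -> None:
        for name, (mean, sd) in self.params.items():
            if sd <= 0:
                raise DomainError(f"SD for {name!r} must be > 0, got {sd}")

    def interval(self, name: str) -> tuple[float, float]:
        mean, sd = self.params[name]
        return mean - self.multiplier * sd, mean + self.multiplier * sd

    def within(self, name: str, value: float) -> bool:
        lo, hi = self.interval(name)
        return lo <= value <= hi


@dataclass(frozen=True)
class PAHRule:
    """Hemodynamic PAH definition; each clause can be switched off."""

    mpap_min: Optional[float] = 25.0
    pcwp_max: Optional[float] = 15.0
    pvr_wood_min: Optional[float] = 3.0

    def matches(self, mpap: float, pcwp: float, pvr_wood: float) -> bool:
        if self.mpap_min is not None and not mpap >= self.mpap_min:
            return False
        if self.pcwp_max is not None and not pcwp <= self.pcwp_max:
            return False
        if self.pvr_wood_min is not None and not pvr_wood > self.pvr_wood_min:
            return False
        return True


def screen_completeness(record: RHCRecord) -> ClassificationResult | None:
    """None when the record passes; an EXCLUDED_INCOMPLETE result otherwise.

    All six fields needed for an RC time (sPAP, dPAP, mPAP, PCWP, CO, HR)
    must be present and positive; a nonpositive value counts as missing.
    """
    bad = [
        FiredRule(f"missing_or_nonpositive:{f}", getattr(record, f))
        for f in RHCRecord.REQUIRED
        if getattr(record, f) is None or getattr(record, f) <= 0
    ]
    if bad:
        return ClassificationResult(Label.EXCLUDED_INCOMPLETE, tuple(bad))
    return None


def classify(
    record: RHCRecord,
    bounds: NormalBounds | None = None,
    pah_rule: PAHRule | None = None,
    *,
    exclude_negative_dpg: bool = True,
    pcwp_max: float = 15.0,
    strict_ci: bool = False,
) -> ClassificationResult:
    """Assign one cohort label to a complete record.

    Evaluation order: (1) negative DPG exclusion (can be disabled for the
    sensitivity analysis that keeps those records); (2) PCWP gate (inclusive
    at ``pcwp_max``); (3) NPH normal-bounds test; (4) PAH definition;
    (5) OTHER. The cardiac-index bound is enforced only when CI is
    computable (BSA present); otherwise the result is annotated
    ``CI-unchecked``, or demoted from NPH when ``strict_ci`` is set.
    """
    incomplete = screen_completeness(record)
    if incomplete is not None:
        return incomplete
    bounds = bounds if bounds is not None else NormalBounds()
    pah_rule = pah_rule if pah_rule is not None else PAHRule()

    dpg_val = hemo.dpg(record.dpap, record.pcwp)
    if exclude_negative_dpg and dpg_val < 0:
        return ClassificationResult(
            Label.EXCLUDED_NEGATIVE_DPG,
            (FiredRule("dpg < 0", dpg_val),),
        )
    if record.pcwp > pcwp_max:
        return ClassificationResult(
            Label.EXCLUDED_HIGH_PCWP,
            (FiredRule(f"pcwp > {pcwp_max:g}", record.pcwp),),
        )

    ci = record.co / record.bsa if record.bsa else None
    values = {
        "spap": record.spap,
        "dpap": record.dpap,
        "mpap": record.mpap,
        "pcwp": record.pcwp,
        "hr": record.hr,
        "ci": ci,
    }
    violations: list[FiredRule] = []
    notes: list[str] = []
    ci_unchecked = False
    for name in bounds.params:
        v = values.get(name)
        if v is None:
            if name == "ci":
                ci_unchecked = True
                continue
            continue  # unmeasured optional parameter: cannot bound it
        if not bounds.within(name, v):
            lo, hi = bounds.interval(name)
            violations.append(FiredRule(f"{name} outside normal", v, f"[{lo:.2f}, {hi:.2f}]"))
    if ci_unchecked:
        notes.append("CI-unchecked")
    if not violations and not (strict_ci and ci_unchecked):
        return ClassificationResult(Label.NPH, notes=tuple(notes))
    if strict_ci and ci_unchecked and not violations:
        violations.append(FiredRule("ci unavailable under strict_ci"))

    pvr_wood = hemo.pvr(record.mpap, record.pcwp, record.co, units="wood")
    if pah_rule.matches(record.mpap, record.pcwp, pvr_wood):
        return ClassificationResult(Label.PAH, notes=tuple(notes))
    return ClassificationResult(Label.OTHER, tuple(violations), tuple(notes))


class HemodynamicClassifier(BaseEstimator):
    """Rule-based cohort classifier with an sklearn-style surface.

    The rules are fixed by configuration, not learned, so :meth:`fit` only
    validates parameters and marks the estimator fitted; :meth:`predict`
    maps a cohort (sequence of records or a DataFrame in the package CSV
    schema) to labels, and :meth:`classify_all` keeps the full audit trail.
    """

    def __init__(
        self,
        bounds: NormalBounds | None = None,
        pah_rule: PAHRule | None = None,
        exclude_negative_dpg: bool = True,
        pcwp_max: float = 15.0,
        strict_ci: bool = False,
    ):
        self.bounds = bounds
        self.pah_rule = pah_rule
        self.exclude_negative_dpg = exclude_negative_dpg
        self.pcwp_max = pcwp_max
        self.strict_ci = strict_ci

    def fit(self, X=None, y=None):
        self.bounds_ = self.bounds if self.bounds is not None else NormalBounds()
        self.pah_rule_ = self.pah_rule if self.pah_rule is not None else PAHRule()
        return self

    def classify_all(self, records: Iterable[RHCRecord]) -> list[ClassificationResult]:
        if not hasattr(self, "bounds_"):
            self.fit()
        return [
            classify(
                r,
                self.bounds_,
                self.pah_rule_,
                exclude_negative_dpg=self.exclude_negative_dpg,
                pcwp_max=self.pcwp_max,
                strict_ci=self.strict_ci,
            )
            for r in records
        ]

    def predict(self, X) -> np.ndarray:
        records = _as_records(X)
        return np.array([res.label.value for res in self.classify_all(records)])


def _as_records(X) -> list[RHCRecord]:
    if isinstance(X, pd.DataFrame):
        from .io import frame_to_records

        return frame_to_records(X)
    return list(X)


#: Table-row order used by :func:`summarize_cohort`, measured then derived.
SUMMARY_ROWS = [
    "age", "spap", "dpap", "mpap", "mpap_spap_ratio", "pcwp", "co", "hr",
    "pvr_wood", "pvr_cgs", "ca", "rc_pvr", "rc_tpr",
    "w_mean", "w_total", "w_osc", "osc_fraction_pct",
]


def summarize_cohort(
    records: Sequence[RHCRecord],
    labels: Sequence[Label | str],
    groups: Sequence[str] = ("NPH", "PAH", "OTHER"),
) -> pd.DataFrame:
    """Per-group n / mean / SD table over measured and derived quantities.

    Means and SDs (ddof=1) are of the *per-record* values — e.g. the group
    RC time is the mean of individual PVR×Ca products, not the product of
    group means. A group with no records keeps n=0 and the explicit marker
    ``"empty"``; single-record groups report SD as NaN (undefined), never a
    fabricated 0.
    """
    if len(records) != len(labels):
        raise DomainError("records and labels must align one-to-one")
    labels = [Label(l) if not isinstance(l, Label) else l for l in labels]
    rows = []
    for group in groups:
        members = [r for r, l in zip(records, labels) if l.value == group]
        if not members:
            rows.append({"group": group, "n": 0, "status": "empty"})
            continue
        table = _derived_frame(members)
        for quantity in SUMMARY_ROWS:
            col = table[quantity].dropna()
            if col.empty:
                continue
            rows.append(
                {
                    "group": group,
                    "n": len(members),
                    "status": "ok",
                    "quantity": quantity,
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=1)) if len(col) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _derived_frame(records: Sequence[RHCRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = hemo.derive_record(r)
        p = hemo.rv_power(r.spap, r.mpap, r.co)
        rows.append(
            {
                "age": r.age,
                "spap": r.spap,
                "dpap": r.dpap,
                "mpap": r.mpap,
                "mpap_spap_ratio": d.mpap_spap_ratio,
                "pcwp": r.pcwp,
                "co": r.co,
                "hr": r.hr,
                "pvr_wood": d.pvr_wood,
                "pvr_cgs": d.pvr_cgs,
                "ca": d.ca,
                "rc_pvr": d.rc_pvr,
                "rc_tpr": d.rc_tpr,
                "w_mean": p.w_mean,
                "w_total": p.w_total,
                "w_osc": p.w_osc,
                "osc_fraction_pct": 100.0 * p.osc_fraction,
            }
        )
    return pd.DataFrame(rows)
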