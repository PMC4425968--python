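"""Per-record derived pulmonary hemodynamics.

Pure formula layer: every function maps measured right-heart-catheterization
(RHC) quantities — pulmonary artery pressures (mmHg), pulmonary capillary
wedge pressure (mmHg), cardiac output (L·min⁻¹) and heart rate (bpm) — to the
derived afterload quantities used throughout the package:

* stroke volume SV = CO/HR and pulse pressure PP = sPAP − dPAP,
* pulmonary arterial compliance Ca = SV/PP (mL·mmHg⁻¹),
* pulmonary vascular resistance PVR = (mPAP − PCWP)/CO and total pulmonary
  resistance TPR = mPAP/CO, in Wood units (mmHg·min·L⁻¹) or in
  mmHg·s·mL⁻¹ (Wood × 0.06),
* the RC time constant, the product of resistance (mmHg·s·mL⁻¹) and
  compliance — the exponential time constant of diastolic pulmonary artery
  pressure decay,
* right-ventricular hydraulic power split into mean and oscillatory
  components, with power in watts via 1 W = 7500 mmHg·mL·s⁻¹.

Convention: pressures in mmHg and flow in L·min⁻¹ at every public boundary;
conversions to mL·s⁻¹ (power) and mmHg·s·mL⁻¹ (resistance) happen inside.
No I/O and no cohort policy live here; exclusion rules belong to
:mod:`rctime.cohort`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional

from .errors import CompletenessError, DomainError

#: 1 watt expressed in mmHg·mL·s⁻¹.
MMHG_ML_PER_SEC_PER_WATT = 7500.0

#: Wood units (mmHg·min·L⁻¹) → mmHg·s·mL⁻¹: 60 s/min ÷ 1000 mL/L.
WOOD_TO_CGS = 0.06

ResistanceUnits = Literal["wood", "cgs"]


@dataclass(frozen=True)
class RHCRecord:
    """One right-heart catheterization's measured quantities.

    Pressures in mmHg, cardiac output in L·min⁻¹, heart rate in beats·min⁻¹.
    ``bsa`` (m²) and ``age`` (years) are optional. Construction does not
    validate — screening and classification are cohort-level policy — but
    :meth:`ordering_violations` reports physiologic inconsistencies.
    """

    id: str
    spap: Optional[float] = None
    dpap: Optional[float] = None
    mpap: Optional[float] = None
    pcwp: Optional[float] = None
    co: Optional[float] = None
    hr: Optional[float] = None
    bsa: Optional[float] = None
    age: Optional[float] = None

    REQUIRED = ("spap", "dpap", "mpap", "pcwp", "co", "hr")

    def is_complete(self) -> bool:
        """True iff every field needed for an RC time is present and positive."""
        return all(
            getattr(self, f) is not None and getattr(self, f) > 0 for f in self.REQUIRED
        )

    def ordering_violations(self) -> list[str]:
        """Physiologic ordering checks (flagged, never silently dropped)."""
        v = []
        if None not in (self.spap, self.mpap) and self.spap < self.mpap:
            v.append(f"spap < mpap ({self.spap} < {self.mpap})")
        if None not in (self.mpap, self.dpap) and self.mpap < self.dpap:
            v.append(f"mpap < dpap ({self.mpap} < {self.dpap})")
        return v


@dataclass(frozen=True)
class DerivedHemodynamics:
    """All per-record derived quantities (full precision, no rounding)."""

    sv: float                      # stroke volume, mL
    pp: float                      # pulse pressure, mmHg
    ca: float                      # compliance SV/PP, mL·mmHg⁻¹
    pvr_wood: float                # (mPAP − PCWP)/CO, Wood units
    pvr_cgs: float                 # PVR, mmHg·s·mL⁻¹
    tpr_wood: float                # mPAP/CO, Wood units
    tpr_cgs: float                 # TPR, mmHg·s·mL⁻¹
    dpg: float                     # diastolic pressure gradient, mmHg
    rc_pvr: float                  # PVR-derived RC time, s
    rc_tpr: float                  # TPR-derived RC time, s
    mpap_spap_ratio: float
    ci: Optional[float] = None     # cardiac index, L·min⁻¹·m⁻², needs BSA


@dataclass(frozen=True)
class RVPowerProfile:
    """Right-ventricular hydraulic power decomposition (watts).

    ``w_total = w_mean + w_osc`` holds exactly by construction and the
    oscillatory fraction equals ``1 − mPAP/sPAP``: mean power uses mPAP,
    total power uses sPAP, both against the same mean flow.
    """

    w_mean: float
    w_total: float
    w_osc: float
    osc_fraction: float
    osc_fraction_corrected: Optional[float] = None


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if value is None:
            raise CompletenessError(f"{name} is missing")
        if value <= 0:
            raise DomainError(f"{name} must be > 0, got {value}")


def stroke_volume(co: float, hr: float) -> float:
    """Stroke volume (mL) from cardiac output (L·min⁻¹) and heart rate (bpm)."""
    _require_positive(co=co, hr=hr)
    return co * 1000.0 / hr


def compliance_sv_pp(sv: float, spap: float, dpap: float) -> float:
    """Pulmonary arterial compliance by the SV/PP method (mL·mmHg⁻¹).

    The SV/PP estimate is an upper bound on true compliance (it assumes the
    proximal arteries see the whole stroke volume), but it tracks the
    pulse-pressure-method gold standard well and needs no waveform.
    """
    if spap is None or dpap is None:
        raise CompletenessError("spap and dpap are both required")
    if spap <= dpap:
        raise DomainError(f"pulse pressure nonpositive: spap={spap} <= dpap={dpap}")
    return sv / (spap - dpap)


def pvr(mpap: float, pcwp: float, co: float, units: ResistanceUnits = "wood") -> float:
    """Pulmonary vascular resistance (mPAP − PCWP)/CO.

    ``units="wood"`` → mmHg·min·L⁻¹; ``units="cgs"`` → mmHg·s·mL⁻¹.
    mPAP < PCWP yields a negative value, returned with a warning: exclusion
    policy is the cohort module's job, not the formula layer's.
    """
    if mpap is None or pcwp is None:
        raise CompletenessError("mpap and pcwp are both required")
    _require_positive(co=co)
    wood = (mpap - pcwp) / co
    if wood < 0:
        warnings.warn(
            f"negative PVR ({wood:.3f} WU): mpap={mpap} < pcwp={pcwp}",
            UserWarning,
            stacklevel=2,
        )
    return _in_units(wood, units)


def tpr(mpap: float, co: float, units: ResistanceUnits = "wood") -> float:
    """Total pulmonary resistance mPAP/CO (ignores wedge pressure)."""
    if mpap is None:
        raise CompletenessError("mpap is required")
    _require_positive(co=co)
    return _in_units(mpap / co, units)


def _in_units(wood: float, units: ResistanceUnits) -> float:
    if units == "wood":
        return wood
    if units == "cgs":
        return wood * WOOD_TO_CGS
    raise DomainError(f"unknown resistance units {units!r}; use 'wood' or 'cgs'")


def dpg(dpap: float, pcwp: float) -> float:
    """Diastolic pressure gradient dPAP − PCWP (mmHg); may be negative."""
    if dpap is None or pcwp is None:
        raise CompletenessError("dpap and pcwp are both required")
    return dpap - pcwp


def rc_time(resistance_cgs: float, ca: float) -> float:
    """RC time (s) = resistance (mmHg·s·mL⁻¹) × compliance (mL·mmHg⁻¹)."""
    if resistance_cgs is None or ca is None:
        raise CompletenessError("resistance and compliance are both required")
    if resistance_cgs < 0 or ca < 0:
        raise DomainError(
            f"resistance and compliance must be >= 0, got {resistance_cgs}, {ca}"
        )
    return resistance_cgs * ca


def mpap_spap_ratio(mpap: float, spap: float) -> float:
    """mPAP/sPAP — the pressure ratio that fixes the oscillatory power fraction."""
    if mpap is None or spap is None:
        raise CompletenessError("mpap and spap are both required")
    if spap <= 0:
        raise DomainError(f"spap must be > 0, got {spap}")
    return mpap / spap


def rv_power(spap: float, mpap: float, co: float) -> RVPowerProfile:
    """Right-ventricular hydraulic power decomposition.

    With mean flow q = CO in mL·s⁻¹:

    * mean power      W_mean  = mPAP·q / 7500
    * total power     W_total = sPAP·q / 7500
    * oscillatory     W_osc   = (sPAP − mPAP)·q / 7500

    so the additive identity W_total = W_mean + W_osc is exact and the
    oscillatory ("wasted") power fraction is W_osc/W_total = 1 − mPAP/sPAP.
    """
    _require_positive(spap=spap, mpap=mpap, co=co)
    if spap < mpap:
        raise DomainError(f"spap must be >= mpap, got spap={spap} < mpap={mpap}")
    q = co * 1000.0 / 60.0  # mL·s⁻¹
    w_mean = mpap * q / MMHG_ML_PER_SEC_PER_WATT
    w_osc = (spap - mpap) * q / MMHG_ML_PER_SEC_PER_WATT
    return RVPowerProfile(
        w_mean=w_mean,
        w_total=w_mean + w_osc,
        w_osc=w_osc,
        osc_fraction=1.0 - mpap / spap,
    )


def corrected_osc_fraction(profile: RVPowerProfile, k: float) -> float:
    """Oscillatory power fraction with a systolic-pressure correction factor.

    Scales the oscillatory component by ``k`` in (0, 1] — accounting for
    systolic pressure not being constant throughout systole — and returns
    k·W_osc / (W_mean + k·W_osc). k = 1 recovers the uncorrected fraction.
    The factor is caller-supplied; the package ships no default.
    """
    if not (0.0 < k <= 1.0):
        raise DomainError(f"correction factor k must be in (0, 1], got {k}")
    return k * profile.w_osc / (profile.w_mean + k * profile.w_osc)


def rc_from_summary(
    spap: float,
    dpap: float,
    mpap: float,
    pcwp: float,
    co: float,
    hr: float,
    mode: Literal["pvr", "tpr"] = "pvr",
) -> float:
    """RC time from published group-level summary statistics.

    Composes SV → Ca → resistance → RC on cohort means, as done when
    re-deriving an RC time from a published table rather than patient-level
    data. Note in ``pvr`` mode CO cancels algebraically:
    RC = 60·(mPAP − PCWP) / (HR·PP).
    """
    sv = stroke_volume(co, hr)
    ca = compliance_sv_pp(sv, spap, dpap)
    if mode == "pvr":
        r = pvr(mpap, pcwp, co, units="cgs")
    elif mode == "tpr":
        r = tpr(mpap, co, units="cgs")
    else:
        raise DomainError(f"unknown mode {mode!r}; use 'pvr' or 'tpr'")
    return rc_time(r, ca)


def derive_record(record: RHCRecord) -> DerivedHemodynamics:
    """All derived quantities for one complete RHC record."""
    if not record.is_complete():
        missing = [
            f
            for f in RHCRecord.REQUIRED
            if getattr(record, f) is None or getattr(record, f) <= 0
        ]
        raise CompletenessError(
            f"record {record.id!r} incomplete: missing/nonpositive {missing}"
        )
    sv = stroke_volume(record.co, record.hr)
    ca = compliance_sv_pp(sv, record.spap, record.dpap)
    pvr_w = pvr(record.mpap, record.pcwp, record.co, units="wood")
    tpr_w = tpr(record.mpap, record.co, units="wood")
    ci = record.co / record.bsa if record.bsa else None
    return DerivedHemodynamics(
        sv=sv,
        pp=record.spap - record.dpap,
        ca=ca,
        pvr_wood=pvr_w,
        pvr_cgs=pvr_w * WOOD_TO_CGS,
        tpr_wood=tpr_w,
        tpr_cgs=tpr_w * WOOD_TO_CGS,
        dpg=dpg(record.dpap, record.pcwp),
        rc_pvr=pvr_w * WOOD_TO_CGS * ca,  # may be negative when mpap < pcwp; flagged upstream
        rc_tpr=rc_time(tpr_w * WOOD_TO_CGS, ca),
        mpap_spap_ratio=mpap_spap_ratio(record.mpap, record.spap),
        ci=ci,
    )
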