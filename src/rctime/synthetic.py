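"""Synthetic right-heart-catheterization cohorts.

Emulates the statistical structure the analysis pipeline assumes — group
marginals like a published cohort-characteristics table, an inverse
compliance–resistance link, and the physiologic orderings
sPAP > mPAP > dPAP ≥ PCWP (so the diastolic pressure gradient is never
negative) — without copying any real patient's data.

Per record the generator

1. draws mPAP, PCWP, CO, HR and age from *truncated* normals whose
   truncated mean/SD are moment-matched to the spec values (the underlying
   location/scale are solved numerically, so a spec that states
   "mPAP 41.1 ± 12, ≥ 25" really delivers those sample moments); these
   marginals are never rejected on, so their sample moments are exact up
   to sampling noise,
2. closes the pressure triplet from two more truncated-normal draws:
   sPAP = mPAP/ratio (ratio < 1 by truncation, so sPAP > mPAP), and
   dPAP = PCWP + DPG with the diastolic pressure gradient DPG drawn ≥ 0
   and below mPAP − PCWP — every ordering constraint then holds by
   construction, with no rejection and therefore no bias in the drawn
   marginals (a record is replaced wholesale only in the rare case
   mPAP ≤ PCWP, where no valid gradient exists),
3. draws compliance from the inverse law Ca = a/(b + PVR_wood) + noise,
   with the noise a truncated Gaussian keeping Ca above ``ca_floor`` and —
   when the spec carries a resistance selection criterion (``pvr_floor``,
   e.g. the PVR > 3 Wood units clause of the PAH definition) — below the
   compliance at which the record's final PVR would cross that floor,
4. rescales CO in a single pass so SV/PP reproduces the drawn Ca. The
   record's final PVR therefore differs from the PVR at which Ca was drawn;
   this residual link inconsistency is measured and reported in the
   diagnostics, which also keep the drawing-basis PVR so the exact noisy
   link (basis PVR, Ca) is available to downstream tests.

Seeds are mandatory: there is no implicit global randomness.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field as dc_field
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .errors import DomainError, SpecInfeasibleError
from .hemo import RHCRecord


@dataclass(frozen=True)
class FieldSpec:
    """Target mean/SD of one marginal, with optional truncation bounds.

    ``mean`` and ``sd`` are the moments of the *truncated* distribution;
    the generator solves for the underlying normal's location and scale.
    """

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise DomainError(f"sd must be > 0, got {self.sd}")
        if not self.lower < self.upper:
            raise DomainError("lower bound must be below upper bound")
        if not (self.lower < self.mean < self.upper):
            raise DomainError("target mean must lie inside the truncation bounds")


@functools.lru_cache(maxsize=256)
def _truncnorm_params(spec: FieldSpec) -> tuple[float, float]:
    """Location/scale of the untruncated normal whose truncation to
    [lower, upper] has the spec's mean and SD."""
    if math.isinf(spec.lower) and math.isinf(spec.upper):
        return spec.mean, spec.sd

    def moments(theta):
        mu, log_sigma = theta
        if abs(log_sigma) > 20:  # solver excursion
            return [1e6, 1e6]
        sigma = math.exp(log_sigma)
        a = (spec.lower - mu) / sigma
        b = (spec.upper - mu) / sigma
        with np.errstate(all="ignore"):
            m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        m, v = float(m), float(v)
        if not (math.isfinite(m) and math.isfinite(v)) or v <= 0:
            return [1e6, 1e6]
        return [m - spec.mean, math.sqrt(v) - spec.sd]

    sol = optimize.root(moments, x0=[spec.mean, math.log(spec.sd)], method="hybr")
    if not sol.success or max(abs(np.asarray(moments(sol.x)))) > 1e-6:
        raise SpecInfeasibleError(
            f"cannot moment-match truncated normal for {spec}: "
            "the target SD may be unattainable within the bounds"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _draw_truncated(
    spec: FieldSpec,
    size: int,
    rng: np.random.Generator,
    upper_override: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Inverse-CDF sample from the moment-matched truncated normal;
    ``upper_override`` tightens the upper bound per draw (element-wise)."""
    mu, sigma = _truncnorm_params(spec)
    lo = sps.norm.cdf((spec.lower - mu) / sigma) if math.isfinite(spec.lower) else 0.0
    if upper_override is None:
        hi = sps.norm.cdf((spec.upper - mu) / sigma) if math.isfinite(spec.upper) else 1.0
    else:
        upper = np.minimum(spec.upper, upper_override)
        hi = sps.norm.cdf((upper - mu) / sigma)
    u = rng.uniform(lo, hi, size)
    return mu + sigma * sps.norm.ppf(u)


@dataclass(frozen=True)
class GroupSpec:
    """Everything needed to emulate one cohort group.

    ``dpg`` is the diastolic pressure gradient dPAP − PCWP (mmHg), the
    primitive that closes the pressure triplet; its lower bound must be
    ≥ 0. ``link_a``/``link_b`` parameterize the compliance link
    Ca = a/(b + PVR) with PVR in Wood units; ``link_noise_sd`` is the
    Gaussian scatter around that law (mL·mmHg⁻¹), truncated so Ca stays
    above ``ca_floor`` and, if ``pvr_floor`` is set, so the record's final
    PVR stays above that selection floor. Optional ``spap_bounds`` /
    ``dpap_bounds`` emulate selection criteria on the derived pressures by
    whole-record rejection (off by default: rejection biases the drawn
    marginals).
    """

    label: str
    n: int
    mpap: FieldSpec
    ratio: FieldSpec
    pcwp: FieldSpec
    co: FieldSpec
    hr: FieldSpec
    dpg: FieldSpec = FieldSpec(2.0, 0.7, 0.0, math.inf)
    age: Optional[FieldSpec] = None
    link_a: float = 10.4
    link_b: float = 0.5
    link_noise_sd: float = 0.3
    ca_floor: float = 0.1
    spap_bounds: Optional[tuple[float, float]] = None
    dpap_bounds: Optional[tuple[float, float]] = None
    pvr_floor: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if self.link_a <= 0:
            raise DomainError("link numerator a must be > 0")
        if self.link_noise_sd < 0:
            raise DomainError("link_noise_sd must be >= 0")
        if self.dpg.lower < 0:
            raise DomainError("dpg lower bound must be >= 0 (no negative gradients)")
        if self.ratio.lower <= 0 or self.ratio.upper >= 1:
            raise DomainError("ratio bounds must lie inside (0, 1)")


def nph_spec(n: int = 156, seed: Optional[int] = None) -> GroupSpec:
    """Normal-pulmonary-hemodynamics group.

    Directly drawn marginals (mPAP, PCWP, HR) are truncated at the ±2 SD
    selection bounds of the published healthy reference values that define
    the group, so the drawn moments match the cohort table exactly. The
    DPG spec's SD is chosen so the implied dPAP = PCWP + DPG reproduces
    the table's dPAP SD under an independent gradient (√(2.4² − 2.3²)).
    """
    return GroupSpec(
        label="NPH",
        n=n,
        mpap=FieldSpec(16.0, 2.3, 7.41, 20.49),
        ratio=FieldSpec(0.66, 0.08, 0.45, 0.95),
        pcwp=FieldSpec(7.8, 2.3, 2.27, 13.67),
        co=FieldSpec(4.6, 1.0, 1.5, math.inf),
        hr=FieldSpec(75.2, 13.2, 48.0, 104.0),
        dpg=FieldSpec(2.0, 0.69, 0.0, math.inf),
        age=FieldSpec(53.3, 13.1, 18.0, 95.0),
        link_a=10.4,
        link_b=0.5,
        seed=seed,
    )


def pah_spec(n: int = 717, seed: Optional[int] = None) -> GroupSpec:
    """Pulmonary-arterial-hypertension group: elevated pressures with mPAP
    truncated at the defining 25 mmHg floor, PCWP ≤ 15 mmHg, and the
    resistance clause of the hemodynamic definition (PVR > 3 Wood units)
    enforced through the compliance-noise truncation (``pvr_floor``).
    DPG SD is √(8.7² − 2.9²) so dPAP = PCWP + DPG has the table's SD."""
    return GroupSpec(
        label="PAH",
        n=n,
        mpap=FieldSpec(41.1, 12.0, 25.0, math.inf),
        ratio=FieldSpec(0.61, 0.06, 0.45, 0.95),
        pcwp=FieldSpec(10.5, 2.9, 2.0, 15.0),
        co=FieldSpec(4.3, 1.3, 1.0, math.inf),
        hr=FieldSpec(78.5, 13.3, 40.0, 130.0),
        dpg=FieldSpec(14.9, 8.2, 0.0, math.inf),
        age=FieldSpec(60.4, 14.6, 18.0, 95.0),
        link_a=10.4,
        link_b=0.8,
        pvr_floor=3.0,
        seed=seed,
    )


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus generator diagnostics: the wholesale-replaced
    record count, the mean absolute residual of the compliance link after
    CO rescaling, and the per-record drawing-basis PVR/Ca arrays."""

    records: tuple[RHCRecord, ...]
    diagnostics: dict = dc_field(default_factory=dict)

    def __iter__(self) -> Iterator[RHCRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def generate_cohort(spec: GroupSpec, seed: Optional[int] = None) -> SyntheticCohort:
    """Draw ``spec.n`` physiologically ordered records (see module docs).

    ``seed`` overrides ``spec.seed``; one of them must be given. Identical
    (spec, seed) pairs produce identical cohorts.
    """
    if seed is None:
        seed = spec.seed
    if seed is None:
        raise DomainError("an explicit seed is required (spec.seed or argument)")
    rng = np.random.default_rng(seed)

    replaced_total = 0
    parts: dict[str, list[np.ndarray]] = {
        k: [] for k in ("spap", "dpap", "mpap", "pcwp", "co", "hr", "age")
    }
    collected = 0
    while collected < spec.n:
        n = spec.n - collected
        if replaced_total > 100 * spec.n + 1000:
            raise SpecInfeasibleError(
                f"spec {spec.label!r}: rejection rate above 99% "
                f"({replaced_total} records replaced)"
            )
        # 1. gate marginals, drawn unconditionally (exact moments)
        mpap = _draw_truncated(spec.mpap, n, rng)
        pcwp = _draw_truncated(spec.pcwp, n, rng)
        co = _draw_truncated(spec.co, n, rng)
        hr = _draw_truncated(spec.hr, n, rng)
        age = _draw_truncated(spec.age, n, rng) if spec.age else np.full(n, np.nan)

        # 2. pressure closure by construction: a record is only infeasible
        # when mPAP <= PCWP (no valid gradient interval)
        gradient_room = mpap - pcwp
        feasible = gradient_room > 1e-6
        dpg = np.full(n, np.nan)
        if feasible.any():
            dpg[feasible] = _draw_truncated(
                spec.dpg, int(feasible.sum()), rng,
                upper_override=gradient_room[feasible],
            )
        dpap = pcwp + dpg
        ratio = _draw_truncated(spec.ratio, n, rng)
        spap = mpap / ratio
        ok = feasible & (dpap < mpap) & (mpap < spap) & (dpap > 0)
        if spec.spap_bounds:
            ok &= (spap >= spec.spap_bounds[0]) & (spap <= spec.spap_bounds[1])
        if spec.dpap_bounds:
            ok &= (dpap >= spec.dpap_bounds[0]) & (dpap <= spec.dpap_bounds[1])
        replaced_total += int((~ok).sum())
        for key, arr in (("spap", spap), ("dpap", dpap), ("mpap", mpap),
                         ("pcwp", pcwp), ("co", co), ("hr", hr), ("age", age)):
            parts[key].append(arr[ok])
        collected += int(ok.sum())

    spap, dpap, mpap, pcwp, co, hr, age = (
        np.concatenate(parts[k])[: spec.n]
        for k in ("spap", "dpap", "mpap", "pcwp", "co", "hr", "age")
    )

    # 3. compliance link with truncated noise
    pvr_basis = (mpap - pcwp) / co
    ca_mean = spec.link_a / (spec.link_b + pvr_basis)
    pp = spap - dpap
    flow_factor = pp * hr / 1000.0  # rescaled CO per unit compliance
    ca_hi = (
        (mpap - pcwp) / (flow_factor * spec.pvr_floor)
        if spec.pvr_floor
        else np.full(spec.n, np.inf)
    )
    link_clipped = 0
    if spec.link_noise_sd > 0:
        lo_q = sps.norm.cdf((spec.ca_floor - ca_mean) / spec.link_noise_sd)
        hi_q = sps.norm.cdf((ca_hi - ca_mean) / spec.link_noise_sd)
        degenerate = hi_q - lo_q < 1e-12
        link_clipped = int(degenerate.sum())
        u = rng.uniform(lo_q, np.maximum(hi_q, lo_q + 1e-12), spec.n)
        ca = ca_mean + spec.link_noise_sd * sps.norm.ppf(u)
        if degenerate.any():
            ca[degenerate] = np.clip(
                ca_mean[degenerate], spec.ca_floor, ca_hi[degenerate]
            )
    else:
        ca = np.clip(ca_mean, spec.ca_floor, ca_hi)

    # 4. single CO-rescaling pass: SV/PP now equals the drawn compliance
    co_rescaled = ca * flow_factor
    pvr_after = (mpap - pcwp) / co_rescaled
    resid = np.abs(ca - spec.link_a / (spec.link_b + pvr_after))

    records = tuple(
        RHCRecord(
            id=f"{spec.label}-{i:04d}",
            spap=float(spap[i]),
            dpap=float(dpap[i]),
            mpap=float(mpap[i]),
            pcwp=float(pcwp[i]),
            co=float(co_rescaled[i]),
            hr=float(hr[i]),
            age=None if np.isnan(age[i]) else float(age[i]),
        )
        for i in range(spec.n)
    )
    diagnostics = {
        "n": spec.n,
        "replaced_records": replaced_total,
        "rejection_rate": replaced_total / (spec.n + replaced_total),
        "link_residual_mean_abs": float(np.mean(resid)),
        "link_clipped": link_clipped,
        # PVR at which each record's compliance was drawn; (pvr_link_basis,
        # ca_drawn) lie exactly on the noisy inverse law
        "pvr_link_basis": pvr_basis,
        "ca_drawn": ca,
        "seed": int(seed),
    }
    return SyntheticCohort(records=records, diagnostics=diagnostics)


# --------------------------------------------------------------------------
# regression fixtures


def generate_regression_fixture(
    model: Literal["inverse", "linear"],
    params: dict | Sequence[dict],
    noise_sd: float,
    n: int | Sequence[int],
    seed: int,
    x_range: tuple[float, float] | Sequence[tuple[float, float]] = (0.5, 15.0),
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """(x, y, group) arrays from a known generating curve plus noise.

    ``params`` is one dict (single group; returned ``group`` is None) or a
    sequence of per-group dicts — ``{"a", "b"}`` for the inverse law
    a/(b + x), ``{"slope", "intercept"}`` for a line. ``n`` and ``x_range``
    may likewise be given per group. x is uniform over its range.
    """
    if seed is None:
        raise DomainError("an explicit seed is required")
    single = isinstance(params, dict)
    param_list = [params] if single else list(params)
    n_list = [n] * len(param_list) if isinstance(n, int) else list(n)
    if isinstance(x_range[0], (int, float)):
        range_list = [tuple(x_range)] * len(param_list)
    else:
        range_list = [tuple(r) for r in x_range]
    if not (len(param_list) == len(n_list) == len(range_list)):
        raise DomainError("params, n and x_range must have matching group counts")

    n_params_per_group = 2
    rng = np.random.default_rng(seed)
    xs, ys, gs = [], [], []
    for g, (p, ng, (lo, hi)) in enumerate(zip(param_list, n_list, range_list)):
        if ng < n_params_per_group + 1:
            raise SpecInfeasibleError(f"group {g}: n={ng} below parameter count")
        x = rng.uniform(lo, hi, ng)
        if model == "inverse":
            y = p["a"] / (p["b"] + x)
        elif model == "linear":
            y = p["intercept"] + p["slope"] * x
        else:
            raise DomainError(f"unknown model {model!r}")
        y = y + rng.normal(0.0, noise_sd, ng) if noise_sd > 0 else y
        xs.append(x)
        ys.append(y)
        gs.append(np.full(ng, g))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    group = None if single else np.concatenate(gs)
    return x, y, group
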